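"""Homology screen: find putative pre-miRNA loci in assembled transcripts.

A k-mer seed-and-extend local aligner (match +1, mismatch -2, gap -2.5)
replaces an external BLASTN binary so the pipeline is self-contained. Both
strands of every transcript are searched. Significance is a Karlin-Altschul
style proxy E = K * m * N * exp(-lambda * S) with calibrated constants
(lambda = 1.9, K = 0.35) chosen so that an exact match of >= 24 nt against a
1 Mb database clears a 1e-10 cutoff; the proxy orders hits like BLAST
e-values but does not reproduce NCBI statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .refio import SequenceRecord, reverse_complement

__all__ = [
    "HomologyHit",
    "PrecursorCandidate",
    "KmerIndex",
    "build_index",
    "search",
    "extract_candidates",
    "hit_table",
]

MATCH = 1.0
MISMATCH = -2.0
GAP = -2.5
LAMBDA = 1.9
KA_K = 0.35
BAND = 8  # half-width of the banded extension around a seed diagonal
XDROP = 12.0


@dataclass(frozen=True)
class HomologyHit:
    """A local alignment between a reference pre-miRNA and a transcript.

    All coordinates are 1-based inclusive on the plus strand of both
    sequences; ``strand`` records which transcript strand aligned.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # "+" or "-"
    identity_percent: float
    alignment_length: int
    score: float
    evalue_proxy: float


@dataclass(frozen=True)
class PrecursorCandidate:
    """A transcript subsequence proposed as a pre-miRNA, with provenance."""

    id: str
    seq: str
    source_id: str
    start: int  # 1-based inclusive on the transcript plus strand
    end: int
    strand: str
    matched_refs: tuple[str, ...]


@dataclass(frozen=True)
class KmerIndex:
    k: int
    references: tuple[SequenceRecord, ...]
    postings: dict  # kmer -> tuple[(ref_index, offset), ...]


def build_index(references: list[SequenceRecord], k: int = 11) -> KmerIndex:
    """Exact k-mer -> (reference, 0-based offset) postings; deterministic."""
    if k < 4:
        raise ValueError(f"k must be >= 4, got {k}")
    postings: dict[str, list[tuple[int, int]]] = {}
    kept: list[SequenceRecord] = []
    for rec in references:
        if len(rec.seq) < k:
            warnings.warn(
                f"reference {rec.id!r} shorter than k={k}; skipped", stacklevel=2
            )
            continue
        idx = len(kept)
        kept.append(rec)
        for off in range(len(rec.seq) - k + 1):
            postings.setdefault(rec.seq[off : off + k], []).append((idx, off))
    return KmerIndex(
        k=k,
        references=tuple(kept),
        postings={kmer: tuple(v) for kmer, v in postings.items()},
    )


def _banded_local(query: str, subject: str, diag: int) -> tuple | None:
    """Banded local alignment around ``diag`` (s_off - q_off).

    Returns (score, q_start, q_end, s_start, s_end, matches, length) with
    0-based half-open coordinates, or None if no positive-score alignment.
    """
    m, n = len(query), len(subject)
    NEG = -1e30
    # cell (i, j): query prefix i, subject prefix j; restrict |j - i - diag| <= BAND
    prev = [0.0] * (n + 1)
    prev_src = [None] * (n + 1)
    best = (0.0, None)
    cells_src: list[list] = [prev_src]
    rows: list[list[float]] = [prev]
    for i in range(1, m + 1):
        cur = [NEG] * (n + 1)
        cur_src: list = [None] * (n + 1)
        lo = max(1, i + diag - BAND)
        hi = min(n, i + diag + BAND)
        if lo > hi:
            rows.append(cur)
            cells_src.append(cur_src)
            continue
        for j in range(lo, hi + 1):
            sub = MATCH if query[i - 1] == subject[j - 1] else MISMATCH
            cand = 0.0
            src = None  # local start
            d = rows[i - 1][j - 1] + sub
            if d > cand:
                cand, src = d, ("d", i - 1, j - 1)
            u = rows[i - 1][j] + GAP
            if u > cand:
                cand, src = u, ("u", i - 1, j)
            l = cur[j - 1] + GAP
            if l > cand:
                cand, src = l, ("l", i, j - 1)
            cur[j] = cand
            cur_src[j] = src
            if cand > best[0]:
                best = (cand, (i, j))
        rows.append(cur)
        cells_src.append(cur_src)
    if best[1] is None:
        return None
    # traceback for coordinates and identity
    score, (i, j) = best
    q_end, s_end = i, j
    matches = length = 0
    while True:
        src = cells_src[i][j]
        if src is None:
            break
        kind, pi, pj = src
        if kind == "d":
            matches += 1 if query[i - 1] == subject[j - 1] else 0
        length += 1
        i, j = pi, pj
    return score, i, q_end, j, s_end, matches, length


def search(
    transcripts: list[SequenceRecord],
    index: KmerIndex,
    min_identity: float = 85.0,
    evalue_max: float = 1e-10,
) -> list[HomologyHit]:
    """Seed-and-extend search of every transcript (both strands) against the index.

    Hits are sorted by score descending with a deterministic (subject, start)
    tie-break; an empty result is valid.
    """
    k = index.k
    db_len = 2 * sum(len(t.seq) for t in transcripts)
    hits: list[HomologyHit] = []
    for tr in transcripts:
        n = len(tr.seq)
        for strand in ("+", "-"):
            subject = tr.seq if strand == "+" else reverse_complement(tr.seq)
            # seeds grouped by (reference, diagonal)
            groups: dict[tuple[int, int], list[int]] = {}
            for s_off in range(n - k + 1):
                for ref_idx, q_off in index.postings.get(subject[s_off : s_off + k], ()):
                    groups.setdefault((ref_idx, s_off - q_off), []).append(s_off)
            # merge nearby diagonals per reference
            merged: dict[int, list[list[int]]] = {}
            for (ref_idx, diag) in sorted(groups):
                lst = merged.setdefault(ref_idx, [])
                if lst and diag - lst[-1][-1] <= BAND // 2:
                    lst[-1].append(diag)
                else:
                    lst.append([diag])
            for ref_idx, diag_runs in sorted(merged.items()):
                ref = index.references[ref_idx]
                seen_spans: set[tuple[int, int]] = set()
                for run in diag_runs:
                    diag = run[len(run) // 2]
                    res = _banded_local(ref.seq, subject, diag)
                    if res is None:
                        continue
                    score, q0, q1, s0, s1, matches, length = res
                    if length == 0:
                        continue
                    span = (s0, s1)
                    if span in seen_spans:
                        continue
                    seen_spans.add(span)
                    identity = 100.0 * matches / length
                    evalue = KA_K * len(ref.seq) * db_len * math.exp(-LAMBDA * score)
                    if identity < min_identity or evalue > evalue_max:
                        continue
                    if strand == "+":
                        s_start, s_end = s0 + 1, s1
                    else:  # map back to plus-strand coordinates
                        s_start, s_end = n - s1 + 1, n - s0
                    hits.append(
                        HomologyHit(
                            query_id=ref.id,
                            subject_id=tr.id,
                            q_start=q0 + 1,
                            q_end=q1,
                            s_start=s_start,
                            s_end=s_end,
                            strand=strand,
                            identity_percent=identity,
                            alignment_length=length,
                            score=score,
                            evalue_proxy=evalue,
                        )
                    )
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start, h.strand, h.query_id))
    return hits


def extract_candidates(
    hits: list[HomologyHit],
    transcripts: list[SequenceRecord],
    flank: int = 20,
) -> list[PrecursorCandidate]:
    """One candidate per merged overlapping hit region, extended by ``flank`` nt.

    Minus-strand candidates are reverse-complemented to the reference-sense
    strand; flank extension is clipped at transcript ends.
    """
    by_id = {t.id: t for t in transcripts}
    regions: dict[tuple[str, str], list[tuple[int, int, set[str]]]] = {}
    for h in hits:
        key = (h.subject_id, h.strand)
        regions.setdefault(key, []).append((h.s_start, h.s_end, {h.query_id}))
    candidates: list[PrecursorCandidate] = []
    for (subject_id, strand) in sorted(regions):
        tr = by_id[subject_id]
        intervals = sorted(regions[(subject_id, strand)])
        merged: list[list] = []
        for start, end, refs in intervals:
            if merged and start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] |= refs
            else:
                merged.append([start, end, set(refs)])
        for start, end, refs in merged:
            lo = max(1, start - flank)
            hi = min(len(tr.seq), end + flank)
            seq = tr.seq[lo - 1 : hi]
            if strand == "-":
                seq = reverse_complement(seq)
            candidates.append(
                PrecursorCandidate(
                    id=f"{subject_id}:{lo}-{hi}({strand})",
                    seq=seq,
                    source_id=subject_id,
                    start=lo,
                    end=hi,
                    strand=strand,
                    matched_refs=tuple(sorted(refs)),
                )
            )
    candidates.sort(key=lambda c: (c.source_id, c.start, c.strand))
    return candidates


def hit_table(hits: list[HomologyHit]):
    """BLAST tabular (outfmt-6-like) column order, as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(h.identity_percent, 2),
                "length": h.alignment_length,
                "qstart": h.q_start,
                "qend": h.q_end,
                "sstart": h.s_start,
                "send": h.s_end,
                "strand": h.strand,
                "bitscore": h.score,
                "evalue": h.evalue_proxy,
            }
            for h in hits
        ],
        columns=[
            "qseqid", "sseqid", "pident", "length", "qstart", "qend",
            "sstart", "send", "strand", "bitscore", "evalue",
        ],
    )
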