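"""miRNA target prediction by antiparallel complementarity, with degradome validation.

Scoring follows the plant-miRNA complementarity convention: per-position
penalties of 1.0 for a mismatch, 0.5 for a G:U wobble and 2.0 for a gap, all
doubled within the seed-proximal region (miRNA positions 2-13), with sites
kept below a total-penalty cutoff (default 3.0). The duplex is antiparallel:
miRNA position 1 pairs the 3' end of the site. Slicing happens between the
bases pairing miRNA positions 10 and 11; the reported cleavage coordinate is
the transcript base opposite position 10. Predicted sites are validated
against degradome (PARE) tag pileups using t-plot categories in the
CleaveLand style.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np

from .refio import DegradomeTag, SequenceRecord

__all__ = [
    "TargetAlignment",
    "TPlot",
    "score_site",
    "align_duplex",
    "scan_transcripts",
    "cleavage_position",
    "degradome_validate",
    "target_report",
]

MISMATCH_W = 1.0
GU_W = 0.5
GAP_W = 2.0
SEED_START, SEED_END = 2, 13  # positions with doubled weights
SEED_MULT = 2.0
MAX_GAPS = 3  # max gap columns; window length stays within miRNA length +/- 3
CLEAVAGE_OPPOSITE = 10  # miRNA position opposite the slice site

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_WC = {(0, 3), (3, 0), (2, 1), (1, 2)}
_WOBBLE = {(2, 3), (3, 2)}
_INF = 1e30


def _pos_weight(mpos: int) -> float:
    return SEED_MULT if SEED_START <= mpos <= SEED_END else 1.0


def _pair_state(m_base: int, t_base: int) -> str:
    if (m_base, t_base) in _WC:
        return "match"
    if (m_base, t_base) in _WOBBLE:
        return "gu"
    return "mismatch"


def _subst_cost(m_base: int, t_base: int, mpos: int) -> float:
    state = _pair_state(m_base, t_base)
    if state == "match":
        return 0.0
    w = _pos_weight(mpos)
    return GU_W * w if state == "gu" else MISMATCH_W * w


def _gap_cost(mpos: int) -> float:
    return GAP_W * _pos_weight(mpos)


@dataclass(frozen=True)
class TargetAlignment:
    """An antiparallel miRNA:mRNA duplex over a transcript site.

    ``states`` gives one of match / mismatch / gu / gap_t per miRNA position
    (5'->3'); ``t_positions`` the 1-based transcript coordinate paired with
    each miRNA position (None at a gap_t column). ``gap_m_positions`` lists
    transcript coordinates bulged out of the duplex (gap in the miRNA).
    ``penalty`` is the sum of position weights. miRNA position 1 pairs
    ``site_end``.
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    states: tuple[str, ...]
    t_positions: tuple[int | None, ...]
    gap_m_positions: tuple[int, ...]
    penalty: float

    @property
    def n_gaps(self) -> int:
        return self.states.count("gap_t") + len(self.gap_m_positions)


def align_duplex(
    mirna_seq: str, window_seq: str
) -> tuple[float, list[tuple[int | None, int | None, str]]]:
    """Optimal antiparallel duplex between a miRNA and a transcript window.

    Both sequences are given 5'->3'; the window is reversed internally so
    miRNA position 1 faces the window's 3' end. Global over both sequences
    with at most MAX_GAPS gap columns. Returns the penalty and alignment
    columns ``(mirna_pos, window_pos, state)`` with 1-based positions
    (window_pos in window coordinates; None marks the gapped side).
    Tie-break: fewest gaps, then gaps as late as possible along the miRNA.
    """
    L, W = len(mirna_seq), len(window_seq)
    if abs(W - L) > MAX_GAPS:
        raise ValueError(
            f"window length {W} outside miRNA length {L} +/- {MAX_GAPS}"
        )
    m = [_CODE[b] for b in mirna_seq]
    t = [_CODE[b] for b in reversed(window_seq)]
    G = MAX_GAPS
    D = np.full((G + 1, L + 1, W + 1), _INF)
    D[0, 0, 0] = 0.0
    for g in range(G + 1):
        for i in range(L + 1):
            for j in range(W + 1):
                cur = D[g, i, j]
                if cur >= _INF:
                    continue
                if i < L and j < W:
                    c = cur + _subst_cost(m[i], t[j], i + 1)
                    if c < D[g, i + 1, j + 1]:
                        D[g, i + 1, j + 1] = c
                if g < G and i < L:  # gap_t: miRNA base unpaired
                    c = cur + _gap_cost(i + 1)
                    if c < D[g + 1, i + 1, j]:
                        D[g + 1, i + 1, j] = c
                if g < G and j < W:  # gap_m: window base bulged
                    c = cur + _gap_cost(min(i + 1, L))
                    if c < D[g + 1, i, j + 1]:
                        D[g + 1, i, j + 1] = c
    finals = [(float(D[g, L, W]), g) for g in range(G + 1)]
    penalty, g = min(finals)
    if penalty >= _INF:
        raise ValueError("no admissible alignment within the gap budget")
    # traceback, preferring the diagonal (pushes gaps late along the miRNA)
    cols: list[tuple[int | None, int | None, str]] = []
    i, j = L, W
    while i > 0 or j > 0:
        placed = False
        if i > 0 and j > 0:
            c = _subst_cost(m[i - 1], t[j - 1], i)
            if D[g, i - 1, j - 1] + c == D[g, i, j]:
                cols.append((i, W - j + 1, _pair_state(m[i - 1], t[j - 1])))
                i, j = i - 1, j - 1
                placed = True
        if not placed and g > 0 and i > 0:
            if D[g - 1, i - 1, j] + _gap_cost(i) == D[g, i, j]:
                cols.append((i, None, "gap_t"))
                i, g = i - 1, g - 1
                placed = True
        if not placed and g > 0 and j > 0:
            if D[g - 1, i, j - 1] + _gap_cost(min(i + 1, L)) == D[g, i, j]:
                cols.append((None, W - j + 1, "gap_m"))
                j, g = j - 1, g - 1
                placed = True
        if not placed:  # inconsistent tables; cannot happen
            raise AssertionError("duplex traceback failed")
    cols.reverse()
    return penalty, cols


def score_site(
    mirna: SequenceRecord,
    transcript_window: str,
    *,
    transcript_id: str = "",
    site_start: int = 1,
) -> TargetAlignment:
    """Score one candidate window; coordinates are relative to ``site_start``."""
    from .refio import normalize_rna

    window = normalize_rna(transcript_window)
    penalty, cols = align_duplex(mirna.seq, window)
    L = len(mirna.seq)
    states: list[str] = [""] * L
    t_positions: list[int | None] = [None] * L
    gap_m: list[int] = []
    for mpos, wpos, state in cols:
        tpos = site_start + wpos - 1 if wpos is not None else None
        if state == "gap_m":
            gap_m.append(tpos)  # type: ignore[arg-type]
        else:
            states[mpos - 1] = state
            t_positions[mpos - 1] = tpos
    return TargetAlignment(
        mirna_id=mirna.id,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_start + len(window) - 1,
        states=tuple(states),
        t_positions=tuple(t_positions),
        gap_m_positions=tuple(sorted(gap_m)),
        penalty=penalty,
    )


def _ungapped_penalties(m: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Penalty of the gapless duplex at every window start (vectorized)."""
    L, n = len(m), len(t)
    if n < L:
        return np.full(0, np.inf)
    starts = n - L + 1
    total = np.zeros(starts)
    for i in range(1, L + 1):  # miRNA position i pairs transcript base s + L - i
        tb = t[L - i : L - i + starts]
        mb = m[i - 1]
        w = _pos_weight(i)
        cost = np.full(starts, MISMATCH_W * w)
        wc = [u for (mm, u) in _WC if mm == mb]
        wob = [u for (mm, u) in _WOBBLE if mm == mb]
        for u in wc:
            cost[tb == u] = 0.0
        for u in wob:
            cost[tb == u] = GU_W * w
        total += cost
    return total


def scan_transcripts(
    mirnas: list[SequenceRecord],
    transcripts: list[SequenceRecord],
    max_penalty: float = 3.0,
) -> list[TargetAlignment]:
    """All target sites with optimal duplex penalty <= ``max_penalty``.

    A fast gapless scan locates candidate registers; candidates within
    ``2 * GAP_W`` of the cutoff are refined with the gapped aligner over
    window lengths L +/- MAX_GAPS. Overlapping windows for the same miRNA on
    the same transcript collapse to the best (lowest penalty, then fewest
    gaps, then leftmost).
    """
    results: list[TargetAlignment] = []
    for tr in transcripts:
        t = np.array([_CODE[b] for b in tr.seq], dtype=np.int8)
        for mir in mirnas:
            L = len(mir.seq)
            m = np.array([_CODE[b] for b in mir.seq], dtype=np.int8)
            pens = _ungapped_penalties(m, t)
            cand_starts = np.nonzero(pens <= max_penalty + 2 * GAP_W)[0]
            sites: list[TargetAlignment] = []
            for s0 in cand_starts:
                best: TargetAlignment | None = None
                for w in range(max(1, L - MAX_GAPS), L + MAX_GAPS + 1):
                    if s0 + w > len(tr.seq):
                        continue
                    window = tr.seq[s0 : s0 + w]
                    aln = score_site(
                        mir, window, transcript_id=tr.id, site_start=s0 + 1
                    )
                    if best is None or (aln.penalty, aln.n_gaps) < (
                        best.penalty,
                        best.n_gaps,
                    ):
                        best = aln
                if best is not None and best.penalty <= max_penalty:
                    sites.append(best)
            sites.sort(key=lambda a: (a.penalty, a.n_gaps, a.site_start))
            kept: list[TargetAlignment] = []
            for aln in sites:
                if all(
                    aln.site_end < k.site_start or aln.site_start > k.site_end
                    for k in kept
                ):
                    kept.append(aln)
            results.extend(kept)
    results.sort(key=lambda a: (a.transcript_id, a.site_start, a.mirna_id))
    return results


def cleavage_position(alignment: TargetAlignment) -> int | None:
    """Transcript coordinate opposite miRNA position 10; None when position
    10 sits at a gap (reported as "undetermined")."""
    return alignment.t_positions[CLEAVAGE_OPPOSITE - 1]


@dataclass(frozen=True)
class TPlot:
    """Degradome tag pileup around a predicted cleavage site."""

    transcript_id: str
    counts: tuple[int, ...]  # per-position tag counts, index 0 = position 1
    cleavage_pos: int
    site_count: int
    category: int  # 0 best (unique maximum) .. 4 (single read)


def degradome_validate(
    alignment: TargetAlignment,
    tags: list[DegradomeTag],
    window: int = 1,
) -> TPlot | None:
    """Validate a predicted site against degradome tags.

    ``site_count`` sums tag counts over cleavage_pos +/- window. Categories:
    0 when it equals a unique transcript-wide maximum, 1 when it equals a
    tied maximum, 2 when above the median of nonzero positions, 3 when at or
    below the median but more than one read, 4 for exactly one read. Sites
    with no tag support (or an undetermined cleavage position) are rejected
    (None).
    """
    cleavage = cleavage_position(alignment)
    if cleavage is None:
        return None
    mine = [t for t in tags if t.transcript_id == alignment.transcript_id]
    if not mine:
        return None
    n = max(max(t.position for t in mine), alignment.site_end)
    counts = [0] * n
    for t in mine:
        counts[t.position - 1] += t.count
    lo = max(1, cleavage - window)
    hi = min(n, cleavage + window)
    site_count = sum(counts[lo - 1 : hi])
    if site_count == 0:
        return None
    peak = max(counts)
    n_at_peak = counts.count(peak)
    if site_count == peak and n_at_peak == 1:
        category = 0
    elif site_count == peak:
        category = 1
    else:
        med = median([c for c in counts if c > 0])
        if site_count > med:
            category = 2
        elif site_count > 1:
            category = 3
        else:
            category = 4
    return TPlot(
        transcript_id=alignment.transcript_id,
        counts=tuple(counts),
        cleavage_pos=cleavage,
        site_count=site_count,
        category=category,
    )


def target_report(
    alignments: list[TargetAlignment],
    tags: list[DegradomeTag] | None = None,
    window: int = 1,
):
    """Target table: miRNA, transcript, site, cleavage site or "undetermined",
    penalty, and t-plot category when degradome tags are supplied."""
    import pandas as pd

    rows = []
    for aln in alignments:
        cleavage = cleavage_position(aln)
        row = {
            "mirna": aln.mirna_id,
            "transcript": aln.transcript_id,
            "site_start": aln.site_start,
            "site_end": aln.site_end,
            "penalty": aln.penalty,
            "cleavage_site": "undetermined" if cleavage is None else cleavage,
        }
        if tags is not None:
            tplot = degradome_validate(aln, tags, window)
            row["tplot_category"] = "" if tplot is None else tplot.category
            row["site_tag_count"] = 0 if tplot is None else tplot.site_count
        rows.append(row)
    cols = ["mirna", "transcript", "site_start", "site_end", "penalty", "cleavage_site"]
    if tags is not None:
        cols += ["tplot_category", "site_tag_count"]
    return pd.DataFrame(rows, columns=cols)
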