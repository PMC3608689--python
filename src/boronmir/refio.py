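"""Readers and writers for every external format the pipeline touches.

This module is the single home of two conventions used everywhere else:

* **Alphabet** — sequences are RNA over ``{A, C, G, U}``. DNA input is
  accepted (``T`` is normalized to ``U`` on read, case-folded to upper) but
  ``U -> T`` is never emitted.
* **Coordinates** — every transcript/precursor position that crosses a module
  boundary is 1-based inclusive. :func:`to_zero_based` / :func:`to_one_based`
  are the only sanctioned conversions; raw 0-based offsets never appear in a
  public field.

File formats: FASTA for sequences (via Biopython), TSV with ``#``-prefixed
metadata lines for count tables, degradome tags, Ct tables and reports.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "RefIOError",
    "DuplicateIdError",
    "EmptySequenceError",
    "AlphabetError",
    "CountTableError",
    "CoordinateError",
    "MalformedLineError",
    "SequenceRecord",
    "CountTable",
    "DegradomeTag",
    "CtRecord",
    "RNA_ALPHABET",
    "normalize_rna",
    "reverse_complement",
    "to_zero_based",
    "to_one_based",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_degradome",
    "write_degradome",
    "read_ct",
    "write_ct",
    "write_report",
]

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

LIBRARY_COLUMNS = ("root_control", "root_treated", "leaf_control", "leaf_treated")


class RefIOError(ValueError):
    """Base class for all validation errors raised by this module."""


class DuplicateIdError(RefIOError):
    pass


class EmptySequenceError(RefIOError):
    pass


class AlphabetError(RefIOError):
    pass


class CountTableError(RefIOError):
    pass


class CoordinateError(RefIOError):
    pass


class MalformedLineError(RefIOError):
    pass


def normalize_rna(seq: str, *, context: str = "") -> str:
    """Upper-case, T->U normalize and validate a sequence string."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"non-IUPAC RNA characters {sorted(bad)}"
            + (f" in record {context!r}" if context else "")
        )
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_zero_based(pos: int) -> int:
    """1-based inclusive coordinate -> 0-based offset."""
    if pos < 1:
        raise CoordinateError(f"1-based coordinate must be >= 1, got {pos}")
    return pos - 1


def to_one_based(offset: int) -> int:
    """0-based offset -> 1-based inclusive coordinate."""
    if offset < 0:
        raise CoordinateError(f"0-based offset must be >= 0, got {offset}")
    return offset + 1


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA sequence (unigene, pre-miRNA or mature miRNA)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise RefIOError("sequence id must be non-empty")
        if not self.seq:
            raise EmptySequenceError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", normalize_rna(self.seq, context=self.id))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DegradomeTag:
    """A degradome (PARE) tag: 5' end position of an uncapped mRNA fragment."""

    transcript_id: str
    position: int  # 1-based on the sense strand
    count: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CoordinateError(
                f"degradome tag position is 1-based, got {self.position} "
                f"on {self.transcript_id!r}"
            )
        if self.count < 1:
            raise RefIOError(f"tag count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR threshold-cycle measurement."""

    sample_id: str
    assay_id: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.ct):
            raise RefIOError(f"Ct must be finite, got {self.ct}")
        if self.replicate < 1:
            raise RefIOError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class CountTable:
    """Per-precursor read counts for the four libraries (root/leaf x control/boron).

    ``counts`` is indexed by precursor id with the four library columns.
    ``totals`` are per-library sequencing depths; when ``None`` the counts are
    treated as already normalized (the published count table ships without
    totals). ``lengths`` (nt) are needed only for RPKM normalization.
    """

    counts: pd.DataFrame
    totals: dict[str, int] | None = None
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.counts
        missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
        if missing:
            raise CountTableError(f"missing library columns: {missing}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate precursor ids: {dups}")
        sub = df[list(LIBRARY_COLUMNS)]
        if (sub.values < 0).any():
            bad = df.index[(sub < 0).any(axis=1)].tolist()
            raise CountTableError(f"negative counts for {bad}")
        if self.totals is not None:
            for col in LIBRARY_COLUMNS:
                tot = self.totals.get(col)
                if tot is None or tot < 1:
                    raise CountTableError(f"library total for {col!r} must be >= 1")
                if tot < sub[col].sum():
                    raise CountTableError(
                        f"library total for {col!r} ({tot}) below column sum"
                    )
        if self.lengths is not None and (self.lengths < 1).any():
            raise CountTableError("precursor lengths must be >= 1")

    @property
    def ids(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        same_counts = self.counts.equals(other.counts)
        same_tot = self.totals == other.totals
        if self.lengths is None or other.lengths is None:
            same_len = self.lengths is None and other.lengths is None
        else:
            same_len = self.lengths.equals(other.lengths)
        return same_counts and same_tot and same_len


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Order is preserved, multi-line bodies are concatenated, T is normalized
    to U. Duplicate ids, empty sequences and non-IUPAC characters raise
    named errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# TSV plumbing


def _read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV with optional ``#key: value`` metadata lines."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, val = stripped.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if line.strip():
                body_lines.append(line)
    if not body_lines:
        return pd.DataFrame(), meta
    df = pd.read_csv(_stdio.StringIO("".join(body_lines)), sep="\t", dtype=str)
    return df, meta


def _parse_int(value: str, *, row: str, path: str | Path) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise CountTableError(f"non-numeric count {value!r} in row {row!r} of {path}")
    if f != int(f):
        raise CountTableError(f"non-integer count {value!r} in row {row!r} of {path}")
    return int(f)


def read_counts(path: str | Path) -> CountTable:
    """Read a four-library count table.

    Library totals come from an optional ``#totals: root_control=N ...``
    metadata line; without one the counts are treated as already normalized.
    An optional ``length_nt`` column carries precursor lengths.
    """
    df, meta = _read_tsv(path)
    if df.empty:
        empty = pd.DataFrame(columns=list(LIBRARY_COLUMNS))
        empty.index.name = "precursor_id"
        return CountTable(counts=empty.astype(int))
    if "precursor_id" not in df.columns:
        raise CountTableError(f"{path}: missing 'precursor_id' column")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: missing library columns {missing}")
    out = pd.DataFrame(index=df["precursor_id"].tolist())
    out.index.name = "precursor_id"
    for col in LIBRARY_COLUMNS:
        out[col] = [
            _parse_int(v, row=r, path=path)
            for v, r in zip(df[col], df["precursor_id"])
        ]
    totals = None
    if "totals" in meta:
        totals = {}
        for chunk in meta["totals"].split():
            key, _, val = chunk.partition("=")
            totals[key] = int(val)
    lengths = None
    if "length_nt" in df.columns:
        lengths = pd.Series(
            [_parse_int(v, row=r, path=path) for v, r in zip(df["length_nt"], df["precursor_id"])],
            index=out.index,
            name="length_nt",
        )
    return CountTable(counts=out, totals=totals, lengths=lengths)


def write_counts(table: CountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        if table.totals is not None:
            packed = " ".join(f"{k}={v}" for k, v in table.totals.items())
            fh.write(f"#totals: {packed}\n")
        df = table.counts.copy()
        if table.lengths is not None:
            df["length_nt"] = table.lengths
        df.to_csv(fh, sep="\t", index_label="precursor_id")


def read_degradome(path: str | Path) -> list[DegradomeTag]:
    """Read degradome tags: transcript_id, position (1-based), count."""
    tags: list[DegradomeTag] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "transcript_id":  # header
                continue
            if len(parts) != 3:
                raise MalformedLineError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            try:
                pos, count = int(parts[1]), int(parts[2])
            except ValueError:
                raise MalformedLineError(f"{path}:{lineno}: non-integer position/count")
            tags.append(DegradomeTag(transcript_id=parts[0], position=pos, count=count))
    return tags


def write_degradome(tags: Iterable[DegradomeTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tcount\n")
        for t in tags:
            fh.write(f"{t.transcript_id}\t{t.position}\t{t.count}\n")


def read_ct(path: str | Path) -> list[CtRecord]:
    """Read a Ct table: sample_id, assay_id, replicate, ct."""
    records: list[CtRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "sample_id":
                continue
            if len(parts) != 4:
                raise MalformedLineError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            try:
                rep, ct = int(parts[2]), float(parts[3])
            except ValueError:
                raise MalformedLineError(f"{path}:{lineno}: bad replicate/Ct value")
            records.append(
                CtRecord(sample_id=parts[0], assay_id=parts[1], ct=ct, replicate=rep)
            )
    return records


def write_ct(records: Iterable[CtRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tassay_id\treplicate\tct\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.assay_id}\t{r.replicate}\t{r.ct:g}\n")


def write_report(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    *,
    metadata: Mapping[str, str] | None = None,
) -> list[Path]:
    """Write named report tables as TSV files under ``outdir``.

    Row order is preserved as given (callers sort generated rows by id);
    returns the written paths in name order for determinism.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            for key, val in (metadata or {}).items():
                fh.write(f"#{key}: {val}\n")
            tables[name].to_csv(fh, sep="\t", index=False)
        written.append(path)
    return written
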