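"""Pre-miRNA hairpin folding, MFEI statistics and the seven-point candidate filter.

A plant pre-miRNA candidate is kept when it folds into a single stem-loop
hairpin carrying the mature miRNA on one arm, is at least 60 nt long, matches
the query mature with at most 3 mismatches, has no large break in the
miRNA:miRNA* duplex, and fewer than 6 mismatches against its star sequence.
The minimal folding free energy index, MFEI = AMFE / GC% with
AMFE = (|MFE| / length) x 100, separates miRNA precursors (typically > 0.67)
from tRNA/rRNA/mRNA backgrounds; because published precursor tables retain
rows down to MFEI 0.33, the MFEI criterion is soft by default (it flags
rather than rejects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import _fold
from .refio import SequenceRecord, normalize_rna

__all__ = [
    "HairpinStructure",
    "MatureLocation",
    "CriteriaReport",
    "gc_percent",
    "fold_hairpin",
    "compute_mfei",
    "locate_mature",
    "apply_criteria",
    "arm_fraction",
    "structure_report",
]

MIN_FOLD_LENGTH = 12


def gc_percent(seq: str) -> float:
    """GC content of a sequence as a percentage."""
    if not seq:
        raise ValueError("cannot compute GC% of an empty sequence")
    s = normalize_rna(seq)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class HairpinStructure:
    """A folded precursor: nested pair map plus the derived energy statistics.

    ``pairs`` holds 1-based (i, j) tuples with i < j, outermost first, forming
    a single-hairpin chain. ``mfe`` (kcal/mol, <= 0) is the model energy;
    ``amfe`` and ``mfei`` are recomputable from (mfe, length, gc) to 1e-9.
    """

    seq: str
    pairs: tuple[tuple[int, int], ...]
    mfe: float
    gc: float  # GC%
    length: int  # LP, nt
    amfe: float
    mfei: float

    @property
    def loop_span(self) -> tuple[int, int] | None:
        """1-based inclusive (start, end) of the terminal loop, or None."""
        if not self.pairs:
            return None
        p, q = self.pairs[-1]  # innermost pair
        return (p + 1, q - 1)

    @property
    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


def fold_hairpin(seq: str) -> HairpinStructure:
    """Fold a sequence into its minimum-energy single-hairpin structure.

    Deterministic for a fixed input: among equal-energy structures the one
    with more base pairs wins, then the lexicographically smallest pair list.
    A sequence admitting no structure of energy <= 0 folds to an empty pair
    set with mfe 0.
    """
    s = normalize_rna(seq)
    if len(s) < MIN_FOLD_LENGTH:
        raise ValueError(
            f"sequence too short to fold ({len(s)} nt < {MIN_FOLD_LENGTH})"
        )
    pairs0, mfe = _fold.fold(_fold.encode(s))
    pairs = tuple((i + 1, j + 1) for i, j in pairs0)
    gc = gc_percent(s)
    lp = len(s)
    amfe = abs(mfe) / lp * 100.0
    mfei = amfe / gc if gc > 0 else 0.0
    return HairpinStructure(
        seq=s, pairs=pairs, mfe=mfe, gc=gc, length=lp, amfe=amfe, mfei=mfei
    )


def compute_mfei(mfe: float, lp: int, gc: float) -> tuple[float, float, float]:
    """AMFE, MFEI and the 2-decimal reporting value from (MFE, LP, GC%).

    ``mfei_2dp`` truncates toward zero, matching how published precursor
    tables print the index (0.7191 -> 0.71, 1.3658 -> 1.36; rounding would
    disagree with both).
    """
    if lp < 1:
        raise ValueError(f"precursor length must be >= 1, got {lp}")
    if mfe > 0:
        raise ValueError(f"minimum folding energy must be <= 0, got {mfe}")
    if gc <= 0:
        raise ValueError("MFEI undefined for GC% == 0")
    amfe = abs(mfe) / lp * 100.0
    mfei = amfe / gc
    mfei_2dp = math.floor(mfei * 100.0 + 1e-9) / 100.0
    return amfe, mfei, mfei_2dp


@dataclass(frozen=True)
class MatureLocation:
    """Placement of a mature miRNA on its precursor (1-based inclusive)."""

    precursor_id: str
    start: int
    end: int
    arm: str  # 5p / 3p / loop-overlapping
    mismatches_to_query: int
    star_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def locate_mature(
    structure: HairpinStructure,
    mature: SequenceRecord,
    max_mismatch: int = 3,
    *,
    precursor_id: str = "",
) -> MatureLocation | None:
    """Best ungapped placement of a mature miRNA on a folded precursor.

    Returns None (not-found, not an error) when no placement has at most
    ``max_mismatch`` mismatches. Ties go to the leftmost placement. The arm
    is 5p when the mature ends before the terminal loop, 3p when it starts
    after it, else loop-overlapping; star mismatches count mature positions
    left unpaired by the hairpin (the duplex against the opposite arm).
    """
    m = mature.seq
    if not 19 <= len(m) <= 24:
        raise ValueError(f"mature length must be in [19, 24], got {len(m)}")
    prec = structure.seq
    if len(m) > len(prec):
        return None
    best_off, best_mm = None, max_mismatch + 1
    for off in range(len(prec) - len(m) + 1):
        mm = sum(1 for a, b in zip(m, prec[off : off + len(m)]) if a != b)
        if mm < best_mm:
            best_off, best_mm = off, mm
    if best_off is None or best_mm > max_mismatch:
        return None
    start, end = best_off + 1, best_off + len(m)
    loop = structure.loop_span
    if loop is None:
        arm = "loop-overlapping"
    elif end < loop[0]:
        arm = "5p"
    elif start > loop[1]:
        arm = "3p"
    else:
        arm = "loop-overlapping"
    partner = structure.partner
    star_mm = sum(1 for pos in range(start, end + 1) if pos not in partner)
    return MatureLocation(
        precursor_id=precursor_id,
        start=start,
        end=end,
        arm=arm,
        mismatches_to_query=best_mm,
        star_mismatches=star_mm,
    )


@dataclass(frozen=True)
class CriteriaReport:
    """Outcome of the seven-point precursor filter.

    Criteria: c1 hairpin fold with the mature in a stem; c2 mature on a
    single arm; c3 precursor >= 60 nt; c4 <= 3 mismatches to the query
    mature; c5 MFEI above threshold (soft); c6 no interior break >= 4 nt in
    the mature duplex; c7 < 6 star mismatches. ``overall`` is reject when a
    hard criterion fails, flag when only the MFEI criterion fails, else
    accept.
    """

    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    c7: bool
    overall: str
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, bool | str]:
        d: dict[str, bool | str] = {f"c{i}": getattr(self, f"c{i}") for i in range(1, 8)}
        d["overall"] = self.overall
        return d


def apply_criteria(
    structure: HairpinStructure,
    location: MatureLocation | None,
    *,
    min_lp: int = 60,
    max_mature_mismatch: int = 3,
    mfei_threshold: float = 0.67,
    max_star_mismatch: int = 6,
    max_duplex_break: int = 4,
    mfei: float | None = None,
) -> CriteriaReport:
    """Evaluate the empirical pre-miRNA filter; always returns a report.

    ``mfei`` overrides the structure's own index when the statistic comes
    from an external folding engine (reported tables); all other criteria are
    read off the structure and the mature location.
    """
    reasons: list[str] = []
    partner = structure.partner

    if location is None:
        c1 = c2 = c4 = c6 = c7 = False
        reasons.append("mature miRNA not located on the precursor")
    else:
        mature_paired = any(
            pos in partner for pos in range(location.start, location.end + 1)
        )
        c1 = bool(structure.pairs) and mature_paired
        if not c1:
            reasons.append("no hairpin stem covering the mature miRNA")
        c2 = location.arm in ("5p", "3p")
        if not c2:
            reasons.append("mature overlaps the terminal loop")
        c4 = location.mismatches_to_query <= max_mature_mismatch
        if not c4:
            reasons.append(
                f"{location.mismatches_to_query} mismatches to query "
                f"(> {max_mature_mismatch})"
            )
        # longest run of unpaired positions inside the mature:miRNA* duplex
        longest_break = run = 0
        for pos in range(location.start, location.end + 1):
            run = run + 1 if pos not in partner else 0
            longest_break = max(longest_break, run)
        c6 = longest_break < max_duplex_break
        if not c6:
            reasons.append(
                f"{longest_break}-nt break in the miRNA:miRNA* duplex "
                f"(>= {max_duplex_break})"
            )
        c7 = location.star_mismatches < max_star_mismatch
        if not c7:
            reasons.append(
                f"{location.star_mismatches} star mismatches (>= {max_star_mismatch})"
            )

    c3 = structure.length >= min_lp
    if not c3:
        reasons.append(f"precursor {structure.length} nt (< {min_lp})")
    mfei_val = structure.mfei if mfei is None else mfei
    c5 = mfei_val > mfei_threshold
    if not c5:
        reasons.append(f"MFEI {mfei_val:.2f} <= {mfei_threshold}")

    hard_ok = c1 and c2 and c3 and c4 and c6 and c7
    overall = "reject" if not hard_ok else ("accept" if c5 else "flag")
    return CriteriaReport(
        c1=c1, c2=c2, c3=c3, c4=c4, c5=c5, c6=c6, c7=c7,
        overall=overall, reasons=tuple(reasons),
    )


def arm_fraction(locations: list[MatureLocation]) -> tuple[float, float]:
    """Fraction of matures on the 5p vs 3p arm; the two sum to 1."""
    arms = [loc.arm for loc in locations]
    if any(a not in ("5p", "3p") for a in arms):
        raise ValueError("all locations must be resolved to 5p or 3p")
    if not arms:
        raise ValueError("no locations given")
    n5 = arms.count("5p")
    return n5 / len(arms), (len(arms) - n5) / len(arms)


def structure_report(
    entries: list[tuple[str, SequenceRecord, HairpinStructure, MatureLocation | None]],
) -> pd.DataFrame:
    """Precursor feature table: name, sequence, LM, LP, GC%, dG, AMFE, MFEI, structure."""
    rows = []
    for name, mature, structure, location in entries:
        rows.append(
            {
                "name": name,
                "sequence": mature.seq if mature is not None else "",
                "LM": location.length if location is not None else (len(mature) if mature else 0),
                "LP": structure.length,
                "GC%": round(structure.gc, 1),
                "dG": round(structure.mfe, 2),
                "AMFE": round(structure.amfe, 2),
                "MFEI": math.floor(structure.mfei * 100.0 + 1e-9) / 100.0,
                "structure": structure.dot_bracket(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "sequence", "LM", "LP", "GC%", "dG", "AMFE", "MFEI", "structure"],
    )
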