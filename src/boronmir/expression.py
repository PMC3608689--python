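"""RPKM normalization and boron-response fold-change calling per tissue.

The caller reproduces the published rule exactly: within a tissue, a miRNA
with both normalized counts nonzero is responsive when the ratio of the
larger to the smaller count is at least the threshold (default 2.0; the
comparison is >=, matching the published table's boundary call of 8 -> 16 as
2-fold responsive). The reported fold is the floor of that ratio. One-sided
zeros are not comparable and excluded from the responsive set; double zeros
are not detected. No count-based significance model is applied - the method
is a bare fold-change rule on pooled libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .refio import CountTable, LIBRARY_COLUMNS

__all__ = [
    "ExpressionCall",
    "rpkm",
    "normalize_table",
    "call_expression",
    "call_table",
    "responsive_set",
    "tissue_specificity",
    "call_report",
]

TISSUES = ("root", "leaf")


def rpkm(reads: float, length_nt: int, library_total: int) -> float:
    """Reads per kilobase of precursor per million library reads."""
    if length_nt < 1:
        raise ValueError(f"length must be >= 1 nt, got {length_nt}")
    if library_total < 1:
        raise ValueError(f"library total must be >= 1, got {library_total}")
    return reads * 1e9 / (length_nt * library_total)


def normalize_table(table: CountTable) -> pd.DataFrame:
    """RPKM-normalize a count table; without totals, counts pass through as-is."""
    df = table.counts[list(LIBRARY_COLUMNS)].astype(float)
    if table.totals is None:
        return df
    if table.lengths is None:
        raise ValueError("RPKM normalization requires precursor lengths")
    out = df.copy()
    for col in LIBRARY_COLUMNS:
        out[col] = [
            rpkm(r, int(l), table.totals[col])
            for r, l in zip(df[col], table.lengths)
        ]
    return out


@dataclass(frozen=True)
class ExpressionCall:
    """Per-precursor, per-tissue response call."""

    precursor_id: str
    tissue: str
    control: float
    treated: float
    ratio: float | None
    integer_fold: int | None
    direction: str  # up / down / unchanged / not_detected / not_comparable


def call_expression(
    control: float, treated: float, threshold: float = 2.0
) -> tuple[str, float | None, int | None]:
    """Classify one (control, treated) pair; returns (direction, ratio, fold)."""
    if control < 0 or treated < 0:
        raise ValueError("counts must be non-negative")
    if control == 0 and treated == 0:
        return "not_detected", None, None
    if control == 0 or treated == 0:
        return "not_comparable", None, None
    ratio = max(control, treated) / min(control, treated)
    fold = math.floor(ratio)
    if ratio >= threshold:
        direction = "up" if treated > control else "down"
    else:
        direction = "unchanged"
    return direction, ratio, fold


def call_table(table: CountTable, threshold: float = 2.0) -> list[ExpressionCall]:
    """Expression calls for every precursor in both tissues (root, then leaf)."""
    norm = normalize_table(table)
    calls: list[ExpressionCall] = []
    for pid, row in norm.iterrows():
        for tissue in TISSUES:
            control = float(row[f"{tissue}_control"])
            treated = float(row[f"{tissue}_treated"])
            direction, ratio, fold = call_expression(control, treated, threshold)
            calls.append(
                ExpressionCall(
                    precursor_id=str(pid),
                    tissue=tissue,
                    control=control,
                    treated=treated,
                    ratio=ratio,
                    integer_fold=fold,
                    direction=direction,
                )
            )
    return calls


def responsive_set(table: CountTable, threshold: float = 2.0) -> list[str]:
    """Precursors called up or down in at least one tissue, sorted by id."""
    responsive = {
        c.precursor_id
        for c in call_table(table, threshold)
        if c.direction in ("up", "down")
    }
    return sorted(responsive)


def tissue_specificity(table: CountTable) -> dict[str, str]:
    """root_only / leaf_only / both / neither, by summed detection per tissue."""
    norm = normalize_table(table)
    out: dict[str, str] = {}
    for pid, row in norm.iterrows():
        in_root = row["root_control"] + row["root_treated"] > 0
        in_leaf = row["leaf_control"] + row["leaf_treated"] > 0
        if in_root and in_leaf:
            cat = "both"
        elif in_root:
            cat = "root_only"
        elif in_leaf:
            cat = "leaf_only"
        else:
            cat = "neither"
        out[str(pid)] = cat
    return out


def _fold_label(call: ExpressionCall) -> str:
    if call.direction == "up":
        return f"up {call.integer_fold}-fold"
    if call.direction == "down":
        return f"down {call.integer_fold}-fold"
    if call.direction == "not_detected":
        return "not detected"
    if call.direction == "not_comparable":
        return "not comparable"
    if call.ratio is not None and call.ratio == 1.0:
        return "not changed"
    return "not significantly changed"


def call_report(table: CountTable, threshold: float = 2.0) -> pd.DataFrame:
    """Per-precursor response table mirroring the published layout
    (leaf counts and call, then root counts and call)."""
    calls = call_table(table, threshold)
    by_id: dict[str, dict[str, ExpressionCall]] = {}
    for c in calls:
        by_id.setdefault(c.precursor_id, {})[c.tissue] = c
    rows = []
    for pid in table.ids:
        leaf, root = by_id[pid]["leaf"], by_id[pid]["root"]
        rows.append(
            {
                "precursor_id": pid,
                "leaf_control": leaf.control,
                "leaf_treated": leaf.treated,
                "leaf_call": _fold_label(leaf),
                "root_control": root.control,
                "root_treated": root.treated,
                "root_call": _fold_label(root),
                "responsive": int(
                    leaf.direction in ("up", "down") or root.direction in ("up", "down")
                ),
            }
        )
    return pd.DataFrame(rows)
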