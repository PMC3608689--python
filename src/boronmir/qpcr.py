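"""Stem-loop RT-qPCR quantification: replicate aggregation and 2^-dCt.

Replicate Ct values are aggregated by arithmetic mean (standard dCt
practice). Each assay is normalized against the same sample's reference
assay (default 18S rRNA): dCt = Ct_assay - Ct_reference, relative expression
2^-dCt. Condition-to-condition fold changes are ratios of relative
expressions, algebraically identical to 2^-ddCt. No-RT / no-RNA control rows
pass through as ordinary assays and are never used for normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev

from .refio import CtRecord

__all__ = ["QpcrError", "RelativeExpression", "relative_expression", "condition_fold"]


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class RelativeExpression:
    """Relative expression of one assay in one sample via 2^-dCt.

    ``sd`` is the standard deviation of dCt propagated from the replicate
    scatter of the assay and the reference (0 for single replicates).
    """

    assay_id: str
    sample_id: str
    mean_ct: float
    reference_mean_ct: float
    delta_ct: float
    rel: float
    sd: float


def _sd(values: list[float]) -> float:
    return stdev(values) if len(values) > 1 else 0.0


def relative_expression(
    ct_records: list[CtRecord], reference_assay: str = "18S"
) -> list[RelativeExpression]:
    """Per-sample relative expression of every assay against the reference.

    Every sample must carry the reference assay; a missing reference raises
    :class:`QpcrError`. Output is sorted by (sample, assay); the reference
    assay itself is reported too (rel == 1 by construction).
    """
    by_group: dict[tuple[str, str], list[float]] = {}
    for rec in ct_records:
        by_group.setdefault((rec.sample_id, rec.assay_id), []).append(rec.ct)
    samples = sorted({s for s, _ in by_group})
    out: list[RelativeExpression] = []
    for sample in samples:
        ref_key = (sample, reference_assay)
        if ref_key not in by_group:
            raise QpcrError(
                f"reference assay {reference_assay!r} missing in sample {sample!r}"
            )
        ref_cts = by_group[ref_key]
        ref_mean, ref_sd = mean(ref_cts), _sd(ref_cts)
        for (s, assay) in sorted(by_group):
            if s != sample:
                continue
            cts = by_group[(s, assay)]
            m, s_sd = mean(cts), _sd(cts)
            delta = m - ref_mean
            out.append(
                RelativeExpression(
                    assay_id=assay,
                    sample_id=sample,
                    mean_ct=m,
                    reference_mean_ct=ref_mean,
                    delta_ct=delta,
                    rel=2.0 ** (-delta),
                    sd=math.sqrt(s_sd**2 + ref_sd**2),
                )
            )
    return out


def condition_fold(rel_treated: float, rel_control: float) -> tuple[float, str]:
    """Treated/control ratio of relative expressions with a direction label.

    Equals 2^-ddCt computed from the Ct means directly.
    """
    if rel_treated <= 0 or rel_control <= 0:
        raise QpcrError("relative expressions must be positive")
    fold = rel_treated / rel_control
    if fold > 1:
        label = "induced"
    elif fold < 1:
        label = "inhibited"
    else:
        label = "unchanged"
    return fold, label
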