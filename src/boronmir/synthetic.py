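"""Synthetic data with known ground truth for every pipeline stage.

The study's raw material (sequencing reads, assembly, degradome library) is
not public, so this module generates structurally faithful stand-ins:
hairpin precursors with planted matures, transcripts carrying planted
precursors or complementary target sites, four-library count tables with
planted fold changes under gamma-Poisson (negative-binomial-like) noise,
degradome tags peaked at the true cleavage position, and Ct tables encoding
known relative expressions. Every generator is deterministic given
(parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refio import CountTable, CtRecord, DegradomeTag, SequenceRecord, reverse_complement
from .targets import CLEAVAGE_OPPOSITE

__all__ = [
    "PlantedPrecursor",
    "ExpressionTruth",
    "PlantedSite",
    "GroundTruth",
    "make_precursor",
    "embed_precursor",
    "simulate_libraries",
    "simulate_degradome",
    "simulate_ct",
    "plant_targets",
]

BASES = np.array(list("ACGU"))
DEFAULT_TOTALS = (1_000_000, 1_000_000, 1_000_000, 1_000_000)


@dataclass(frozen=True)
class PlantedPrecursor:
    """Ground truth for one generated hairpin precursor."""

    id: str
    seq: str
    mature_start: int  # 1-based inclusive
    mature_end: int
    arm: str  # 5p or 3p
    mature_seq: str
    loop_start: int
    loop_end: int


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted abundance and per-tissue fold change for one precursor."""

    precursor_id: str
    length: int
    root_abundance: float  # mean control count at 1e6 depth
    leaf_abundance: float
    root_fold: float = 1.0  # >= 1
    leaf_fold: float = 1.0
    root_direction: str = "flat"  # up / down / flat
    leaf_direction: str = "flat"


@dataclass(frozen=True)
class PlantedSite:
    """A planted miRNA target site with its expected penalty class."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    cleavage_pos: int
    penalty_class: str  # zero / low / high
    expected_penalty: float


@dataclass
class GroundTruth:
    """Serializable record of everything a simulation planted."""

    seed: int
    params: dict = field(default_factory=dict)
    precursors: list[PlantedPrecursor] = field(default_factory=list)
    expression: list[ExpressionTruth] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, items in (
            ("precursors", self.precursors),
            ("expression", self.expression),
            ("sites", self.sites),
        ):
            if items:
                pd.DataFrame([asdict(x) for x in items]).to_csv(
                    outdir / f"truth_{name}.tsv", sep="\t", index=False
                )
        manifest = {"seed": self.seed, "params": self.params}
        (outdir / "truth_manifest.json").write_text(json.dumps(manifest, indent=1))


def _sample_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def make_precursor(
    seed: int,
    lp: int = 120,
    mature_len: int = 21,
    arm: str = "5p",
    gc_target: float = 0.5,
    n_wobbles: int = 2,
) -> tuple[SequenceRecord, PlantedPrecursor]:
    """Construct a hairpin precursor with a planted mature miRNA.

    The precursor is a near-perfect stem (left arm, 4-8 nt terminal loop,
    reverse-complemented right arm carrying up to ``n_wobbles`` planted G:U
    wobbles) so it folds into a single hairpin and passes the candidate
    filter. The mature sits at a random offset on the requested arm.
    """
    if not 19 <= mature_len <= 24:
        raise ValueError(f"mature length must be in [19, 24], got {mature_len}")
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    if lp < 2 * mature_len + 8:
        raise ValueError(
            f"lp={lp} too short: need >= 2 * mature_len + 8 = {2 * mature_len + 8}"
        )
    rng = np.random.default_rng(seed)
    loop_len = int(rng.integers(4, 9))
    arm_len = (lp - loop_len) // 2
    loop_len = lp - 2 * arm_len  # absorb rounding so lengths add up exactly
    left = _sample_bases(rng, arm_len, gc_target)
    right = list(reverse_complement(left))
    # plant G:U wobbles: a C on the right arm (pairing a left-arm G) becomes U
    c_positions = [i for i, b in enumerate(right) if b == "C"]
    if c_positions and n_wobbles > 0:
        chosen = rng.choice(
            len(c_positions), size=min(n_wobbles, len(c_positions)), replace=False
        )
        for idx in sorted(chosen):
            right[c_positions[idx]] = "U"
    loop = _sample_bases(rng, loop_len, gc_target)
    seq = left + loop + "".join(right)
    if arm == "5p":
        start = int(rng.integers(1, arm_len - mature_len + 2))
    else:
        start = int(rng.integers(arm_len + loop_len + 1, lp - mature_len + 2))
    end = start + mature_len - 1
    prec_id = f"syn-pre-{seed}"
    record = SequenceRecord(id=prec_id, seq=seq)
    truth = PlantedPrecursor(
        id=prec_id,
        seq=record.seq,
        mature_start=start,
        mature_end=end,
        arm=arm,
        mature_seq=record.seq[start - 1 : end],
        loop_start=arm_len + 1,
        loop_end=arm_len + loop_len,
    )
    return record, truth


def embed_precursor(
    precursor_seq: str,
    transcript_len: int,
    mutation_rate: float,
    seed: int,
    *,
    transcript_id: str = "syn-transcript",
    gc: float = 0.5,
) -> tuple[SequenceRecord, int, int]:
    """Plant a (possibly mutated) precursor copy inside a random transcript.

    Each precursor base mutates to a different base with probability
    ``mutation_rate``. Returns the transcript and the 1-based inclusive
    span of the planted copy.
    """
    if transcript_len < len(precursor_seq):
        raise ValueError("transcript shorter than the precursor")
    rng = np.random.default_rng(seed)
    copy = list(precursor_seq)
    for i in range(len(copy)):
        if rng.random() < mutation_rate:
            alternatives = [b for b in "ACGU" if b != copy[i]]
            copy[i] = alternatives[int(rng.integers(0, 3))]
    slack = transcript_len - len(copy)
    start0 = int(rng.integers(0, slack + 1))
    left = _sample_bases(rng, start0, gc)
    right = _sample_bases(rng, slack - start0, gc)
    seq = left + "".join(copy) + right
    return (
        SequenceRecord(id=transcript_id, seq=seq),
        start0 + 1,
        start0 + len(copy),
    )


def simulate_libraries(
    truth: list[ExpressionTruth],
    totals: tuple[int, int, int, int] = DEFAULT_TOTALS,
    dispersion: float = 0.1,
    seed: int = 0,
) -> CountTable:
    """Draw four-library counts with planted fold changes.

    Counts follow a gamma-Poisson mixture (negative-binomial-like) with the
    given dispersion; mean = abundance x fold-direction factor x depth
    factor (totals of 1e6 give factor 1). ``dispersion == 0`` is the
    noise-free limit: counts equal the rounded means. Zero-abundance entries
    stay zero.
    """
    rng = np.random.default_rng(seed)
    depth = {
        "root_control": totals[0] / 1e6,
        "root_treated": totals[1] / 1e6,
        "leaf_control": totals[2] / 1e6,
        "leaf_treated": totals[3] / 1e6,
    }
    rows = {}
    for t in truth:
        if t.root_fold < 1 or t.leaf_fold < 1:
            raise ValueError("planted folds must be >= 1")
        means = {}
        for tissue in ("root", "leaf"):
            abundance = getattr(t, f"{tissue}_abundance")
            fold = getattr(t, f"{tissue}_fold")
            direction = getattr(t, f"{tissue}_direction")
            treated = abundance
            if direction == "up":
                treated = abundance * fold
            elif direction == "down":
                treated = abundance / fold
            means[f"{tissue}_control"] = abundance * depth[f"{tissue}_control"]
            means[f"{tissue}_treated"] = treated * depth[f"{tissue}_treated"]
        counts = {}
        for col, mu in means.items():
            if mu == 0:
                counts[col] = 0
            elif dispersion == 0:
                counts[col] = int(round(mu))
            else:
                lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
                counts[col] = int(rng.poisson(lam))
        rows[t.precursor_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "precursor_id"
    lengths = pd.Series(
        {t.precursor_id: t.length for t in truth}, name="length_nt"
    ).reindex(df.index)
    return CountTable(counts=df, totals=None, lengths=lengths)


def simulate_degradome(
    sites: list[PlantedSite],
    transcripts: list[SequenceRecord],
    signal_reads: int = 50,
    noise_reads: int = 0,
    seed: int = 0,
) -> list[DegradomeTag]:
    """Degradome tags: ``signal_reads`` at every true cleavage position plus
    ``noise_reads`` single-read tags uniform over each transcript."""
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, int], int] = {}
    lengths = {t.id: len(t.seq) for t in transcripts}
    for site in sites:
        if signal_reads > 0:
            key = (site.transcript_id, site.cleavage_pos)
            counts[key] = counts.get(key, 0) + signal_reads
    for tr in transcripts:
        for _ in range(noise_reads):
            pos = int(rng.integers(1, lengths[tr.id] + 1))
            key = (tr.id, pos)
            counts[key] = counts.get(key, 0) + 1
    return [
        DegradomeTag(transcript_id=tid, position=pos, count=c)
        for (tid, pos), c in sorted(counts.items())
    ]


def simulate_ct(
    rel_truth: dict[tuple[str, str], float],
    sd: float = 0.2,
    seed: int = 0,
    replicates: int = 3,
    reference_assay: str = "18S",
    base_ct: float = 25.0,
) -> list[CtRecord]:
    """Ct tables encoding known relative expressions.

    For each (sample, assay) with true relative expression r the noise-free
    Ct is base_ct - log2(r); the reference assay sits at base_ct, so
    2^-dCt recovers r exactly at sd = 0. Gaussian noise of the given sd is
    added per replicate.
    """
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    samples = sorted({s for s, _ in rel_truth})
    for sample in samples:
        for rep in range(1, replicates + 1):
            noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
            records.append(
                CtRecord(
                    sample_id=sample,
                    assay_id=reference_assay,
                    ct=base_ct + noise,
                    replicate=rep,
                )
            )
        for (s, assay) in sorted(rel_truth):
            if s != sample:
                continue
            r = rel_truth[(s, assay)]
            if r <= 0:
                raise ValueError("relative expressions must be positive")
            true_ct = base_ct - float(np.log2(r))
            for rep in range(1, replicates + 1):
                noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
                records.append(
                    CtRecord(sample_id=sample, assay_id=assay, ct=true_ct + noise, replicate=rep)
                )
    return records


_CLASS_EDITS = {
    # miRNA positions to convert into mismatches, and the resulting penalty
    "zero": ((), 0.0),
    "low": ((16,), 1.0),  # one mismatch outside the seed-proximal region
    "high": ((4, 6), 4.0),  # two seed mismatches, above the default cutoff
}


def plant_targets(
    mirnas: list[SequenceRecord],
    n_transcripts: int,
    penalty_profile: str | list[str] = "zero",
    seed: int = 0,
    transcript_len: int = 300,
    gc: float = 0.5,
) -> tuple[list[SequenceRecord], list[PlantedSite]]:
    """Random transcripts each carrying one planted target site.

    ``penalty_profile`` assigns each transcript a penalty class: ``zero``
    (perfect complement), ``low`` (penalty 1.0, below the default cutoff) or
    ``high`` (penalty 4.0, above it). miRNAs are used round-robin. The true
    cleavage position is the transcript base opposite miRNA position 10.
    """
    if isinstance(penalty_profile, str):
        profile = [penalty_profile] * n_transcripts
    else:
        profile = list(penalty_profile)
        if len(profile) != n_transcripts:
            raise ValueError("penalty_profile length must equal n_transcripts")
    unknown = set(profile) - set(_CLASS_EDITS)
    if unknown:
        raise ValueError(f"unknown penalty classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    transcripts: list[SequenceRecord] = []
    sites: list[PlantedSite] = []
    for idx in range(n_transcripts):
        mir = mirnas[idx % len(mirnas)]
        L = len(mir.seq)
        site = list(reverse_complement(mir.seq))
        positions, expected = _CLASS_EDITS[profile[idx]]
        for p in positions:
            # the transcript base opposite miRNA position p; setting it equal
            # to the miRNA base guarantees a mismatch (never a G:U wobble)
            site[L - p] = mir.seq[p - 1]
        background = _sample_bases(rng, transcript_len, gc)
        start0 = int(rng.integers(20, transcript_len - L - 20))
        seq = background[:start0] + "".join(site) + background[start0 + L :]
        tid = f"syn-tr-{idx}"
        transcripts.append(SequenceRecord(id=tid, seq=seq))
        site_start = start0 + 1
        sites.append(
            PlantedSite(
                mirna_id=mir.id,
                transcript_id=tid,
                site_start=site_start,
                site_end=site_start + L - 1,
                cleavage_pos=site_start + L - CLEAVAGE_OPPOSITE,
                penalty_class=profile[idx],
                expected_penalty=expected,
            )
        )
    return transcripts, sites
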