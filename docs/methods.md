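# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make every run reproducible.

## Sequence and coordinate conventions

All sequences are RNA over {A, C, G, U}; DNA input is normalized (T → U,
upper-cased) on read and never converted back. Every position that crosses a
module boundary is 1-based inclusive; `refio.to_zero_based` /
`to_one_based` are the only conversion points. Count, degradome, Ct and
report tables are TSV with `#key: value` metadata lines.

## Hairpin folding energy model

The folding engine is a deliberately simple nested dynamic program over
single-hairpin topologies, not a Turner-parameter implementation. The
structure is a chain of pairs (canonical A:U/G:C plus G:U wobble) around one
terminal loop of ≥ 3 nt. Energies (kcal/mol-scaled, all binary fractions so
floating-point comparisons are exact):

| term | value |
|---|---|
| stack, G:C on G:C | −2.0 |
| stack, mixed G:C/A:U | −1.5 |
| stack, A:U on A:U | −1.0 |
| stack involving G:U | −0.5 |
| hairpin-loop initiation | +4.0 |
| per unpaired loop nt beyond 3 | +0.5 |
| per interior/bulge nt between consecutive pairs | +1.0 |

Interior loops between consecutive pairs are capped at 12 unpaired
nucleotides total — larger breaks are modelled as "no structure" rather
than a continued helix, which matches how candidate hairpins are judged
(criterion: no large break in the duplex). Determinism: among equal-energy
structures the one with more pairs wins, then the lexicographically
smallest pair list; the test suite verifies the DP against a brute-force
enumeration of every admissible chain, tie-breaks included.

Because this model is an approximation, computed ΔG values do **not**
reproduce the ΔG column of the bundled precursor table (which came from a
Turner-rule folder). The MFEI statistic is therefore decoupled from the
folding engine: `compute_mfei(mfe, lp, gc)` accepts any energy source, and
the published-table checks feed each row's own printed ΔG back through the
formula. MFEI values are reported truncated toward zero at two decimals
(0.7191 → 0.71, 1.3658 → 1.36): truncation, not rounding, reproduces the
published cells. One bundled row (hvu-mir-397, printed MFEI 0.98) is
internally inconsistent with its own (ΔG, L_P, GC%) triple, which computes
to 0.84 (a GC% of 57 instead of the printed 67 would explain it); the
fixture flags that row and the tests assert the discrepancy rather than
hiding it.

## Candidate filter

Seven criteria, mirroring standard plant-miRNA annotation practice:
single-hairpin fold with the mature in a stem; mature on one arm; precursor
≥ 60 nt; ≤ 3 mismatches between candidate and query mature; MFEI > 0.67;
no interior break ≥ 4 nt within the mature:miRNA\* duplex (the "no large
loop or break" rule, quantified here since no number is standard); and < 6
star mismatches, counted as mature positions left unpaired by the hairpin.
The MFEI criterion is **soft** (flag, not reject) because published
precursor sets retain entries down to MFEI 0.33; the threshold and all
other limits are configurable (`PipelineConfig`). The filter is monotone:
worsening any single quantity can never flip a criterion from fail to pass.

## Homology screen

An in-repo seed-and-extend aligner replaces an external BLASTN binary:
exact 11-mer seeds, diagonal grouping, banded (±8) local alignment with
match +1 / mismatch −2 / gap −2.5, both strands searched (whether the
original screen searched both strands is unrecorded; the strand is flagged
in output). Significance uses E = K·m·N·exp(−λS) with λ = 1.9, K = 0.35.
These are *calibrated proxy constants*, not Karlin–Altschul parameters for
this scoring system (those would be λ ≈ 1.34, under which no alignment of
pre-miRNA length reaches 1e-10 in a megabase database); they are chosen so
an exact match of ≥ 24 nt in 1 Mb clears the 1e-10 cutoff, preserving the
intended selectivity of the original screen. Hits are additionally filtered
at ≥ 85% identity. Measured on planted precursors: recall 100% at mutation
rate 0 and ≥ 95% at 10%, with ≤ 5% hits on composition-matched shuffled
decoys (200 trials each in the test suite).

## Expression calling

RPKM = reads × 10⁹ / (length_nt × library_total). The bundled count table
ships already normalized (no `#totals` line), so its values pass through
unchanged. Response rule per tissue: both counts nonzero and
max/min ≥ threshold (default 2.0). The comparison is ≥, not >, because the
published boundary case (8 → 16, ratio exactly 2) is called responsive.
Reported fold = ⌊max/min⌋. One-sided zeros are "not comparable" and
excluded from the responsive set; double zeros are "not detected". No
dispersion estimation or multiple-testing correction is applied — the
method is a bare fold-change rule on pooled libraries, and adding a
significance model would change which miRNAs it selects. Consequence,
quantified in the tests: at a planted fold exactly at the threshold under
negative-binomial noise (dispersion 0.1), about half the draws fall below
threshold and are called unchanged; the *direction* of change is what the
rule preserves (≥ 95% direction recovery across planted folds {2, 4, 8},
500 seeds).

## Target prediction and degradome validation

Duplex scoring: mismatch 1.0, G:U 0.5, gap 2.0, doubled at miRNA positions
2–13, site cutoff 3.0, at most 3 gap columns (window length within miRNA
length ± 3). The literature names this scheme without printing the numbers,
so the weights are configurable defaults. Scanning uses a vectorized
gapless pass over every register, with gapped refinement of any register
within two gap-weights of the cutoff; a site that *requires* gaps to score
and has no gapless register near the cutoff is not recovered (known
limitation — planted and validated sites in this pipeline are ungapped).
Cleavage is reported as the transcript coordinate opposite miRNA position
10 (slicing occurs between positions 10 and 11; published integer cleavage
sites cannot disambiguate the convention, so it is fixed and documented).
A gap at position 10 yields "undetermined".

T-plot categories follow the CleaveLand family: site count = tags within
cleavage ± 1; category 0 = equals a unique transcript-wide maximum, 1 =
tied maximum, 2 = above the median of nonzero positions, 3 = at or below
the median but > 1 read, 4 = exactly 1 read; unsupported sites are
rejected. Categories 3–4 are defined by absolute read counts, so only
categories 0–2 are invariant to uniform scaling of the tag counts.

## qPCR

Replicate Cts aggregate by arithmetic mean (the standard ΔCt convention;
geometric aggregation of 2^−Ct would differ only at high replicate
scatter). ΔCt is taken against the same sample's reference assay, rel =
2^−ΔCt, and condition folds are ratios of rels — algebraically 2^−ΔΔCt.
The reported `sd` is the replicate ΔCt standard deviation propagated from
assay and reference. Both ΔCt-level and ΔΔCt-level outputs are exposed,
since per-panel conventions vary. No amplification-efficiency correction.

## Synthetic data

The generator emulates the *structure* of the study's inputs, with defaults
matching its stated conditions: precursors 60–360 nt with 19–24-nt matures
(built as a near-perfect stem with a 4–8 nt loop and up to 2 planted G:U
wobbles, so every planted hairpin passes the filter); four libraries at
10⁶ reads each so raw counts sit on the published normalized scale; count
noise gamma-Poisson with dispersion 0.1 (the study pooled replicates and
reports single counts, so the noise model is a documented stand-in, with
dispersion 0 giving the rounded-mean limit); degradome signal of 50 reads
at the true cleavage position over uniform single-read noise; Ct tables
encoding rel as Ct = 25 − log₂(rel) against a reference at Ct 25. Every
generator is bit-reproducible from (parameters, seed).

What the generator does **not** emulate: sequencing-read-level error and
adapter artifacts, assembly fragmentation and chimerism, multi-hairpin or
pseudoknotted precursors, expression correlation between miRNA family
members, and degradome background that tracks transcript abundance.
Passing the planted-truth suites therefore demonstrates the correctness of
the algorithms under the stated noise models, not performance on raw
sequencing data.

## Problem sizes in the test suite

The suites use sizes chosen to make the statistical assertions stable while
keeping a full run around a few seconds: 200 random 14–22-nt sequences for
the folding oracle (exhaustive enumeration is exact at these lengths), 200
planted-precursor transcripts of 400 nt for homology recall, 500 seeded
count tables for direction recovery, 20 transcripts of 300 nt for exact
cleavage recovery, and 100 replicates for degradome category recovery.

## Known limitations

* Folding energies are model units, comparable within this package only.
* The e-value proxy orders hits sensibly but is not calibrated probability.
* Gapped target sites without a near-cutoff gapless register are missed.
* The fold-change caller has no error model; boundary folds are detected
  with ~50% probability by construction.
* Merged precursor ids (e.g. "hvu-miR156a/miR156b/miR156r") are treated as
  single opaque row keys, as in the bundled tables.
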