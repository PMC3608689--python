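"""Target-site scoring, cleavage coordinates, degradome validation."""

import pytest

from boronmir.refio import DegradomeTag, SequenceRecord, reverse_complement
from boronmir.synthetic import plant_targets, simulate_degradome
from boronmir.targets import (
    TargetAlignment,
    cleavage_position,
    degradome_validate,
    scan_transcripts,
    score_site,
)

from _oracles import best_duplex_bruteforce

MIR = "UGACAGAAGAGAGAGAGCACA"  # 21 nt


def test_perfect_site_scores_zero():
    mir = SequenceRecord(id="m", seq=MIR)
    aln = score_site(mir, reverse_complement(MIR))
    assert aln.penalty == 0.0
    assert all(s == "match" for s in aln.states)


def test_wobble_weights_depend_on_seed_region():
    """A G:U wobble costs 0.5 outside the seed-proximal region but 1.0 inside."""
    seq = "AUCGGAAUCGAUCGAUCAUGA"  # G at positions 5 and 20
    mir = SequenceRecord(id="m", seq=seq)
    L = len(seq)
    for pos, expected in [(20, 0.5), (5, 1.0)]:
        assert seq[pos - 1] == "G"
        w = list(reverse_complement(seq))
        w[L - pos] = "U"  # miRNA position pos faces window index L - pos
        aln = score_site(mir, "".join(w))
        assert aln.penalty == expected
        assert aln.states[pos - 1] == "gu"


def test_duplex_penalty_matches_bruteforce(rng):
    """Optimal banded duplex penalty equals exhaustive path enumeration
    (random 21-nt miRNA vs windows of length 18..24, 60 trials)."""
    for trial in range(60):
        mir = "".join(rng.choice(list("ACGU"), size=21))
        w_len = int(rng.integers(18, 25))
        window = "".join(rng.choice(list("ACGU"), size=w_len))
        aln = score_site(SequenceRecord(id="m", seq=mir), window)
        assert aln.penalty == best_duplex_bruteforce(mir, window)


def test_score_site_window_length_guard():
    mir = SequenceRecord(id="m", seq=MIR)
    with pytest.raises(ValueError):
        score_site(mir, "ACGU" * 8)  # 32 nt, outside L +/- 3


def test_cleavage_position_formula():
    """Ungapped 21-nt site at s..s+20: cleavage opposite miRNA position 10
    is s + 11 (site 769..789 -> 780; site 1..21 -> 12)."""
    mir = SequenceRecord(id="m", seq=MIR)
    aln = score_site(mir, reverse_complement(MIR), transcript_id="t", site_start=769)
    assert (aln.site_start, aln.site_end) == (769, 789)
    assert cleavage_position(aln) == 780
    aln1 = score_site(mir, reverse_complement(MIR), transcript_id="t", site_start=1)
    assert cleavage_position(aln1) == 12


def test_gap_at_position_ten_is_undetermined():
    aln = TargetAlignment(
        mirna_id="m", transcript_id="t", site_start=1, site_end=20,
        states=tuple(["match"] * 9 + ["gap_t"] + ["match"] * 11),
        t_positions=tuple(list(range(20, 11, -1)) + [None] + list(range(11, 0, -1))),
        gap_m_positions=(), penalty=4.0,
    )
    assert cleavage_position(aln) is None


def test_scan_finds_planted_perfect_site_and_excludes_seed_mismatches():
    mirs = [SequenceRecord(id="m", seq=MIR)]
    transcripts, sites = plant_targets(mirs, 4, ["zero", "high", "zero", "low"], seed=9)
    alignments = scan_transcripts(mirs, transcripts)
    found = {a.transcript_id: a for a in alignments}
    for site in sites:
        if site.penalty_class == "high":  # penalty 4.0 > default cutoff 3.0
            assert site.transcript_id not in found
        else:
            aln = found[site.transcript_id]
            assert (aln.site_start, aln.site_end) == (site.site_start, site.site_end)
            assert aln.penalty == site.expected_penalty


def test_degradome_categories():
    mir = SequenceRecord(id="m", seq=MIR)
    aln = score_site(mir, reverse_complement(MIR), transcript_id="t", site_start=40)
    cleavage = cleavage_position(aln)

    def tag(pos, count, tid="t"):
        return DegradomeTag(transcript_id=tid, position=pos, count=count)

    # unique transcript-wide maximum at the cleavage site -> category 0
    t0 = degradome_validate(aln, [tag(cleavage, 50), tag(5, 5), tag(90, 3)])
    assert t0.category == 0 and t0.site_count == 50
    # tied maximum -> category 1
    t1 = degradome_validate(aln, [tag(cleavage, 50), tag(5, 50)])
    assert t1.category == 1
    # above the median of nonzero positions, below max -> category 2
    t2 = degradome_validate(
        aln, [tag(cleavage, 10), tag(5, 50), tag(7, 2), tag(90, 2)]
    )
    assert t2.category == 2
    # single read -> category 4
    t4 = degradome_validate(aln, [tag(cleavage, 1), tag(5, 50), tag(7, 8)])
    assert t4.category == 4
    # no tags at the site -> rejected
    assert degradome_validate(aln, [tag(5, 50)]) is None


def test_degradome_category_scale_invariance():
    """Categories 0-2 are invariant to uniform scaling of all tag counts
    (categories 3-4 are defined by absolute read counts)."""
    mir = SequenceRecord(id="m", seq=MIR)
    aln = score_site(mir, reverse_complement(MIR), transcript_id="t", site_start=40)
    cleavage = cleavage_position(aln)
    base = [
        DegradomeTag("t", cleavage, 10),
        DegradomeTag("t", 5, 50),
        DegradomeTag("t", 7, 2),
        DegradomeTag("t", 90, 2),
    ]
    for scale in (1, 3, 10):
        scaled = [
            DegradomeTag(t.transcript_id, t.position, t.count * scale) for t in base
        ]
        assert degradome_validate(aln, scaled).category == 2


def test_planted_signal_recovers_top_category():
    """With 10:1 signal:noise, planted sites score category <= 1 in >= 95%
    of 100 replicates."""
    mirs = [SequenceRecord(id="m", seq=MIR)]
    good = 0
    n = 100
    for i in range(n):
        transcripts, sites = plant_targets(mirs, 1, "zero", seed=70_000 + i)
        tags = simulate_degradome(
            sites, transcripts, signal_reads=50, noise_reads=5, seed=80_000 + i
        )
        (aln,) = scan_transcripts(mirs, transcripts)
        tplot = degradome_validate(aln, tags)
        if tplot is not None and tplot.category <= 1:
            good += 1
    assert good / n >= 0.95
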