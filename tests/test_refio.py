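"""IO layer: FASTA/TSV readers and writers, validation, round-trips."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boronmir.refio import (
    AlphabetError,
    CoordinateError,
    CountTable,
    CountTableError,
    CtRecord,
    DegradomeTag,
    DuplicateIdError,
    MalformedLineError,
    SequenceRecord,
    read_counts,
    read_ct,
    read_degradome,
    read_fasta,
    reverse_complement,
    to_one_based,
    to_zero_based,
    write_counts,
    write_ct,
    write_degradome,
)


def test_read_fasta_normalizes_and_preserves_order(tmp_path):
    p = tmp_path / "x.fasta"
    p.write_text(">a\nACGT\n>b desc here\nGG\nCC\n")
    records = read_fasta(p)
    assert [r.id for r in records] == ["a", "b"]
    assert records[0].seq == "ACGU"  # T -> U
    assert records[1].seq == "GGCC"  # multi-line concatenated
    assert records[1].description == "b desc here"


def test_read_fasta_named_errors(tmp_path):
    dup = tmp_path / "dup.fasta"
    dup.write_text(">a\nACGU\n>a\nGGCC\n")
    with pytest.raises(DuplicateIdError):
        read_fasta(dup)
    bad = tmp_path / "bad.fasta"
    bad.write_text(">a\nACXU\n")
    with pytest.raises(AlphabetError, match="a"):
        read_fasta(bad)


def test_sequence_record_rejects_empty():
    with pytest.raises(ValueError):
        SequenceRecord(id="x", seq="")


def test_reverse_complement_is_involution():
    s = "AUGGCUAGC"
    assert reverse_complement(reverse_complement(s)) == s
    assert reverse_complement("GAUC") == "GAUC"


def test_coordinate_helpers_are_inverse_and_guarded():
    assert to_zero_based(1) == 0
    assert to_one_based(0) == 1
    with pytest.raises(CoordinateError):
        to_zero_based(0)


def test_read_counts_published_style(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text(
        "precursor_id\troot_control\troot_treated\tleaf_control\tleaf_treated\n"
        "hvu-miR408\t0\t0\t130\t8\n"
    )
    table = read_counts(p)
    row = table.counts.loc["hvu-miR408"]
    assert (row["root_control"], row["root_treated"]) == (0, 0)
    assert (row["leaf_control"], row["leaf_treated"]) == (130, 8)
    assert table.totals is None  # already-normalized mode


def test_read_counts_totals_line_and_errors(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text(
        "#totals: root_control=1000 root_treated=1000 leaf_control=1000 leaf_treated=1000\n"
        "precursor_id\troot_control\troot_treated\tleaf_control\tleaf_treated\tlength_nt\n"
        "a\t10\t20\t5\t5\t100\n"
    )
    table = read_counts(p)
    assert table.totals["root_control"] == 1000
    assert int(table.lengths["a"]) == 100

    neg = tmp_path / "neg.tsv"
    neg.write_text(
        "precursor_id\troot_control\troot_treated\tleaf_control\tleaf_treated\n"
        "a\t-3\t0\t0\t0\n"
    )
    with pytest.raises(CountTableError, match="a"):
        read_counts(neg)


def test_read_counts_empty_body_is_valid(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("# nothing here\n")
    assert len(read_counts(p)) == 0


def test_degradome_coordinate_and_line_errors(tmp_path):
    with pytest.raises(CoordinateError):
        DegradomeTag(transcript_id="t", position=0, count=3)
    p = tmp_path / "d.tsv"
    p.write_text("transcript_id\tposition\tcount\nt1\t5\n")
    with pytest.raises(MalformedLineError, match="2"):
        read_degradome(p)


def test_ct_record_validation():
    with pytest.raises(ValueError):
        CtRecord(sample_id="s", assay_id="a", ct=float("nan"))
    with pytest.raises(ValueError):
        CtRecord(sample_id="s", assay_id="a", ct=25.0, replicate=0)


ids = st.lists(
    st.text(alphabet="abcdefgh123", min_size=1, max_size=8),
    min_size=0, max_size=6, unique=True,
)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(ids=ids, data=st.data())
def test_count_table_roundtrip(tmp_path_factory, ids, data):
    """read(write(x)) == x for arbitrary valid count tables."""
    counts = pd.DataFrame(
        {
            col: [data.draw(st.integers(0, 10_000)) for _ in ids]
            for col in ("root_control", "root_treated", "leaf_control", "leaf_treated")
        },
        index=pd.Index(ids, name="precursor_id"),
    ).astype(int)
    table = CountTable(counts=counts)
    path = tmp_path_factory.mktemp("rt") / "c.tsv"
    write_counts(table, path)
    assert read_counts(path) == table


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    tags=st.lists(
        st.tuples(
            st.sampled_from(["t1", "t2", "t3"]),
            st.integers(1, 500),
            st.integers(1, 1000),
        ),
        max_size=10,
    )
)
def test_degradome_roundtrip(tmp_path_factory, tags):
    records = [DegradomeTag(*t) for t in tags]
    path = tmp_path_factory.mktemp("rt") / "d.tsv"
    write_degradome(records, path)
    assert read_degradome(path) == records


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    rows=st.lists(
        st.tuples(
            st.sampled_from(["root+B", "leaf-B"]),
            st.sampled_from(["miR156", "18S"]),
            st.integers(10, 40),
            st.integers(1, 3),
        ),
        max_size=9,
    )
)
def test_ct_roundtrip(tmp_path_factory, rows):
    records = [CtRecord(s, a, float(ct), rep) for s, a, ct, rep in rows]
    path = tmp_path_factory.mktemp("rt") / "ct.tsv"
    write_ct(records, path)
    assert read_ct(path) == records
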