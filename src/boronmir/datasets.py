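"""Bundled reference tables from the barley boron-stress study.

Three small TSV fixtures ship with the package: the published precursor
feature table (mature sequence, LM, LP, MFEI, GC%, dG), the four-library
normalized count table (42 precursors), and the per-tissue response calls
for the 25 boron-responsive miRNAs, plus the name map linking count-table
ids to response-table labels.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .refio import CountTable, read_counts

__all__ = [
    "hairpin_features",
    "normalized_counts",
    "expected_calls",
    "name_map",
]


def _data(name: str):
    return files("boronmir.data").joinpath(name)


def hairpin_features() -> pd.DataFrame:
    """Published precursor features (35 rows)."""
    with _data("table1_hairpin_features.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def normalized_counts() -> CountTable:
    """Published normalized count table (42 precursors, four libraries)."""
    return read_counts(str(_data("table2_normalized_counts.tsv")))


def expected_calls() -> pd.DataFrame:
    """Published per-tissue response calls for the 25 responsive miRNAs."""
    with _data("table3_expected_calls.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def name_map() -> pd.DataFrame:
    """Count-table id -> response-table label map (one inferred entry)."""
    with _data("table2_to_table3_names.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
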