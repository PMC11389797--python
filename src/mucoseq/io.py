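"""Readers/writers for the package's plain-text formats.

Count matrices are TSV (gene_id row index, sample IDs as header), sample
designs CSV (sample_id index), measurement tables long-format CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import LONG_COLUMNS


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, index_label="sample_id")


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    table[LONG_COLUMNS].to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    table["probe"] = table["probe"].fillna("")
    return table
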