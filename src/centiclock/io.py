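"""Readers and writers for the package's plain-text formats.

Beta matrices are TSV with a leading ``cpg_id`` column and one column per
sample; sample sheets are CSV; annotations are BED-like TSV with 0-based
half-open coordinates.  Floats are written with ``%.10g`` so a rerun with
the same seed produces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_beta(beta: pd.DataFrame, path) -> None:
    beta = beta.copy()
    beta.index.name = "cpg_id"
    beta.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_beta(path) -> pd.DataFrame:
    beta = pd.read_csv(path, sep="\t", index_col="cpg_id")
    return beta


def write_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path, sep="\t") -> None:
    table.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def read_table(path, sep="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
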