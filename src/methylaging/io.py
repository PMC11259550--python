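"""Readers and writers for the plain-text tabular formats.

Beta and expression matrices travel as TSV with features in rows (index
column ``probe_id``/``gene_id``) and a header row of sample ids; sample
metadata, probe annotation, and result tables travel as CSV.  Writers use
a fixed float format so reruns with identical seeds are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.8g"


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_beta_tsv(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


read_expression_tsv = read_beta_tsv
write_expression_tsv = write_beta_tsv


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, index_col=0)
    required = {"chromosome", "position", "island_class", "feature_class"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"probe annotation missing columns: {sorted(missing)}")
    return annot


def read_reference_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0).astype(float)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT, index=index)


def read_clock_coefficients(path: str | Path) -> tuple[float, dict[str, float]]:
    """Read a published-clock coefficient CSV (columns: probe, coefficient).

    A row whose probe field is ``intercept`` (case-insensitive) supplies
    the intercept; default 0.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    probe_col = cols.get("probe", df.columns[0])
    coef_col = cols.get("coefficient", df.columns[1])
    intercept = 0.0
    weights: dict[str, float] = {}
    for _, row in df.iterrows():
        pid = str(row[probe_col])
        if pid.lower() == "intercept":
            intercept = float(row[coef_col])
        else:
            weights[pid] = float(row[coef_col])
    return intercept, weights
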