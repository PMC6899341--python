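"""Tab-separated matrix and covariate table I/O.

Count matrices follow the common convention: first column is the feature
identifier (gene symbol, Ensembl ID or ``gene|repeat`` key), remaining
columns are per-sample integer counts.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["read_count_matrix", "write_count_matrix", "read_covariates"]


def read_count_matrix(path) -> pd.DataFrame:
    """Read a feature x sample count matrix; validates non-negative integers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    try:
        df = df.astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: counts must be integers ({exc})") from None
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: counts must be non-negative")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate feature ids, e.g. {dupes}")
    return df


def write_count_matrix(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_covariates(path) -> pd.DataFrame:
    """Read a sample x covariate table (first column: sample name)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: covariate table has missing cells")
    return df
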