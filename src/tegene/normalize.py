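"""Filtering, TMM scaling factors and log2-CPM transformation.

The merged gene+TE count matrix is filtered on row totals, scaled between
samples with the trimmed mean of M-values (TMM) method, and transformed to
log2 counts-per-million for linear modelling.  Only the log2-CPM transform
is applied — no observation-level precision weights — because the downstream
models are plain unweighted least squares on logCPM.

TMM, briefly: pick a reference sample whose upper-quartile count fraction is
closest to the average; for each sample compute gene-wise log ratios (M) and
average log abundances (A) against the reference over features positive in
both; doubly trim (30% of M on each tail, 5% of A), and average the
surviving M values weighted by inverse asymptotic (delta-method binomial)
variances.  The 2^weighted-mean is the scaling factor; factors are rescaled
to geometric mean one so they only redistribute library size.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = ["filter_low_counts", "tmm_factors", "log_cpm", "normalize_counts"]


def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop features whose total count across all samples is below ``min_total``.

    The boundary is inclusive: a row summing to exactly ``min_total`` is kept.

    Raises
    ------
    ValueError
        If no feature survives.
    """
    keep = counts.sum(axis=1) >= min_total
    out = counts.loc[keep]
    if out.shape[0] == 0:
        raise ValueError(
            f"no feature has a total count >= {min_total}; check the input matrix"
        )
    return out


def _tmm_pair_log2(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
    a_cutoff: float,
) -> float:
    """log2 TMM factor of one sample against the reference column."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        warnings.warn("sample shares no positive feature with the TMM reference; factor set to 1")
        return 0.0
    o, r = obs[mask], ref[mask]
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    ok = a > a_cutoff
    m, a, v = m[ok], a[ok], v[ok]
    if m.size == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 0.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * m[keep]) / np.sum(w))
    return f if np.isfinite(f) else 0.0


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference sample is the column whose 75th-percentile count fraction
    (count / library size) is closest to the mean of those quantiles across
    samples.  Returned factors have geometric mean 1 (within floating point).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive library size")
    f75 = np.array([np.quantile(y[:, k] / lib[k], 0.75) for k in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log.debug("TMM reference sample: %s", counts.columns[ref])
    logf = np.array(
        [
            _tmm_pair_log2(y[:, k], y[:, ref], lib[k], lib[ref], logratio_trim, abs_trim, a_cutoff)
            for k in range(y.shape[1])
        ]
    )
    logf -= logf.mean()  # geometric mean 1
    return pd.Series(2.0**logf, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count and effective library sizes.

    value[g, s] = log2( (count[g, s] + prior) / (lib_size[s] * factor[s] + 1) * 1e6 )

    ``lib_size`` is the column sum of ``counts`` (compute on the filtered
    matrix that enters modelling); ``factors`` default to 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        f = pd.Series(1.0, index=counts.columns)
    else:
        f = factors.reindex(counts.columns)
        if f.isna().any() or (f <= 0).any():
            raise ValueError("factors must be positive and cover every sample")
    eff = lib * f + 1.0
    vals = np.log2((counts.to_numpy(dtype=float) + prior) / eff.to_numpy() * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def normalize_counts(
    counts: pd.DataFrame,
    min_total: int = 10,
    prior: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """filter -> TMM -> log2-CPM pipeline on a merged count matrix.

    Returns (logcpm, tmm_factors); both are computed on the filtered matrix.
    """
    filtered = filter_low_counts(counts, min_total=min_total)
    factors = tmm_factors(filtered)
    return log_cpm(filtered, factors, prior=prior), factors
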