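"""Per-gene linear models of gene expression on upstream-TE expression.

For each gene *i* with at least one linked TE term, the model is

    y_i = b0 + b1*TE_1i + ... + bn*TE_ni + bm*Cov_mi + e_i,   e_i ~ N(0, s^2)

where y_i and the TE_ki are normalized log2-CPM values across samples and
the Cov_m are user covariates (tissue type, patient, age, ...).  Fits are
ordinary least squares; each model reports per-term t tests, R², adjusted
R², and the overall F test with (p, n-p-1) degrees of freedom.

The default covariate encoding is ``numeric`` — one design column per
covariate, with categorical levels coded as integers in first-appearance
order.  ``onehot`` (reference level dropped) is statistically preferable
for unordered categories and is available; with numeric encoding a model
with one TE term and two covariates has p = 3 predictor columns.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .normalize import normalize_counts
from .proximity import TE_KEY_SEP, TEGeneLink

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "GeneFitResult",
    "TEAssociationModel",
    "TEAssociationResults",
    "build_design",
    "fit_gene_lm",
    "run_all_models",
    "write_outputs",
    "adjusted_r_squared",
    "model_f_test",
]

INTERCEPT = "Intercept"


def adjusted_r_squared(r_squared: float, n: int, p: int) -> float:
    """Model-size-penalized R²: 1 - (1-R²)(n-1)/(n-p-1)."""
    return 1.0 - (1.0 - r_squared) * (n - 1) / (n - p - 1)


def model_f_test(r_squared: float, n: int, p: int) -> tuple[float, float]:
    """Overall F statistic and its upper-tail p for a model with p predictors.

    F = (R²/p) / ((1-R²)/(n-p-1)), referred to F(p, n-p-1).
    """
    from scipy import stats

    f = (r_squared / p) / ((1.0 - r_squared) / (n - p - 1))
    return float(f), float(stats.f.sf(f, p, n - p - 1))


@dataclass(frozen=True)
class ModelSpec:
    """Design description for one gene's model."""

    gene_id: str
    te_terms: tuple[str, ...]
    covariate_terms: tuple[str, ...]
    n: int
    p: int


@dataclass
class GeneFitResult:
    """OLS fit of one gene: estimates, per-term tests and model-level stats."""

    gene_id: str
    n: int
    p: int
    terms: pd.DataFrame  # index: term; columns: estimate, se, t, p
    sigma2_hat: float
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    model_p: float
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    aliased: tuple[str, ...] = ()


def _encode_covariates(covariates: pd.DataFrame, encoding: str) -> pd.DataFrame:
    """Turn a covariate table into numeric design columns."""
    if encoding not in ("numeric", "onehot"):
        raise ValueError(f"encoding must be 'numeric' or 'onehot', got {encoding!r}")
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
        elif encoding == "numeric":
            # integer codes in first-appearance order
            levels = {v: i for i, v in enumerate(pd.unique(col))}
            cols[name] = col.map(levels).astype(float)
        else:
            levels = list(pd.unique(col))
            for level in levels[1:]:  # first level is the reference
                cols[f"{name}[{level}]"] = (col == level).astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def _find_aliased(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Greedy scan for columns that add no rank (aliased/collinear)."""
    aliased = []
    kept: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(j)
            rank = r
        else:
            aliased.append(names[j])
    return aliased


def build_design(
    spec: ModelSpec,
    te_logcpm: pd.DataFrame,
    covariates: pd.DataFrame | None,
    encoding: str = "numeric",
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the n x (p+1) design matrix for one gene.

    Column 0 is the intercept; TE columns carry the linked TE logCPM rows
    (named by repeat subfamily); covariates follow, encoded per ``encoding``.
    Sample order is taken from ``te_logcpm`` columns; the covariate table
    must cover the same samples.

    Returns (design, aliased) where ``aliased`` names columns that are
    linearly dependent on earlier ones (flagged, not yet dropped).
    """
    samples = list(te_logcpm.columns)
    blocks = [pd.Series(1.0, index=samples, name=INTERCEPT)]
    for gene_te_key, term in zip(
        [f"{spec.gene_id}{TE_KEY_SEP}{t}" for t in spec.te_terms], spec.te_terms
    ):
        row = te_logcpm.loc[gene_te_key]
        blocks.append(pd.Series(row.to_numpy(dtype=float), index=samples, name=term))
    X = pd.concat(blocks, axis=1)
    if covariates is not None and len(covariates.columns):
        cov = covariates.loc[samples]
        if cov.isna().any().any():
            raise ValueError(f"covariate table has missing cells for gene {spec.gene_id}")
        enc = _encode_covariates(cov, encoding)
        enc.index = samples
        X = pd.concat([X, enc], axis=1)
    aliased = _find_aliased(X.to_numpy(dtype=float), list(X.columns))
    return X, aliased


def fit_gene_lm(response: pd.Series | np.ndarray, design: pd.DataFrame) -> GeneFitResult:
    """Ordinary least squares of one gene's logCPM on its design matrix.

    The design must be full rank after alias removal; ``p`` counts predictor
    columns excluding the intercept.  Model-level statistics use TSS about
    the mean: R² = 1 - RSS/TSS, adj R² = 1 - (1-R²)(n-1)/(n-p-1),
    F = (R²/p)/((1-R²)/(n-p-1)) with the upper F(p, n-p-1) tail as model p.
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    p = design.shape[1] - 1
    if n <= p + 1:
        raise ValueError(f"cannot fit: n={n} <= p+1={p + 1}")
    gene_id = getattr(response, "name", "") or ""
    res = sm.OLS(y, design.to_numpy(dtype=float)).fit()
    terms = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=design.columns,
    )
    return GeneFitResult(
        gene_id=str(gene_id),
        n=n,
        p=p,
        terms=terms,
        sigma2_hat=float(res.ssr / res.df_resid),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        model_p=float(res.f_pvalue),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
    )


class TEAssociationModel:
    """Per-gene linear models of gene logCPM on linked-TE logCPM + covariates.

    Build either directly from normalized matrices, or from raw counts with
    :meth:`from_counts`, which merges genes and TEs into one matrix, filters
    features with fewer than ``min_total`` total reads, computes TMM factors
    on the merged matrix and transforms to log2-CPM — in that order.

    Parameters
    ----------
    gene_logcpm : DataFrame
        Genes x samples normalized log2-CPM.
    te_logcpm : DataFrame
        (gene|repeat) keyed rows x samples normalized log2-CPM.
    links : sequence of TEGeneLink
        Which TE terms belong to which gene.
    covariates : DataFrame or None
        Samples x covariates; sample index must match the matrix columns.
    encoding : {'numeric', 'onehot'}
        Categorical covariate encoding (see module docstring).
    alpha : float
        Significance threshold for flagging models (strictly below).

    Examples
    --------
    >>> model = TEAssociationModel.from_counts(gene_counts, te_counts, links,
    ...                                        covariates)      # doctest: +SKIP
    >>> results = model.fit()                                   # doctest: +SKIP
    >>> print(results.summary())                                # doctest: +SKIP
    """

    def __init__(
        self,
        gene_logcpm: pd.DataFrame,
        te_logcpm: pd.DataFrame,
        links: Sequence[TEGeneLink],
        covariates: pd.DataFrame | None = None,
        encoding: str = "numeric",
        alpha: float = 0.05,
    ):
        if list(gene_logcpm.columns) != list(te_logcpm.columns):
            raise ValueError("gene and TE matrices must share identical sample columns")
        if covariates is not None:
            missing = set(gene_logcpm.columns) - set(covariates.index)
            if missing:
                raise ValueError(f"covariate table misses samples: {sorted(missing)}")
            covariates = covariates.loc[list(gene_logcpm.columns)]
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        self.gene_logcpm = gene_logcpm
        self.te_logcpm = te_logcpm
        self.links = list(links)
        self.covariates = covariates
        self.encoding = encoding
        self.alpha = alpha
        self.norm_factors: pd.Series | None = None

    @classmethod
    def from_counts(
        cls,
        gene_counts: pd.DataFrame,
        te_counts: pd.DataFrame,
        links: Sequence[TEGeneLink],
        covariates: pd.DataFrame | None = None,
        *,
        min_total: int = 10,
        prior: float = 0.5,
        encoding: str = "numeric",
        alpha: float = 0.05,
    ) -> "TEAssociationModel":
        """Merge gene+TE counts, filter, TMM-normalize, log2-CPM, build model."""
        if list(gene_counts.columns) != list(te_counts.columns):
            raise ValueError("gene and TE count matrices must share identical sample columns")
        overlap = set(gene_counts.index) & set(te_counts.index)
        if overlap:
            raise ValueError(f"row keys shared between gene and TE matrices: {sorted(overlap)[:3]}")
        merged = pd.concat([gene_counts, te_counts])
        logcpm, factors = normalize_counts(merged, min_total=min_total, prior=prior)
        in_genes = logcpm.index.isin(gene_counts.index)
        obj = cls(
            gene_logcpm=logcpm.loc[in_genes],
            te_logcpm=logcpm.loc[~in_genes],
            links=links,
            covariates=covariates,
            encoding=encoding,
            alpha=alpha,
        )
        obj.norm_factors = factors
        return obj

    # -- fitting ---------------------------------------------------------

    def _spec_for(self, gene_id: str) -> ModelSpec | None:
        terms = [
            lk.repeat_name
            for lk in self.links
            if lk.gene_id == gene_id and lk.key in self.te_logcpm.index
        ]
        if not terms:
            return None
        n = self.gene_logcpm.shape[1]
        n_cov = 0 if self.covariates is None else len(self.covariates.columns)
        return ModelSpec(
            gene_id=gene_id,
            te_terms=tuple(dict.fromkeys(terms)),
            covariate_terms=tuple(self.covariates.columns) if n_cov else (),
            n=n,
            p=len(terms) + n_cov,  # provisional; onehot encoding may widen
        )

    def fit(self) -> "TEAssociationResults":
        """Fit one OLS model per gene with at least one surviving TE term."""
        linked_genes = {lk.gene_id for lk in self.links}
        fits: dict[str, GeneFitResult] = {}
        skipped: list[dict] = []
        for gene_id in self.gene_logcpm.index:
            if gene_id not in linked_genes:
                continue
            spec = self._spec_for(gene_id)
            if spec is None:
                skipped.append(
                    {"gene_id": gene_id, "reason": "no TE term survived count filtering"}
                )
                continue
            y = self.gene_logcpm.loc[gene_id]
            if float(np.var(y.to_numpy(dtype=float))) == 0.0:
                skipped.append({"gene_id": gene_id, "reason": "zero-variance response"})
                continue
            X, aliased = build_design(spec, self.te_logcpm, self.covariates, self.encoding)
            if aliased:
                log.warning("gene %s: dropping aliased columns %s", gene_id, aliased)
                X = X.drop(columns=aliased)
            p = X.shape[1] - 1
            if spec.n <= p + 1:
                skipped.append(
                    {"gene_id": gene_id, "reason": f"too few samples (n={spec.n}, p={p})"}
                )
                continue
            fit = fit_gene_lm(y, X)
            fit.gene_id = gene_id
            fit.aliased = tuple(aliased)
            if aliased:  # report NA coefficients for dropped columns
                na = pd.DataFrame(
                    np.nan, index=list(aliased), columns=fit.terms.columns
                )
                fit.terms = pd.concat([fit.terms, na])
            fits[gene_id] = fit
        return TEAssociationResults(self, fits, pd.DataFrame(skipped, columns=["gene_id", "reason"]))


class TEAssociationResults:
    """Collected per-gene fits with tabular views, writers and plots."""

    def __init__(
        self,
        model: TEAssociationModel,
        fits: dict[str, GeneFitResult],
        skipped: pd.DataFrame,
    ):
        self.model = model
        self.gene_results = fits
        self.skipped = skipped
        self.alpha = model.alpha

    @property
    def models(self) -> pd.DataFrame:
        """One row per fitted gene with model-level statistics.

        ``model_q`` is a Benjamini-Hochberg FDR across the fitted genes,
        provided as a convenience column; ``significant`` uses the raw
        model p at the strict ``alpha`` threshold.
        """
        rows = [
            {
                "gene_id": f.gene_id,
                "n": f.n,
                "p": f.p,
                "r_squared": f.r_squared,
                "adj_r_squared": f.adj_r_squared,
                "f_statistic": f.f_statistic,
                "model_p": f.model_p,
            }
            for f in self.gene_results.values()
        ]
        df = pd.DataFrame(
            rows,
            columns=["gene_id", "n", "p", "r_squared", "adj_r_squared", "f_statistic", "model_p"],
        )
        if len(df):
            df["model_q"] = multipletests(df["model_p"].fillna(1.0), method="fdr_bh")[1]
            df["significant"] = df["model_p"] < self.alpha
        else:
            df["model_q"] = pd.Series(dtype=float)
            df["significant"] = pd.Series(dtype=bool)
        return df

    @property
    def terms(self) -> pd.DataFrame:
        """One row per gene x design term: estimate, se, t, p."""
        rows = []
        for f in self.gene_results.values():
            for term, r in f.terms.iterrows():
                rows.append(
                    {
                        "gene_id": f.gene_id,
                        "term": term,
                        "estimate": r["estimate"],
                        "se": r["se"],
                        "t": r["t"],
                        "p": r["p"],
                    }
                )
        return pd.DataFrame(rows, columns=["gene_id", "term", "estimate", "se", "t", "p"])

    def significant_genes(self) -> list[str]:
        return [f.gene_id for f in self.gene_results.values() if f.model_p < self.alpha]

    def summary(self) -> str:
        m = self.models
        lines = [
            "TE-gene association models (OLS on log2-CPM)",
            f"  samples: {self.model.gene_logcpm.shape[1]}",
            f"  genes fitted: {len(m)}   skipped: {len(self.skipped)}",
            f"  significant at model p < {self.alpha:g}: {int(m['significant'].sum()) if len(m) else 0}",
            "",
        ]
        if len(m):
            top = m.sort_values("model_p").head(10)
            lines.append(
                top.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.4g}",
                    columns=["gene_id", "n", "p", "r_squared", "adj_r_squared", "f_statistic", "model_p"],
                )
            )
        return "\n".join(lines)

    # -- output ----------------------------------------------------------

    def write(self, out_dir, make_plots: bool = True) -> dict[str, list[str]]:
        """Write models.tsv, terms.tsv, logcpm.tsv and per-significant-gene plots.

        Plots (residuals-vs-fitted + normal QQ diagnostics, and a TE-vs-gene
        logCPM scatter) are produced only for models with raw model p
        strictly below alpha.
        """
        os.makedirs(out_dir, exist_ok=True)
        if not os.access(out_dir, os.W_OK):
            raise PermissionError(f"output directory {out_dir} is not writable")
        written: dict[str, list[str]] = {"tables": [], "plots": []}
        for name, df in (("models.tsv", self.models), ("terms.tsv", self.terms)):
            path = os.path.join(out_dir, name)
            _write_float_tsv(df, path)
            written["tables"].append(path)
        logcpm = pd.concat([self.model.gene_logcpm, self.model.te_logcpm])
        path = os.path.join(out_dir, "logcpm.tsv")
        logcpm.round(6).to_csv(path, sep="\t", index_label="feature")
        written["tables"].append(path)
        skip_path = os.path.join(out_dir, "skipped.tsv")
        self.skipped.to_csv(skip_path, sep="\t", index=False)
        written["tables"].append(skip_path)
        if make_plots:
            for gene_id in self.significant_genes():
                written["plots"].append(self.plot_diagnostics(gene_id, out_dir))
                written["plots"].append(self.plot_scatter(gene_id, out_dir))
        return written

    def plot_diagnostics(self, gene_id: str, out_dir) -> str:
        """Residuals-vs-fitted and normal QQ panels for one gene."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy import stats as sps

        f = self.gene_results[gene_id]
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(f.fitted, f.residuals, s=12)
        ax1.axhline(0.0, lw=0.8, color="grey")
        ax1.set_xlabel("fitted log2-CPM")
        ax1.set_ylabel("residual")
        ax1.set_title(f"{gene_id}: residuals vs fitted")
        sps.probplot(f.residuals, dist="norm", plot=ax2)
        ax2.set_title(f"{gene_id}: normal Q-Q")
        fig.tight_layout()
        path = os.path.join(out_dir, f"{gene_id}.diagnostics.png")
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return path

    def plot_scatter(self, gene_id: str, out_dir) -> str:
        """Gene logCPM against each linked TE term's logCPM."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        f = self.gene_results[gene_id]
        te_terms = [
            t
            for t in f.terms.index
            if f"{gene_id}{TE_KEY_SEP}{t}" in self.model.te_logcpm.index
        ]
        y = self.model.gene_logcpm.loc[gene_id]
        ncol = max(len(te_terms), 1)
        fig, axes = plt.subplots(1, ncol, figsize=(4.2 * ncol, 4), squeeze=False)
        for ax, term in zip(axes[0], te_terms):
            x = self.model.te_logcpm.loc[f"{gene_id}{TE_KEY_SEP}{term}"]
            ax.scatter(x, y, s=14)
            ax.set_xlabel(f"{term} log2-CPM")
            ax.set_ylabel(f"{gene_id} log2-CPM")
        fig.tight_layout()
        path = os.path.join(out_dir, f"{gene_id}.scatter.png")
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return path


def _fmt_float(v) -> str:
    if isinstance(v, float):
        if np.isnan(v):
            return "NA"
        return f"{v:.6g}"  # >= 6 significant digits; scientific for tiny p
    return str(v)


def _write_float_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt_float(v) for v in row) + "\n")


# -- functional wrappers over the Model/Results objects ------------------


def run_all_models(
    gene_logcpm: pd.DataFrame,
    te_logcpm: pd.DataFrame,
    links: Sequence[TEGeneLink],
    covariates: pd.DataFrame | None = None,
    encoding: str = "numeric",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every gene's model; return (models table, skipped table)."""
    results = TEAssociationModel(
        gene_logcpm, te_logcpm, links, covariates, encoding=encoding, alpha=alpha
    ).fit()
    return results.models, results.skipped


def write_outputs(results: TEAssociationResults, out_dir, make_plots: bool = True):
    """Write the standard tsv outputs (and plots for significant models)."""
    return results.write(out_dir, make_plots=make_plots)
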