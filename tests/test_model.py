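import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tegene.model import (
    INTERCEPT,
    ModelSpec,
    TEAssociationModel,
    adjusted_r_squared,
    build_design,
    fit_gene_lm,
    model_f_test,
    run_all_models,
)
from tegene.proximity import TEGeneLink

SAMPLES = [f"S{i}" for i in range(10)]


def covariate_table(n=10):
    return pd.DataFrame(
        {"tissue": ["N" if i % 2 == 0 else "T" for i in range(n)],
         "patient": [i // 2 + 1 for i in range(n)]},
        index=SAMPLES[:n],
    )


def te_matrix(terms, gene="G1", seed=0, n=10):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(2, 8, size=(len(terms), n)),
                        index=[f"{gene}|{t}" for t in terms], columns=SAMPLES[:n])


class TestBuildDesign:
    def test_numeric_encoding_one_column_per_covariate(self):
        spec = ModelSpec("G1", ("L2c",), ("tissue", "patient"), 10, 3)
        X, aliased = build_design(spec, te_matrix(["L2c"]), covariate_table())
        assert list(X.columns) == [INTERCEPT, "L2c", "tissue", "patient"]
        assert X.shape == (10, 4) and aliased == []
        assert set(X["tissue"]) == {0.0, 1.0}  # first-appearance order: N=0, T=1

    def test_onehot_encoding_drops_reference_level(self):
        cov = covariate_table()
        cov["batch"] = ["a", "b", "c", "a", "b", "c", "a", "b", "c", "a"]
        spec = ModelSpec("G1", ("L2c",), tuple(cov.columns), 10, 4)
        X, _ = build_design(spec, te_matrix(["L2c"]), cov, encoding="onehot")
        assert "batch[b]" in X.columns and "batch[c]" in X.columns
        assert "batch[a]" not in X.columns  # reference level

    def test_no_covariates_single_te(self):
        spec = ModelSpec("G1", ("L2c",), (), 10, 1)
        X, _ = build_design(spec, te_matrix(["L2c"]), None)
        assert list(X.columns) == [INTERCEPT, "L2c"]

    def test_duplicate_column_flagged_aliased(self):
        te = te_matrix(["L2c"])
        dup = te.copy()
        dup.index = ["G1|L2c_copy"]
        both = pd.concat([te, dup])
        spec = ModelSpec("G1", ("L2c", "L2c_copy"), (), 10, 2)
        _, aliased = build_design(spec, both, None)
        assert aliased == ["L2c_copy"]

    def test_missing_covariate_cell_rejected(self):
        cov = covariate_table()
        cov.iloc[3, 0] = np.nan
        spec = ModelSpec("G1", ("L2c",), ("tissue", "patient"), 10, 3)
        with pytest.raises(ValueError, match="missing"):
            build_design(spec, te_matrix(["L2c"]), cov)


class TestFitGeneLM:
    def test_exact_fit(self):
        X = pd.DataFrame({INTERCEPT: [1.0, 1, 1], "x": [1.0, 2, 3]})
        fit = fit_gene_lm(np.array([3.0, 5.0, 7.0]), X)
        assert fit.terms["estimate"].to_numpy() == pytest.approx([1.0, 2.0], abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_closed_form(self):
        """OLS coefficients, sigma^2 and R^2 against the closed form."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            n, p = 30, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
            y = rng.normal(size=n)
            Xdf = pd.DataFrame(X, columns=[INTERCEPT] + [f"x{j}" for j in range(p)])
            fit = fit_gene_lm(y, Xdf)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.abs(fit.terms["estimate"].to_numpy() - beta).max() < 1e-8
            rss = float(((y - X @ beta) ** 2).sum())
            tss = float(((y - y.mean()) ** 2).sum())
            assert fit.sigma2_hat == pytest.approx(rss / (n - p - 1), rel=1e-8)
            assert fit.r_squared == pytest.approx(1 - rss / tss, rel=1e-8)
            se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * rss / (n - p - 1))
            assert np.abs(fit.terms["se"].to_numpy() - se).max() < 1e-8

    def test_model_statistics_follow_f_and_t_formulas(self):
        rng = np.random.default_rng(3)
        n, p = 25, 3
        X = pd.DataFrame(np.column_stack([np.ones(n), rng.normal(size=(n, p))]),
                         columns=[INTERCEPT, "a", "b", "c"])
        y = X["a"].to_numpy() + rng.normal(size=n)
        fit = fit_gene_lm(y, X)
        f_ref, p_ref = model_f_test(fit.r_squared, n, p)
        assert fit.f_statistic == pytest.approx(f_ref, rel=1e-10)
        assert fit.model_p == pytest.approx(p_ref, rel=1e-10)
        assert fit.adj_r_squared == pytest.approx(
            adjusted_r_squared(fit.r_squared, n, p), abs=1e-12)
        t = fit.terms.loc["a"]
        assert t["p"] == pytest.approx(2 * stats.t.sf(abs(t["t"]), n - p - 1), rel=1e-10)

    def test_model_p_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(4)
        n = 20
        X = pd.DataFrame({INTERCEPT: np.ones(n), "x": rng.normal(size=n),
                          "z": rng.normal(size=n)})
        y = rng.normal(size=n)
        base = fit_gene_lm(y, X)
        X2 = X.copy()
        X2["x"] = 3.7 * X2["x"] - 11.0
        again = fit_gene_lm(y, X2)
        assert again.model_p == pytest.approx(base.model_p, rel=1e-9)
        assert again.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.ones((3, 3)), columns=[INTERCEPT, "a", "b"])
        with pytest.raises(ValueError, match="n=3"):
            fit_gene_lm(np.zeros(3), X)


def _model_inputs(seed=0, n=10, betas=(1.2,)):
    rng = np.random.default_rng(seed)
    te = te_matrix(["L2c"], seed=seed, n=n)
    y = 3.0 + betas[0] * te.loc["G1|L2c"].to_numpy() + rng.normal(0, 0.3, n)
    gene = pd.DataFrame([y], index=["G1"], columns=SAMPLES[:n])
    links = [TEGeneLink("G1", "L2c", ("chr1:5-200:L2c",), (1000,))]
    return gene, te, links


class TestRunAllModels:
    def test_gene_without_surviving_te_rows_is_skipped(self):
        gene, te, links = _model_inputs()
        links = links + [TEGeneLink("G2", "AluY", ("chr1:9-99:AluY",), (50,))]
        gene2 = pd.concat([gene, pd.DataFrame([np.ones(10)], index=["G2"],
                                              columns=gene.columns)])
        models, skipped = run_all_models(gene2, te, links, covariate_table())
        assert list(models["gene_id"]) == ["G1"]
        assert skipped["gene_id"].tolist() == ["G2"]

    def test_zero_variance_response_reported_as_skipped(self):
        gene, te, links = _model_inputs()
        gene.loc["G1"] = 4.0
        models, skipped = run_all_models(gene, te, links, None)
        assert len(models) == 0
        assert "zero-variance" in skipped["reason"].iloc[0]

    def test_alpha_one_flags_every_fitted_gene(self):
        gene, te, links = _model_inputs()
        results = TEAssociationModel(gene, te, links, covariate_table(), alpha=1.0).fit()
        assert results.models["significant"].all()

    def test_aliased_columns_dropped_with_na_coefficients(self):
        gene, te, links = _model_inputs()
        cov = covariate_table()
        cov["patient_copy"] = cov["patient"]
        results = TEAssociationModel(gene, te, links, cov).fit()
        fit = results.gene_results["G1"]
        assert fit.aliased == ("patient_copy",)
        assert np.isnan(fit.terms.loc["patient_copy", "estimate"])
        assert results.models["r_squared"].between(0, 1).all()

    def test_adjusted_r2_identity_on_every_emitted_row(self):
        rng = np.random.default_rng(8)
        genes, tes, all_links = [], [], []
        for i in range(6):
            g, t, lk = _model_inputs(seed=i, betas=(rng.uniform(-1, 1),))
            g.index, t.index = [f"G{i}"], [f"G{i}|L2c"]
            lk = [TEGeneLink(f"G{i}", "L2c", (f"chr1:{i}-{i + 100}:L2c",), (10,))]
            genes.append(g)
            tes.append(t)
            all_links += lk
        models, _ = run_all_models(pd.concat(genes), pd.concat(tes), all_links,
                                   covariate_table())
        for _, row in models.iterrows():
            expected = adjusted_r_squared(row["r_squared"], int(row["n"]), int(row["p"]))
            assert abs(row["adj_r_squared"] - expected) < 1e-10


class TestWriteOutputs:
    @pytest.fixture
    def results(self):
        gene, te, links = _model_inputs(seed=1)
        return TEAssociationModel(gene, te, links, covariate_table()).fit()

    def test_tables_written_and_floats_round_trip(self, tmp_path, results):
        written = results.write(tmp_path, make_plots=False)
        assert {p.split("/")[-1] for p in written["tables"]} == {
            "models.tsv", "terms.tsv", "logcpm.tsv", "skipped.tsv"}
        back = pd.read_csv(tmp_path / "models.tsv", sep="\t")
        for col in ("r_squared", "adj_r_squared", "f_statistic", "model_p"):
            orig = results.models[col].iloc[0]
            assert back[col].iloc[0] == pytest.approx(orig, rel=1e-5)

    def test_significance_threshold_is_strict(self):
        gene, te, links = _model_inputs(seed=1)
        results = TEAssociationModel(gene, te, links, covariate_table()).fit()
        p = results.gene_results["G1"].model_p
        results.alpha = p  # boundary: p == alpha must NOT be significant
        assert results.significant_genes() == []
        results.alpha = np.nextafter(p, 1)
        assert results.significant_genes() == ["G1"]

    def test_no_significant_models_writes_tables_but_no_images(self, tmp_path, results):
        results.alpha = 0.0  # nothing can be strictly below zero
        written = results.write(tmp_path, make_plots=True)
        assert written["plots"] == []
        assert (tmp_path / "models.tsv").exists()

    def test_plots_written_for_significant_genes(self, tmp_path, results):
        if not results.significant_genes():
            pytest.skip("fixture fit not significant at default alpha")
        written = results.write(tmp_path, make_plots=True)
        names = {p.split("/")[-1] for p in written["plots"]}
        assert "G1.diagnostics.png" in names and "G1.scatter.png" in names


class TestFromCounts:
    def test_merged_normalization_then_split(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(8)]
        gene_counts = pd.DataFrame(rng.integers(50, 500, size=(5, 8)),
                                   index=[f"G{i}" for i in range(5)], columns=samples)
        te_counts = pd.DataFrame(rng.integers(20, 200, size=(3, 8)),
                                 index=["G0|L2c", "G1|AluY", "G2|MIR3"], columns=samples)
        links = [TEGeneLink("G0", "L2c", ("i0",), (1,)),
                 TEGeneLink("G1", "AluY", ("i1",), (2,)),
                 TEGeneLink("G2", "MIR3", ("i2",), (3,))]
        model = TEAssociationModel.from_counts(gene_counts, te_counts, links)
        # logCPM must come from the merged matrix: recompute directly
        from tegene.normalize import normalize_counts
        merged, _ = normalize_counts(pd.concat([gene_counts, te_counts]))
        pd.testing.assert_frame_equal(model.gene_logcpm, merged.loc[gene_counts.index])
        pd.testing.assert_frame_equal(model.te_logcpm, merged.loc[te_counts.index])
        assert model.norm_factors is not None

    def test_low_count_te_term_drops_gene_into_skipped(self):
        samples = [f"S{i}" for i in range(6)]
        gene_counts = pd.DataFrame([[100] * 6, [120, 80, 100, 100, 110, 90]],
                                   index=["G0", "G1"], columns=samples)
        te_counts = pd.DataFrame([[1, 0, 0, 1, 0, 0], [30, 20, 25, 30, 20, 25]],
                                 index=["G0|L2c", "G1|AluY"], columns=samples)
        links = [TEGeneLink("G0", "L2c", ("i0",), (1,)),
                 TEGeneLink("G1", "AluY", ("i1",), (2,))]
        results = TEAssociationModel.from_counts(gene_counts, te_counts, links).fit()
        assert "G0" in results.skipped["gene_id"].tolist()
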