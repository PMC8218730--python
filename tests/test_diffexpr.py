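"""Gene filter, size factors, NB GLM fits, LRT, Holm and DEG selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnmacs import (
    ExpressionMatrix,
    NBDifferentialExpression,
    SimConfig,
    ValidationError,
    build_design,
    canonical_metadata,
    filter_genes,
    fit_nb_glm,
    generate_counts,
    holm_adjust,
    lrt_test,
    nb_loglik,
    run_comparison,
    select_deg,
    size_factors,
)
from lnmacs.diffexpr import RankDeficientError


def _counts(arr, meta=None) -> ExpressionMatrix:
    arr = np.asarray(arr)
    values = pd.DataFrame(
        arr, index=[f"g{i}" for i in range(arr.shape[0])],
        columns=meta.index if meta is not None
        else [f"s{i}" for i in range(arr.shape[1])])
    return ExpressionMatrix(values, "counts", meta)


class TestFilterGenes:
    def test_boundary_of_both_rules(self):
        rows = np.zeros((3, 16), dtype=int)
        rows[0, :2] = 5          # total 10, detected in 2 -> keep
        rows[1, 0] = 10          # total 10, detected in 1 -> drop
        rows[2, :3] = 3          # total 9, detected in 3 -> drop
        out = filter_genes(_counts(rows))
        assert out.gene_ids == ["g0"]

    def test_matches_bruteforce_oracle(self, rng):
        arr = rng.negative_binomial(1, 0.15, size=(50, 16))
        arr[rng.random(arr.shape) < 0.5] = 0
        kept = filter_genes(_counts(arr)).gene_ids
        oracle = [f"g{i}" for i, row in enumerate(arr)
                  if row.sum() >= 10 and (row > 0).sum() >= 2]
        assert kept == oracle

    def test_idempotent_subset(self, small_sim):
        _, counts, _ = small_sim
        once = filter_genes(counts)
        twice = filter_genes(once)
        assert set(once.gene_ids) <= set(counts.gene_ids)
        assert twice.gene_ids == once.gene_ids


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([[4], [9], [100]])
        sf = size_factors(_counts(np.tile(col, (1, 5))))
        assert np.allclose(sf, 1.0)

    def test_doubled_column_ratio_preserved(self, rng):
        base = rng.integers(5, 200, size=(40, 4))
        arr = np.column_stack([base, 2 * base[:, 0]])
        sf = size_factors(_counts(arr))
        assert sf.iloc[4] / sf.iloc[0] == pytest.approx(2.0)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_requires_an_always_positive_gene(self):
        arr = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValidationError, match="positive"):
            size_factors(_counts(arr))


class TestNBGLMFit:
    def test_constant_vector_closed_form(self):
        y = np.full(16, 5.0)
        X = np.ones((16, 1))
        fit = fit_nb_glm(y, X, alpha=0.1)
        assert fit.coef.iloc[0] == pytest.approx(np.log(5.0), abs=1e-8)
        assert fit.loglik == pytest.approx(
            nb_loglik(y, np.full(16, 5.0), 0.1), abs=1e-8)

    def test_offset_shifts_intercept(self):
        y = np.full(8, 20.0)
        X = np.ones((8, 1))
        sf = np.full(8, 2.0)
        fit = fit_nb_glm(y, X, sf=sf, alpha=0.05)
        assert fit.coef.iloc[0] == pytest.approx(np.log(10.0), abs=1e-8)

    def test_duplicated_column_is_rank_error(self):
        X = np.ones((10, 2))
        with pytest.raises(RankDeficientError):
            fit_nb_glm(np.arange(10.0), X)

    def test_poisson_limit_dispersion_collapses(self, rng):
        X = np.ones((16, 1))
        alphas = np.array([fit_nb_glm(rng.poisson(100, 16), X).alpha
                           for _ in range(500)])
        assert (alphas < 0.01).mean() >= 0.95
        assert np.median(alphas) < 1e-3

    def test_matches_statsmodels_at_fixed_dispersion(self, rng):
        import statsmodels.api as sm
        meta = canonical_metadata()
        X, _, _, _ = build_design(meta, "C1")
        mu = 50 * np.exp(0.4 * X["phenotype"].to_numpy())
        y = rng.poisson(mu)
        alpha = 0.08
        ours = fit_nb_glm(y, X, alpha=alpha)
        ref = sm.GLM(y, X.to_numpy(),
                     family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert np.allclose(ours.coef.to_numpy(), ref.params, atol=1e-6)


class TestLRT:
    @staticmethod
    def _design16():
        return build_design(canonical_metadata(), "C1")

    def test_null_factor_gives_near_zero_stat(self, rng):
        # reduced model already explains the data: stat ~ 0, p ~ 1 when the
        # dropped column is pure noise orthogonal to the truth
        Xf, Xr, _, _ = self._design16()
        y = np.full(16, 25.0)
        full = fit_nb_glm(y, Xf, alpha=0.1)
        reduced = fit_nb_glm(y, Xr, alpha=0.1)
        stat, p = lrt_test(full, reduced)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_reduced_equals_full_information(self, rng):
        Xf, Xr, _, _ = self._design16()
        y = rng.poisson(30, 16).astype(float)
        full = fit_nb_glm(y, Xf, alpha=0.1)
        reduced = fit_nb_glm(y, Xr, alpha=0.1)
        stat, p = lrt_test(full, reduced)
        assert stat >= 0 and 0 <= p <= 1
        with pytest.raises(ValidationError, match="nested"):
            lrt_test(reduced, full)

    def test_invariant_to_pool_reference_level(self, rng):
        meta = canonical_metadata()
        Xf, Xr, _, _ = build_design(meta, "C1")
        y = rng.poisson(40, 16).astype(float)

        def relevel(X, pools):
            Z = X.copy()
            for c in [c for c in Z.columns if c.startswith("pool")]:
                Z = Z.drop(columns=c)
            for p in pools:
                Z[f"pool[{p}]"] = (meta["pool"] == p).astype(float)
            return Z

        stat1, _ = lrt_test(fit_nb_glm(y, Xf, alpha=0.05),
                            fit_nb_glm(y, Xr, alpha=0.05))
        Xf2, Xr2 = relevel(Xf, ["P1", "P2", "P3"]), relevel(Xr, ["P1", "P2", "P3"])
        stat2, _ = lrt_test(fit_nb_glm(y, Xf2, alpha=0.05),
                            fit_nb_glm(y, Xr2, alpha=0.05))
        assert stat1 == pytest.approx(stat2, abs=1e-6)

    def test_invariant_to_sample_order_and_sf_rescaling(self):
        cfg = SimConfig(n_genes=60, seed=8)
        counts, _ = generate_counts(cfg)
        filtered = filter_genes(counts)
        res = run_comparison(filtered, None, "C1", dispersion_method="cox-reid")

        order = list(reversed(filtered.sample_ids))
        reordered = ExpressionMatrix(filtered.values[order], "counts",
                                     filtered.metadata.loc[order])
        res2 = run_comparison(reordered, None, "C1",
                              dispersion_method="cox-reid")
        a = res.table.set_index("gene_id")["lrt_stat"]
        b = res2.table.set_index("gene_id")["lrt_stat"]
        assert np.allclose(a.sort_index(), b.sort_index(), atol=1e-5)


class TestHolm:
    def test_hand_case_and_single(self):
        assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_stepdown_definition_bruteforce(self, p):
        adjusted = holm_adjust(p)
        m = len(p)
        order = sorted(range(m), key=lambda i: (p[i], i))
        oracle = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[idx]))
            oracle[idx] = running
        assert np.allclose(adjusted, oracle)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_statsmodels_oracle(self, p):
        from statsmodels.stats.multitest import multipletests
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), ref)


class TestComparisonsAndSelection:
    def test_sign_convention_up_in_ssm_is_positive(self):
        # plant genes higher in CD11c- (SSM) samples -> positive log2_fc
        eff = {i: 3.0 for i in range(37, 42)}
        cfg = SimConfig(n_genes=120, phenotype_effects=eff, seed=21)
        counts, truth = generate_counts(cfg)
        res = run_comparison(filter_genes(counts), None, "C1")
        planted = truth.genes.index[truth.genes["phenotype_log2fc"] > 0]
        sub = res.table.set_index("gene_id").loc[
            [g for g in planted if g in set(res.table.gene_id)]]
        assert (sub["log2_fc"] > 0).all()
        assert sub["log2_fc"].mean() == pytest.approx(3.0, abs=0.7)

    def test_td_contrast_detects_td_effects(self):
        eff = {i: 2.5 for i in range(37, 42)}
        cfg = SimConfig(n_genes=120, td_effects=eff, seed=22)
        counts, truth = generate_counts(cfg)
        res = run_comparison(filter_genes(counts), None, "C2")
        planted = truth.genes.index[truth.genes["td_log2fc"] > 0]
        sub = res.table.set_index("gene_id").loc[list(planted)]
        assert (sub["p_holm"] < 0.01).all()
        assert (sub["log2_fc"] > 0).all()

    def test_select_deg_strict_inequalities(self):
        table = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d"],
            "base_mean": [150.0, 150.0, 100.0, 150.0],
            "log2_fc": [1.0, -1.0, 1.0, 1.0],
            "p_holm": [0.005, 0.005, 0.005, 0.01],
        })
        up, down = select_deg(table)
        assert list(up["gene_id"]) == ["a"]       # d: p == 0.01 excluded
        assert list(down["gene_id"]) == ["b"]     # c: base_mean == 100 excluded

    def test_results_api_and_summary(self, small_sim):
        _, counts, _ = small_sim
        res = run_comparison(filter_genes(counts), None, "C1")
        assert (res.table["p_holm"] >= res.table["p_raw"] - 1e-15).all()
        assert res.table["p_holm"].is_monotonic_increasing
        assert (res.table["lrt_stat"] >= 0).all()
        text = res.summary()
        assert "C1" in text and "genes tested" in text
        sig = res.significant(padj_max=1.0, base_mean_min=0.0)
        assert set(sig["direction"]) <= {"up", "down"}

    def test_model_from_files(self, small_sim, tmp_path):
        from lnmacs import write_expression_matrix, write_sample_metadata
        _, counts, _ = small_sim
        write_expression_matrix(counts, tmp_path / "c.tsv")
        write_sample_metadata(counts.metadata, tmp_path / "m.tsv")
        model = NBDifferentialExpression.from_files(
            tmp_path / "c.tsv", tmp_path / "m.tsv", comparison="C2")
        assert model.design_full.shape == (16, 6)
        assert model.tested == "td"
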