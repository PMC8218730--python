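"""Probe aggregation, log transform, intersection, standardization,
platform means and the cross-platform comparability correlation."""

import numpy as np
import pandas as pd
import pytest

from lnmacs import (
    ExpressionMatrix,
    ProbeMatrix,
    SimConfig,
    ValidationError,
    aggregate_probes,
    cross_platform_correlation,
    generate_counts,
    generate_microarray,
    harmonize_pair,
    intersect_platform_genes,
    log_transform_counts,
    platform_means,
    standardize_samples,
)


def _probe_matrix(values, mapping):
    df = pd.DataFrame(values["data"], index=values["probes"],
                      columns=values["samples"])
    return ProbeMatrix(df, pd.Series(mapping))


class TestAggregateProbes:
    def test_two_probe_mean(self):
        pm = _probe_matrix(
            {"data": [[2.0], [4.0], [1.0]],
             "probes": ["p1", "p2", "p3"], "samples": ["s1"]},
            {"p1": "gA", "p2": "gA", "p3": "gB"})
        agg = aggregate_probes(pm)
        assert agg.values.loc["gA", "s1"] == 3.0
        assert agg.values.loc["gB", "s1"] == 1.0

    def test_single_probe_identity_and_unmapped_drop(self):
        pm = _probe_matrix(
            {"data": [[5.0, 6.0], [7.0, 8.0]],
             "probes": ["p1", "px"], "samples": ["s1", "s2"]},
            {"p1": "gA"})
        agg = aggregate_probes(pm)
        assert agg.shape == (1, 2)
        assert (agg.values.loc["gA"] == [5.0, 6.0]).all()

    def test_all_unmapped_is_error(self):
        pm = _probe_matrix({"data": [[1.0]], "probes": ["p1"],
                            "samples": ["s1"]}, {})
        with pytest.raises(ValidationError, match="unmapped"):
            aggregate_probes(pm)

    def test_matches_groupby_mean_oracle(self, rng):
        n_probes, n_samples = 60, 5
        genes = [f"g{i}" for i in rng.integers(0, 12, n_probes)]
        pm = _probe_matrix(
            {"data": rng.normal(size=(n_probes, n_samples)),
             "probes": [f"p{i}" for i in range(n_probes)],
             "samples": [f"s{i}" for i in range(n_samples)]},
            dict(zip([f"p{i}" for i in range(n_probes)], genes)))
        agg = aggregate_probes(pm)
        oracle = pm.values.groupby(pd.Series(genes, index=pm.values.index)).mean()
        assert np.allclose(agg.values.sort_index().to_numpy(),
                           oracle.sort_index().to_numpy())


class TestLogTransform:
    def test_formula_forced_values(self):
        values = pd.DataFrame({"s1": [7, 0, 0]}, index=["a", "b", "c"])
        em = ExpressionMatrix(values, "counts")
        out = log_transform_counts(em)
        assert out.values.loc["a", "s1"] == pytest.approx(np.log2(1e6 + 1))
        assert (out.values.loc[["b", "c"], "s1"] == 0).all()

    def test_depth_invariance(self, small_sim):
        _, counts, _ = small_sim
        doubled = ExpressionMatrix(counts.values * 2, "counts",
                                   counts.metadata)
        a = log_transform_counts(counts).values.to_numpy()
        b = log_transform_counts(doubled).values.to_numpy()
        assert np.allclose(a, b)

    def test_zero_column_is_error(self):
        em = ExpressionMatrix(pd.DataFrame({"s1": [1], "s2": [0]},
                                           index=["g"]), "counts")
        with pytest.raises(ValidationError, match="zero column"):
            log_transform_counts(em)


class TestIntersection:
    def test_set_intersection_keeps_order_of_first(self):
        a = ExpressionMatrix(pd.DataFrame(
            {"s1": [1, 2, 3]}, index=["A", "B", "C"]), "counts")
        b = ExpressionMatrix(pd.DataFrame(
            {"t1": [1.0, 2.0, 3.0]}, index=["B", "C", "D"]), "log2_intensity")
        oa, ob = intersect_platform_genes(a, b)
        assert oa.gene_ids == ["B", "C"] == ob.gene_ids

    def test_idempotent_on_identical_matrices(self, tiny_counts):
        oa, ob = intersect_platform_genes(tiny_counts, tiny_counts)
        assert oa.gene_ids == tiny_counts.gene_ids

    def test_detection_rules(self):
        # counts: needs >0 somewhere; intensities: needs a non-missing cell
        a = ExpressionMatrix(pd.DataFrame(
            {"s1": [0, 5]}, index=["A", "B"]), "counts")
        b = ExpressionMatrix(pd.DataFrame(
            {"t1": [np.nan, 1.0], "t2": [np.nan, np.nan]},
            index=["A", "B"]), "log2_intensity")
        oa, ob = intersect_platform_genes(a, b)
        assert oa.gene_ids == ["B"]
        with pytest.raises(ValidationError, match="no genes"):
            intersect_platform_genes(
                a.subset_genes(["A"]), b.subset_genes(["B"]))


class TestStandardize:
    def test_hand_case(self):
        em = ExpressionMatrix(pd.DataFrame({"s1": [1.0, 2.0, 3.0]},
                                           index=list("abc")),
                              "log2_intensity")
        out = standardize_samples(em)
        assert np.allclose(out.values["s1"], [-1.0, 0.0, 1.0])

    def test_idempotent_and_moments(self, rng):
        values = pd.DataFrame(rng.normal(2, 5, size=(40, 6)),
                              index=[f"g{i}" for i in range(40)],
                              columns=[f"s{i}" for i in range(6)])
        z = standardize_samples(ExpressionMatrix(values, "log2_intensity"))
        arr = z.values.to_numpy()
        assert np.abs(arr.mean(axis=0)).max() < 1e-9
        assert np.abs(arr.std(axis=0, ddof=1) - 1).max() < 1e-9
        z2 = standardize_samples(z)
        assert np.abs(z2.values.to_numpy() - arr).max() < 1e-12

    def test_constant_column_error_names_sample(self):
        em = ExpressionMatrix(pd.DataFrame({"ok": [1.0, 2.0],
                                            "flat": [3.0, 3.0]},
                                           index=["a", "b"]),
                              "log2_intensity")
        with pytest.raises(ValidationError, match="flat"):
            standardize_samples(em)


class TestPlatformMeansAndCorrelation:
    def test_means_equal_row_mean_oracle(self, rng):
        values = pd.DataFrame(rng.normal(size=(30, 4)),
                              index=[f"g{i}" for i in range(30)],
                              columns=list("wxyz"))
        em = ExpressionMatrix(values, "log2_intensity")
        assert np.allclose(platform_means(em), values.to_numpy().mean(axis=1))
        single = ExpressionMatrix(values[["w"]], "log2_intensity")
        assert np.allclose(platform_means(single), values["w"])

    def test_correlation_limits_and_errors(self, rng):
        v = pd.Series(rng.normal(size=50))
        assert cross_platform_correlation(v, v) == pytest.approx(1.0)
        assert cross_platform_correlation(v, -v) == pytest.approx(-1.0)
        with pytest.raises(ValidationError, match="variance"):
            cross_platform_correlation(v, pd.Series(np.ones(50)))


class TestHarmonizationChain:
    def test_gene_and_sample_order_equivariance(self, small_sim):
        cfg, counts, _ = small_sim
        probes = generate_microarray(counts, cfg)
        base = harmonize_pair(counts, probes)

        perm_genes = counts.values.sample(frac=1, random_state=1)
        shuffled = ExpressionMatrix(perm_genes, "counts", counts.metadata)
        harm2 = harmonize_pair(shuffled, probes)
        assert harm2["pearson_r"] == pytest.approx(base["pearson_r"], abs=1e-12)

        perm_samples = counts.values[list(reversed(counts.sample_ids))]
        harm3 = harmonize_pair(
            ExpressionMatrix(perm_samples, "counts", counts.metadata), probes)
        assert harm3["pearson_r"] == pytest.approx(base["pearson_r"], abs=1e-12)

    def test_correlation_decreases_with_probe_noise(self):
        noise_grid = [0.0, 0.5, 1.0, 2.0, 4.0]
        from scipy.stats import spearmanr
        rhos = []
        for rep in range(10):
            cfg = SimConfig(n_genes=150, seed=200 + rep)
            counts, _ = generate_counts(cfg)
            rs = []
            for k, sd in enumerate(noise_grid):
                cfg_n = SimConfig(n_genes=150, seed=200 + rep,
                                  probe_offset_sd=0.0, noise_sd_array=sd)
                pm = generate_microarray(counts, cfg_n, seed=900 + k)
                rs.append(harmonize_pair(counts, pm)["pearson_r"])
            rhos.append(spearmanr(noise_grid, rs).statistic)
        assert np.mean(rhos) <= -0.9
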