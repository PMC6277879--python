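import numpy as np
import pandas as pd
import pytest

from carrotmorph.quantstats import (correlation_pair,
                                    estimate_variance_components,
                                    harmonic_design_means, load_qtl_table,
                                    lod_interval_width_mb, parse_marker,
                                    pve_from_lod, qtl_support_table,
                                    repeatability, repeatability_analysis)


def balanced_table(g=20, t=2, r=2, var_G=4.0, var_GE=1.0, var_R=2.0,
                   var_B=0.25, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_product(
        [range(g), range(t), range(r)],
        names=["genotype", "environment", "replication"]).to_frame(index=False)
    G = rng.normal(0, np.sqrt(var_G), g)
    GE = rng.normal(0, np.sqrt(var_GE), (g, t))
    B = rng.normal(0, np.sqrt(var_B), (t, r))
    idx["y"] = (G[idx.genotype] + GE[idx.genotype, idx.environment]
                + B[idx.environment, idx.replication]
                + rng.normal(0, np.sqrt(var_R), len(idx)))
    return idx


class TestCorrelationPair:
    def test_identity_and_reversal(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 11.0])
        assert correlation_pair(x, x) == pytest.approx((1.0, 1.0))
        assert correlation_pair(x, -x) == pytest.approx((-1.0, -1.0))

    def test_allometric_slope_recovery(self):
        rng = np.random.default_rng(0)
        b, c, sigma = 0.75, 2.0, 0.05
        x = rng.uniform(1, 50, 200)
        y = c * x**b * np.exp(rng.normal(0, sigma, 200))
        slope = np.polyfit(np.log(x), np.log(y), 1)[0]
        se = sigma / (np.log(x).std() * np.sqrt(200))
        assert slope == pytest.approx(b, abs=max(4 * se, 0.02))
        r, rho = correlation_pair(x, y, log_log=True)
        assert r > 0.97 and rho > 0.97

    def test_log_log_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            correlation_pair([1, 2, -3], [1, 2, 3], log_log=True)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlation_pair([1, 2], [3, 4])


class TestVarianceComponents:
    def test_zero_noise_genotype_only(self):
        table = balanced_table(var_G=4, var_GE=0, var_R=0, var_B=0)
        table["y"] = table["genotype"].map(
            dict(enumerate(np.random.default_rng(1).normal(0, 2, 20))))
        comp = estimate_variance_components(table, "y", anova=False)
        assert comp.var_R == pytest.approx(0.0, abs=1e-10)
        assert comp.var_GxE == pytest.approx(0.0, abs=1e-10)
        assert comp.var_G > 0

    def test_shuffled_genotype_labels_kill_var_G(self):
        # permuting phenotypes across the whole design detaches them from
        # genotype labels: the genetic variance estimate collapses
        rng = np.random.default_rng(2)
        ests = []
        for seed in range(20):
            table = balanced_table(var_G=4, seed=seed)
            table["y"] = rng.permutation(table["y"].to_numpy())
            comp = estimate_variance_components(table, "y", anova=False)
            ests.append(comp.var_G)
        assert np.mean(ests) < 1.0  # true var_G was 4

    def test_recovery_on_balanced_design(self):
        ests = []
        for seed in range(120):
            comp = estimate_variance_components(
                balanced_table(seed=seed), "y", anova=False)
            ests.append([comp.var_G, comp.var_GxE, comp.var_R])
        mean = np.mean(ests, axis=0)
        np.testing.assert_allclose(mean, [4.0, 1.0, 2.0], rtol=0.15)

    def test_anova_significance_reported(self):
        comp = estimate_variance_components(balanced_table(seed=3), "y")
        assert set(comp.anova_p) == {"G", "E", "GxE"}
        assert comp.anova_p["G"] < 0.01  # strong genotype signal

    def test_single_genotype_rejected(self):
        table = balanced_table()
        table["genotype"] = 0
        with pytest.raises(ValueError, match="genotype"):
            estimate_variance_components(table, "y")

    def test_single_environment_flags_gxe_undefined(self):
        table = balanced_table(t=1)
        with pytest.warns(UserWarning, match="GxE"):
            comp = estimate_variance_components(table, "y", anova=False)
        assert not comp.gxe_defined
        assert np.isnan(comp.var_GxE)

    def test_unbalanced_falls_back_to_reml(self):
        table = balanced_table(seed=4).drop(index=[0, 9, 30])
        comp = estimate_variance_components(table, "y", anova=False)
        assert comp.method == "reml"
        assert comp.var_G >= 0 and comp.var_R >= 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            estimate_variance_components(pd.DataFrame({"y": [1, 2]}), "y")


class TestRepeatability:
    def test_plug_in_value(self):
        assert repeatability(4, 1, 2, t=2, r=2) == pytest.approx(0.8)

    def test_perfect_when_no_noise(self):
        assert repeatability(5, 0, 0, t=2, r=2) == 1.0

    def test_zero_when_no_genetic_variance(self):
        assert repeatability(0, 1, 2, t=2, r=2) == 0.0

    def test_per_environment_formula(self):
        assert repeatability(4, np.nan, 2, t=1, r=2, per_env=True) \
            == pytest.approx(4 / 5)

    def test_all_zero_components_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            repeatability(0, 0, 0, t=2, r=2)

    def test_monotonicity_in_var_G_t_r(self):
        grid = np.linspace(0.5, 8, 12)
        vals_G = [repeatability(v, 1, 2, 2, 2) for v in grid]
        vals_t = [repeatability(4, 1, 2, t, 2) for t in grid]
        vals_r = [repeatability(4, 1, 2, 2, r) for r in grid]
        for vals in (vals_G, vals_t, vals_r):
            assert np.all(np.diff(vals) > 0)

    def test_full_analysis_on_balanced_table(self):
        result = repeatability_analysis(balanced_table(seed=5), "y")
        assert 0 <= result.R_overall <= 1
        assert result.t_harmonic == 2.0
        assert result.r_harmonic == 2.0
        assert set(result.R_per_env) == {0, 1}
        for v in result.R_per_env.values():
            assert 0 <= v <= 1

    def test_harmonic_means_with_missing_cells(self):
        table = balanced_table(seed=6)
        table = table[~((table.genotype == 0) & (table.environment == 1))]
        t, r = harmonic_design_means(table, "y")
        assert t < 2.0
        assert r == 2.0


class TestQtlSupport:
    def test_pve_monotone_and_bounded(self):
        lods = np.linspace(0, 60, 50)
        pves = [pve_from_lod(l, 316) for l in lods]
        assert pves[0] == 0.0
        assert np.all(np.diff(pves) > 0)
        assert all(0 <= v < 100 for v in pves)

    def test_marker_parsing(self):
        assert parse_marker("S2_43085743") == (2, 43085743)
        for bad in ("X2_100", "S2-100", "S_100", "S2_"):
            with pytest.raises(ValueError, match="unparseable"):
                parse_marker(bad)

    def test_identical_markers_zero_width(self):
        assert lod_interval_width_mb("S3_500000", "S3_500000") == 0.0

    def test_chromosome_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            lod_interval_width_mb("S1_100", "S2_200")

    def test_support_table_on_bundled_qtl_data(self):
        table = load_qtl_table()
        out = qtl_support_table(table)
        assert {"pve", "interval_mb"} <= set(out.columns)
        assert (out["pve"] > 0).all()
        assert (out["interval_mb"] >= 0).all()
        row = out.set_index("qtl_name").loc["ht-2.1"]
        assert row["pve"] == pve_from_lod(row["lod"], 316).__round__(2)
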