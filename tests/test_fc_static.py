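"""Static connectivity: pairwise FC, GFC, dual regression, segregation."""

import numpy as np
import pytest

from psyfusion.containers import FCMatrix, NetworkPartition, ParcelTimeSeries
from psyfusion.fc_static import (
    binary_templates,
    dual_regression_stage1,
    gfc,
    global_signal_regress,
    integrity_dual_regression,
    network_templates,
    paired_contrast,
    pairwise_fc,
    segregation,
)
from psyfusion.stats import fisher_z


def make_ts(data, **kw):
    n, r = np.asarray(data).shape
    defaults = dict(tr_seconds=2.0, region_labels=[f"R{i}" for i in range(r)],
                    subject="s", condition="placebo", injection_index=0)
    defaults.update(kw)
    return ParcelTimeSeries(data=np.asarray(data, float), **defaults)


class TestPairwiseFC:
    def test_identical_series_hit_the_fisher_cap(self, rng):
        x = rng.normal(size=200)
        ts = make_ts(np.column_stack([x, x, rng.normal(size=200)]))
        fc = pairwise_fc(ts)
        cap = fisher_z(1.0)
        assert fc.values[0, 1] == pytest.approx(cap)
        np.testing.assert_allclose(fc.values, fc.values.T)

    def test_independent_noise_mean_z_near_zero(self, rng):
        ts = make_ts(rng.normal(size=(2000, 12)))
        fc = pairwise_fc(ts)
        off = fc.offdiag()
        assert abs(np.nanmean(off)) < 0.05

    def test_planted_pairwise_correlation_value(self, rng):
        # r12 = 0.5 planted through a shared component; z = arctanh(0.5)
        n = 200_000
        shared = rng.normal(size=n)
        x1 = shared + rng.normal(size=n)
        x2 = shared + rng.normal(size=n)
        x3 = rng.normal(size=n)
        fc = pairwise_fc(make_ts(np.column_stack([x1, x2, x3])))
        assert fc.values[0, 1] == pytest.approx(0.5493, abs=0.01)
        assert abs(fc.values[0, 2]) < 0.02

    def test_zero_variance_region_propagates_missing(self, rng):
        data = rng.normal(size=(100, 3))
        data[:, 1] = 5.0
        fc = pairwise_fc(make_ts(data))
        assert np.isnan(fc.values[0, 1]) and np.isnan(fc.values[1, 2])
        assert np.isfinite(fc.values[0, 2])

    def test_censored_volumes_excluded(self, rng):
        data = rng.normal(size=(300, 2))
        spiked = data.copy()
        spiked[:50] += 40.0
        mask = np.ones(300, bool)
        mask[:50] = False
        fc_clean = pairwise_fc(make_ts(data[50:]))
        fc_masked = pairwise_fc(make_ts(spiked, censor_mask=mask))
        assert fc_masked.values[0, 1] == pytest.approx(fc_clean.values[0, 1])

    def test_short_window_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_fc(make_ts(rng.normal(size=(10, 3))), slice(0, 2))


class TestGFC:
    def labels(self, n):
        return NetworkPartition([f"R{i}" for i in range(n)], ["VIS"] * n)

    def test_identity_structure_gives_zero_gfc(self):
        fc = FCMatrix(np.zeros((4, 4)), [f"R{i}" for i in range(4)])
        g = gfc(fc, self.labels(4))
        np.testing.assert_allclose(g.region_gfc, 0)
        assert g.whole_brain == 0

    def test_hand_computed_row_mean(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 0.5493
        g = gfc(FCMatrix(z, ["a", "b", "c"]), self.labels(3))
        assert g.region_gfc[0] == pytest.approx(0.27465, abs=1e-4)

    def test_constant_shift_linearity(self, rng):
        z = rng.normal(size=(6, 6))
        z = (z + z.T) / 2
        labels = [f"R{i}" for i in range(6)]
        g0 = gfc(FCMatrix(z, labels), self.labels(6))
        c = 0.37
        zc = z + c * (1 - np.eye(6))
        g1 = gfc(FCMatrix(zc, labels), self.labels(6))
        np.testing.assert_allclose(g1.region_gfc, g0.region_gfc + c, atol=1e-12)

    def test_network_gfc_is_mean_of_members(self, rng):
        z = rng.normal(size=(5, 5))
        z = (z + z.T) / 2
        part = NetworkPartition([f"R{i}" for i in range(5)],
                                ["VIS", "VIS", "DMN", "DMN", "DMN"])
        g = gfc(FCMatrix(z, part.region_labels), part)
        assert g.network_gfc["DMN"] == pytest.approx(g.region_gfc[2:].mean())
        assert g.whole_brain == pytest.approx(g.region_gfc.mean())


class TestDualRegression:
    def test_exact_recovery_on_noise_free_construction(self, rng):
        templates = np.array([[1.0, 1.0, 0.0, 0.0, 0.0],
                              [0.0, 0.0, 1.0, 1.0, 1.0]])
        series = rng.normal(size=(2, 300))
        data = series.T @ templates
        s1 = dual_regression_stage1(data, templates)
        np.testing.assert_allclose(s1, series, atol=1e-8)

    def test_stage1_series_scale_with_spatial_amplitude(self, rng):
        # halving one template's spatial amplitude in the data halves its
        # recovered time series, exactly, and leaves the other untouched
        part = NetworkPartition([f"R{i}" for i in range(6)],
                                ["VIS"] * 3 + ["DMN"] * 3)
        templates = network_templates(part)
        series = rng.normal(size=(2, 400))
        scaled_maps = templates * np.array([[0.5], [1.0]])
        s1 = dual_regression_stage1(series.T @ scaled_maps, templates)
        np.testing.assert_allclose(s1[0], 0.5 * series[0], atol=1e-8)
        np.testing.assert_allclose(s1[1], series[1], atol=1e-8)

    def test_noise_free_dual_regression_is_scale_self_normalizing(self, rng):
        # both stages adapt, so pure amplitude scaling leaves the PE maps
        # unchanged on noise-free data -- integrity changes must come from
        # noise or pattern mismatch, not global scale
        part = NetworkPartition([f"R{i}" for i in range(6)],
                                ["VIS"] * 3 + ["DMN"] * 3)
        templates = network_templates(part)
        series = rng.normal(size=(2, 400))
        full = integrity_dual_regression(
            make_ts(series.T @ templates), templates, ["VIS", "DMN"])
        scaled = integrity_dual_regression(
            make_ts((series * [[0.5], [1.0]]).T @ templates), templates,
            ["VIS", "DMN"])
        assert scaled.pe["VIS"] == pytest.approx(full.pe["VIS"], abs=1e-8)
        assert full.pe["VIS"] == pytest.approx(1.0, abs=1e-8)

    def test_integrity_drops_with_coupling_loss_under_noise(self, rng):
        # the actual integrity mechanism: weaker within-network coupling
        # against a fixed noise floor lowers the mean stage-2 PE
        part = NetworkPartition([f"R{i}" for i in range(8)],
                                ["VIS"] * 4 + ["DMN"] * 4)
        templates = network_templates(part)
        series = rng.normal(size=(2, 4000))
        noise = rng.normal(size=(4000, 8))
        strong = integrity_dual_regression(
            make_ts(series.T @ templates + noise), templates, ["VIS", "DMN"])
        weak_maps = templates * np.array([[0.4], [1.0]])
        weak = integrity_dual_regression(
            make_ts(series.T @ weak_maps + noise), templates, ["VIS", "DMN"])
        assert weak.pe["VIS"] < strong.pe["VIS"]
        assert weak.pe["DMN"] == pytest.approx(strong.pe["DMN"], abs=0.05)

    def test_orthogonal_templates_independent_sources_cross_pe_near_zero(self, rng):
        templates = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        series = rng.normal(size=(2, 5000))
        data = series.T @ templates + 0.1 * rng.normal(size=(5000, 4))
        res = integrity_dual_regression(make_ts(data), templates, ["A", "B"])
        assert abs(res.pe_maps[0, 2:]).max() < 0.05
        assert abs(res.pe_maps[1, :2]).max() < 0.05

    def test_rank_deficient_templates_rejected(self, rng):
        t = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            integrity_dual_regression(make_ts(rng.normal(size=(50, 2))), t, ["A", "B"])

    def test_binary_templates_are_membership_indicators(self):
        part = NetworkPartition(["a", "b", "c"], ["VIS", "DMN", "DMN"])
        t = binary_templates(part)
        np.testing.assert_array_equal(t, [[1, 0, 0], [0, 1, 1]])


class TestSegregation:
    def test_identical_unit_variance_series(self, rng):
        x = rng.normal(size=300)
        out = segregation(np.stack([x, x]), ["A", "B"])
        assert out.loc["A", "B"] == pytest.approx(1.0)

    def test_independent_series_near_zero(self, rng):
        out = segregation(rng.normal(size=(3, 20000)), ["A", "B", "C"])
        assert abs(out.loc["A", "B"]) < 0.03

    def test_directed_estimates_are_arithmetically_averaged(self, rng):
        # x_b = x_a / 2 exactly: slope(a|b) = 2, slope(b|a) = 0.5 -> 1.25
        a = rng.normal(size=500)
        out = segregation(np.stack([a, a / 2]), ["A", "B"])
        assert out.loc["A", "B"] == pytest.approx(1.25)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            segregation(np.stack([np.ones(50), np.zeros(50)]), ["A", "B"])


class TestPairedContrast:
    def test_matches_brute_force_on_random_tables(self, rng):
        from scipy import stats as sps

        drug = rng.normal(size=(8, 5))
        plac = rng.normal(size=(8, 5))
        res = paired_contrast(drug, plac, list("abcde"), family="test")
        for i in range(5):
            t_ref, p_ref = sps.ttest_rel(drug[:, i], plac[:, i])
            assert res.t[i] == pytest.approx(t_ref)
            assert res.p[i] == pytest.approx(p_ref)

    def test_degenerate_and_identical_columns(self):
        drug = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0], [1.0, 5.0]])
        plac = np.array([[0.0, 2.0], [0.0, 3.0], [0.0, 4.0], [0.0, 5.0]])
        res = paired_contrast(drug, plac, ["shift", "same"], family="test")
        assert res.degenerate[0] and res.p[0] == np.finfo(float).tiny
        assert res.t[1] == 0 and res.p[1] == 1.0


class TestGlobalSignalRegression:
    def test_output_orthogonal_to_global_mean(self, rng):
        ts = make_ts(rng.normal(size=(200, 5)) + rng.normal(size=(200, 1)))
        out = global_signal_regress(ts)
        gs = ts.data.mean(axis=1)
        for i in range(5):
            assert abs(np.corrcoef(out.data[:, i], gs)[0, 1]) < 1e-10

    def test_idempotent(self, rng):
        ts = make_ts(rng.normal(size=(100, 4)))
        once = global_signal_regress(ts)
        twice = global_signal_regress(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)

    def test_removes_constant_offsets(self, rng):
        ts = make_ts(rng.normal(size=(150, 3)) + np.array([5.0, -2.0, 9.0]))
        out = global_signal_regress(ts)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10
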