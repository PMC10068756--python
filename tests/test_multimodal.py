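"""EEG -> BOLD fusion: electrode selection, hemodynamic conversion, LMM."""

import numpy as np
import pytest
from scipy import signal as spsig

from psyfusion.containers import Cluster, ClusterTestResult
from psyfusion.multimodal import (
    FusedTrace,
    HRFSpec,
    clean_epoch_trace,
    eeg_fmri_lmm,
    eeg_to_bold_timecourse,
    network_dgfc,
    select_electrodes,
)

CHANNELS = ["Fp1", "Fp2", "F3", "F4", "P3", "P4", "Pz", "Oz"]


def cluster_result(t_values, members, mass=10.0, p=0.01):
    return ClusterTestResult([Cluster(tuple(members), mass, p)],
                             np.asarray(t_values, float), 2.0, 100)


class TestSelectElectrodes:
    def test_lateral_top_pairs_with_contralateral(self):
        t = np.zeros(8)
        t[4] = 5.0  # P3
        out = select_electrodes(cluster_result(t, [4, 5, 6]), CHANNELS)
        assert out == ["P3", "P4"]

    def test_midline_top_pairs_with_itself(self):
        t = np.zeros(8)
        t[6] = -6.0  # Pz, sign must not matter
        out = select_electrodes(cluster_result(t, [5, 6]), CHANNELS)
        assert out == ["Pz"]

    def test_tie_breaks_to_lexicographically_smallest(self):
        t = np.zeros(8)
        t[0] = t[1] = 4.0  # Fp1 and Fp2 tie
        out = select_electrodes(cluster_result(t, [0, 1]), CHANNELS)
        assert out == ["Fp1", "Fp2"]

    def test_missing_mirror_falls_back_with_warning(self):
        channels = ["P3", "Pz", "Oz"]
        t = np.array([5.0, 1.0, 1.0])
        with pytest.warns(RuntimeWarning, match="contralateral"):
            out = select_electrodes(cluster_result(t, [0]), channels)
        assert out == ["P3"]

    def test_empty_result_rejected(self):
        empty = ClusterTestResult([], np.zeros(3), 2.0, 100)
        with pytest.raises(ValueError):
            select_electrodes(empty, CHANNELS)


class TestHRF:
    def test_kernel_integrates_to_one_with_positive_peak(self):
        h = HRFSpec().kernel(dt=2.0)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.max() > 0

    def test_impulse_response_peaks_4_to_8_seconds(self):
        dt = 0.5
        h = HRFSpec().kernel(dt=dt)
        assert 4.0 <= np.argmax(h) * dt <= 8.0
        # undershoot follows the peak
        assert h[int(14 / dt) : int(20 / dt)].min() < 0


class TestCleanTrace:
    def test_outliers_above_5sd_interpolated(self, rng):
        x = rng.normal(size=200)
        x[50] = 100.0
        filled, valid = clean_epoch_trace(x)
        assert abs(filled[50]) < 5
        assert valid[50]  # outlier is replaced, not masked

    def test_missing_epochs_masked_not_interpolated_downstream(self, rng):
        x = rng.normal(size=100)
        x[10:20] = np.nan
        filled, valid = clean_epoch_trace(x)
        assert not valid[10:20].any()
        assert np.isfinite(filled).all()

    def test_majority_missing_rejected(self, rng):
        x = np.full(50, np.nan)
        x[:20] = rng.normal(size=20)
        with pytest.raises(ValueError):
            clean_epoch_trace(x)


class TestHemodynamicConversion:
    grid = np.arange(30.0, 800.0, 2.0)

    def test_constant_trace_maps_to_zero(self):
        out = eeg_to_bold_timecourse(np.full(420, 3.3), 2.0, self.grid)
        assert np.abs(out.values[out.valid]).max() < 1e-6

    def test_bandpass_frequency_response(self, rng):
        fs = 0.5
        t = np.arange(840) / fs
        sos = spsig.butter(2, (0.01, 0.08), btype="bandpass", fs=fs, output="sos")
        for freq, lo_gain, hi_gain in ((0.05, 0.7, 1.3), (0.2, 0.0, 0.2)):
            x = np.sin(2 * np.pi * freq * t)
            y = spsig.sosfiltfilt(sos, x)
            gain = y[100:-100].std() / x[100:-100].std()
            assert lo_gain <= gain <= hi_gain, freq

    def test_pipeline_is_linear(self, rng):
        a = rng.normal(size=420)
        b = rng.normal(size=420)
        fa = eeg_to_bold_timecourse(a, 2.0, self.grid)
        fb = eeg_to_bold_timecourse(b, 2.0, self.grid)
        fab = eeg_to_bold_timecourse(a + b, 2.0, self.grid)
        np.testing.assert_allclose(fab.values, fa.values + fb.values, atol=1e-8)

    def test_output_on_window_grid_with_edge_trim(self, rng):
        grid = np.arange(2.0, 800.0, 2.0)
        out = eeg_to_bold_timecourse(rng.normal(size=420), 2.0, grid)
        assert out.values.shape == grid.shape
        assert not out.valid[grid < 17.0].any()   # one filter length trimmed
        assert out.valid[(grid > 30) & (grid < 700)].all()


def make_fused(values, valid=None, grid=None):
    values = np.asarray(values, float)
    if valid is None:
        valid = np.ones(values.size, bool)
    if grid is None:
        grid = np.arange(values.size, dtype=float)
    return FusedTrace(values, valid, grid)


class TestFusionLMM:
    def test_noiseless_coupling_recovered_exactly(self, rng):
        n_subj, n_win = 4, 150
        dgfc = rng.normal(size=(n_subj, 3, n_win))
        fused = [make_fused(3.0 * dgfc[s, 1] + s) for s in range(n_subj)]
        res = eeg_fmri_lmm(fused, dgfc, ["r0", "r1", "r2"],
                           [f"s{i}" for i in range(n_subj)])
        assert res.beta[1] == pytest.approx(3.0, abs=1e-6)

    def test_independent_traces_mostly_nonsignificant(self, rng):
        n_subj, n_units, n_win = 8, 24, 120
        dgfc = rng.normal(size=(n_subj, n_units, n_win))
        fused = [make_fused(rng.normal(size=n_win)) for _ in range(n_subj)]
        res = eeg_fmri_lmm(fused, dgfc, [f"r{i}" for i in range(n_units)],
                           [f"s{i}" for i in range(n_subj)])
        assert (res.q > 0.05).mean() >= 0.95

    def test_masked_windows_never_contribute(self, rng):
        n_subj, n_win = 4, 100
        dgfc = rng.normal(size=(n_subj, 1, n_win))
        valid = np.ones(n_win, bool)
        valid[40:60] = False
        clean = [make_fused(2.0 * dgfc[s, 0], valid.copy()) for s in range(n_subj)]
        poisoned = []
        for s in range(n_subj):
            vals = 2.0 * dgfc[s, 0].copy()
            vals[~valid] = 1e6  # poison masked windows
            poisoned.append(make_fused(vals, valid.copy()))
        r_clean = eeg_fmri_lmm(clean, dgfc, ["u"], list("abcd"))
        r_poison = eeg_fmri_lmm(poisoned, dgfc, ["u"], list("abcd"))
        assert r_poison.beta[0] == pytest.approx(r_clean.beta[0], abs=1e-9)

    def test_direction_flag_swaps_response_and_predictor(self, rng):
        n_subj, n_win = 4, 200
        dgfc = rng.normal(size=(n_subj, 1, n_win))
        fused = [make_fused(0.5 * dgfc[s, 0] + 0.01 * rng.normal(size=n_win))
                 for s in range(n_subj)]
        fwd = eeg_fmri_lmm(fused, dgfc, ["u"], list("abcd"), eeg_as_response=True)
        rev = eeg_fmri_lmm(fused, dgfc, ["u"], list("abcd"), eeg_as_response=False)
        assert fwd.beta[0] == pytest.approx(0.5, abs=0.01)
        assert rev.beta[0] == pytest.approx(2.0, abs=0.1)

    def test_within_subject_model_beats_trace_averaging(self):
        """With heterogeneous per-subject couplings, the mixed model detects
        the association far more often than correlating subject-averaged
        traces (which discards within-subject covariation)."""
        from scipy import stats as sps

        lmm_hits = avg_hits = 0
        n_sims = 25
        for i in range(n_sims):
            rng = np.random.default_rng(3000 + i)
            n_subj, n_win = 10, 150
            dgfc = rng.normal(size=(n_subj, 1, n_win))
            slopes = rng.uniform(0.2, 0.8, size=n_subj)
            fused = [make_fused(slopes[s] * dgfc[s, 0]
                                + 0.8 * rng.normal(size=n_win))
                     for s in range(n_subj)]
            res = eeg_fmri_lmm(fused, dgfc, ["u"],
                               [f"s{j}" for j in range(n_subj)])
            lmm_hits += res.p[0] < 0.05
            # averaging approach: time-average per subject, then correlate
            # across subjects -- within-subject covariation is discarded
            subj_eeg = np.array([f.values.mean() for f in fused])
            subj_fc = dgfc[:, 0, :].mean(axis=1)
            avg_hits += sps.pearsonr(subj_eeg, subj_fc).pvalue < 0.05
        assert lmm_hits > avg_hits
        assert lmm_hits >= 0.8 * n_sims

    def test_grid_misalignment_rejected(self, rng):
        dgfc = rng.normal(size=(3, 1, 50))
        fused = [make_fused(rng.normal(size=40)) for _ in range(3)]
        with pytest.raises(ValueError):
            eeg_fmri_lmm(fused, dgfc, ["u"], list("abc"))


def test_network_dgfc_averages_members(rng):
    from psyfusion.synthetic import default_partition

    part = default_partition(16)
    diff = rng.normal(size=(3, 16, 20))
    out, nets = network_dgfc(diff, part)
    assert out.shape == (3, len(nets), 20)
    first = nets[0]
    np.testing.assert_allclose(out[:, 0], diff[:, part.members(first)].mean(axis=1))
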