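"""EEG -> BOLD fusion: hemodynamic conversion and mixed-effects coupling.

Per-epoch EEG feature traces are cleaned (5-SD outliers interpolated,
missing epochs masked), band-pass filtered to the BOLD range
(0.01-0.08 Hz, zero-phase), convolved with the canonical double-gamma
HRF, smoothed with the same 6-s Gaussian as the sliding-window taper and
resampled onto the dynamic-FC window grid.  Per-region couplings with
dynamic GFC are then estimated with random-intercept + random-slope mixed
models; following the source analysis convention, the EEG trace is the
response and the region's dynamic GFC the predictor (swappable by flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

from .containers import ClusterTestResult
from .montage import mirror_channel
from .stats import LMMResult, bh_fdr, fit_mixed_model


@dataclass
class HRFSpec:
    """Canonical double-gamma HRF (SPM convention).

    The kernel is scaled to integrate to exactly 1, so convolving a slow
    signal leaves its scale unchanged.
    """

    peak_seconds: float = 6.0
    undershoot_seconds: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    length_seconds: float = 32.0

    def kernel(self, dt: float) -> np.ndarray:
        t = np.arange(0.0, self.length_seconds + dt / 2, dt)
        h = gamma_dist.pdf(t, self.peak_seconds) \
            - self.undershoot_ratio * gamma_dist.pdf(t, self.undershoot_seconds)
        return h / (h.sum() * 1.0)


@dataclass
class FusedTrace:
    """EEG-derived trace on the dynamic-FC window grid, with validity mask."""

    values: np.ndarray
    valid: np.ndarray
    grid_seconds: np.ndarray
    measure: str = ""
    subject: str = ""


def select_electrodes(result: ClusterTestResult, channel_names) -> list[str]:
    """Top-|t| electrode of the strongest cluster plus its contralateral pair.

    Midline electrodes pair with themselves; an electrode whose mirror is
    not in the montage falls back to a singleton with a warning.  Ties in
    |t| resolve to the lexicographically smallest label.
    """
    if not result.clusters:
        raise ValueError("empty cluster result")
    best = max(result.clusters, key=lambda c: abs(c.mass))
    members = list(best.members)
    tvals = np.abs(result.t_values[members])
    top = max(zip(tvals, (channel_names[m] for m in members)),
              key=lambda pair: (pair[0], [-ord(c) for c in pair[1]]))[1]
    mirror = mirror_channel(top)
    if mirror == top:
        return [top]
    if mirror not in channel_names:
        warnings.warn(f"no contralateral partner for {top}; using it alone",
                      RuntimeWarning)
        return [top]
    return sorted([top, mirror])


def clean_epoch_trace(trace: np.ndarray, sd_limit: float = 5.0):
    """Interpolate >5-SD outliers; keep missing (NaN) epochs as a mask."""
    x = np.asarray(trace, dtype=float).copy()
    valid = np.isfinite(x)
    if valid.mean() < 0.5:
        raise ValueError("more than 50% of epochs missing")
    mu = x[valid].mean()
    sd = x[valid].std()
    outlier = valid & (x > mu + sd_limit * sd)
    keep = valid & ~outlier
    idx = np.arange(x.size)
    x[outlier] = np.interp(idx[outlier], idx[keep], x[keep])
    # gaps are filled only so the filter can run; the mask excludes them later
    filled = x.copy()
    filled[~valid] = np.interp(idx[~valid], idx[keep], x[keep])
    return filled, valid


def eeg_to_bold_timecourse(
    trace: np.ndarray,
    epoch_seconds: float,
    window_centers_seconds: np.ndarray,
    hrf: HRFSpec | None = None,
    band: tuple = (0.01, 0.08),
    smooth_sd_seconds: float = 6.0,
    trim_seconds: float = 16.0,
    measure: str = "",
    subject: str = "",
) -> FusedTrace:
    """Convert a per-epoch EEG trace into the hemodynamic frame.

    Pipeline: 5-SD outlier interpolation -> zero-phase order-2 Butterworth
    band-pass (0.01-0.08 Hz) -> canonical HRF convolution -> 6-s Gaussian
    smoothing -> linear resampling to the window-center grid.  Windows
    within one filter length of an edge, or nearest to a missing epoch,
    are masked out.
    """
    hrf = hrf or HRFSpec()
    fs = 1.0 / epoch_seconds
    filled, valid = clean_epoch_trace(trace)
    sos = spsig.butter(2, band, btype="bandpass", fs=fs, output="sos")
    filtered = spsig.sosfiltfilt(sos, filled)
    kernel = hrf.kernel(epoch_seconds)
    convolved = np.convolve(filtered, kernel)[: filtered.size]
    smoothed = gaussian_filter1d(convolved, smooth_sd_seconds * fs, mode="nearest")

    epoch_times = (np.arange(trace.size) + 0.5) * epoch_seconds
    grid = np.asarray(window_centers_seconds, dtype=float)
    values = np.interp(grid, epoch_times, smoothed)
    nearest = np.clip(np.round(grid / epoch_seconds - 0.5).astype(int), 0, trace.size - 1)
    mask = valid[nearest]
    mask &= (grid >= epoch_times[0] + trim_seconds)
    mask &= (grid <= epoch_times[-1] - trim_seconds)
    return FusedTrace(values, mask, grid, measure=measure, subject=subject)


def eeg_fmri_lmm(
    fused: list,
    dgfc_diff: np.ndarray,
    units,
    subjects,
    family: str = "regions",
    eeg_as_response: bool = True,
) -> LMMResult:
    """Per-unit mixed model coupling fused EEG traces to dynamic FC.

    ``fused`` is one :class:`FusedTrace` per subject (condition-differenced
    EEG measure on the window grid); ``dgfc_diff`` is subjects x units x
    windows.  Masked windows never enter the fit.  By default the EEG
    trace is the response and the unit's dGFC the predictor.
    """
    dgfc = np.asarray(dgfc_diff, dtype=float)
    n_subj, n_units, n_win = dgfc.shape
    if len(fused) != n_subj:
        raise ValueError("one fused trace per subject required")
    for f in fused:
        if f.values.size != n_win:
            raise ValueError("fused trace grid misaligned with dGFC windows")
    beta = np.full(n_units, np.nan)
    se = np.full(n_units, np.nan)
    t = np.full(n_units, np.nan)
    p = np.ones(n_units)
    conv = np.zeros(n_units, dtype=bool)
    flags = []
    masks = [f.valid for f in fused]
    for u in range(n_units):
        ys, xs, gs = [], [], []
        for s in range(n_subj):
            m = masks[s]
            eeg = fused[s].values[m]
            fc = dgfc[s, u, m]
            resp, pred = (eeg, fc) if eeg_as_response else (fc, eeg)
            ys.append(resp)
            xs.append(pred)
            gs.append(np.full(m.sum(), s))
        fit = fit_mixed_model(np.concatenate(ys), np.concatenate(xs), np.concatenate(gs))
        beta[u], se[u], t[u], p[u] = fit.beta, fit.se, fit.t, fit.p
        conv[u] = fit.converged
        flags.append(fit.flag)
    q = bh_fdr(p, family=family).q_values
    return LMMResult(list(units), beta, se, t, p, q, conv, flags, family)


def network_dgfc(dgfc_diff: np.ndarray, partition) -> tuple[np.ndarray, list]:
    """Average member-region dGFC traces per network: subjects x nets x windows."""
    nets = partition.present_networks
    out = np.stack(
        [dgfc_diff[:, partition.members(n), :].mean(axis=1) for n in nets], axis=1
    )
    return out, nets
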