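"""Tapered sliding-window dynamic connectivity and its statistics.

Windows of 22 volumes (44 s at TR 2 s) are convolved with a Gaussian taper
of 3 volumes (6 s) truncated at +/-3 sd and renormalized, stepped every
volume.  Dynamic GFC traces are contrasted between conditions with
temporal cluster statistics, associated with covariate traces (subjective
intensity, plasma level, or EEG-derived) through per-unit mixed-effects
models, and per-region slope maps are correlated against receptor density
with a region-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .clusterperm import signflip_cluster_test
from .containers import (
    ClusterTestResult,
    DynamicFCSeries,
    IntensityTrace,
    NetworkPartition,
    ParcelTimeSeries,
    ReceptorMap,
)
from .stats import LMMResult, fisher_z, lmm_per_unit

#: Gaussian smoothing applied to covariate traces, in seconds (the 6-s
#: kernel of the sliding-window taper, sd = 3 volumes at TR 2 s).
COVARIATE_SMOOTH_SD_SECONDS = 6.0


@dataclass
class WindowSpec:
    """Tapered sliding-window parameters, in volumes."""

    window_volumes: int = 22
    taper_sd_volumes: float = 3.0
    step_volumes: int = 1

    def __post_init__(self) -> None:
        if self.window_volumes < 3:
            raise ValueError("window must span at least 3 volumes")
        if self.taper_sd_volumes < 0:
            raise ValueError("taper sd must be nonnegative")
        if self.step_volumes < 1:
            raise ValueError("step must be at least 1 volume")


def tapered_window_weights(spec: WindowSpec, n_volumes: int) -> tuple[np.ndarray, np.ndarray]:
    """Window weight matrix (windows x volumes) and window centers (volumes).

    Each window is a boxcar of ``window_volumes`` convolved with a Gaussian
    of sd ``taper_sd_volumes`` truncated at +/-3 sd, cropped to the series
    and renormalized to sum 1.  A zero taper reproduces the plain boxcar.
    """
    w, sd, step = spec.window_volumes, spec.taper_sd_volumes, spec.step_volumes
    if w > n_volumes:
        raise ValueError("window longer than the series")
    if sd > 0:
        radius = max(1, int(round(3 * sd)))
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sd) ** 2)
        profile = np.convolve(np.ones(w), k / k.sum())
    else:
        radius = 0
        profile = np.ones(w)
    starts = np.arange(0, n_volumes - w + 1, step)
    weights = np.zeros((starts.size, n_volumes))
    for i, s in enumerate(starts):
        lo = s - radius
        a, b = max(lo, 0), min(lo + profile.size, n_volumes)
        weights[i, a:b] = profile[a - lo : b - lo]
    weights /= weights.sum(axis=1, keepdims=True)
    centers = starts + (w - 1) / 2.0
    return weights, centers


def dynamic_fc(ts: ParcelTimeSeries, spec: WindowSpec | None = None) -> DynamicFCSeries:
    """Weighted Pearson correlation per window per region pair, Fisher-z.

    Censored volumes receive zero weight (with renormalization); a window
    left with fewer than 3 effective volumes raises.
    """
    spec = spec or WindowSpec()
    x = ts.data
    n, R = x.shape
    weights, centers = tapered_window_weights(spec, ts.n_volumes)
    weights = weights * ts.censor_mask[None, :]
    effective = (weights > 0).sum(axis=1)
    if np.any(effective < 3):
        raise ValueError("window with fewer than 3 effective volumes")
    weights = weights / weights.sum(axis=1, keepdims=True)

    # every window's support is a contiguous run of at most L volumes;
    # gather padded copies so all windows batch into one matmul
    n_w = weights.shape[0]
    starts = np.arange(0, n - spec.window_volumes + 1, spec.step_volumes)
    radius = max(1, int(round(3 * spec.taper_sd_volumes))) if spec.taper_sd_volumes > 0 else 0
    L = spec.window_volumes + 2 * radius
    xp = np.vstack([np.zeros((radius, R)), x, np.zeros((radius + L, R))])
    wp = np.hstack([np.zeros((n_w, radius)), weights, np.zeros((n_w, radius + L))])
    rows = starts[:, None] + np.arange(L)[None, :]             # padded coords
    Xw = xp[rows]                                              # n_w x L x R
    Wv = np.take_along_axis(wp, rows, axis=1)                  # n_w x L
    M = np.einsum("wl,wlr->wr", Wv, Xw)
    S = np.matmul((Xw * Wv[:, :, None]).transpose(0, 2, 1), Xw)
    cov = S - M[:, :, None] * M[:, None, :]
    d = np.sqrt(np.clip(np.einsum("wii->wi", cov), 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (d[:, :, None] * d[:, None, :])
    stack = fisher_z(r)
    return DynamicFCSeries(stack, centers * ts.tr_seconds, list(ts.region_labels))


@dataclass
class DynamicGFC:
    """Windowed GFC traces at region and network level."""

    region: np.ndarray          # regions x windows
    network: dict               # network -> windows trace
    whole_brain: np.ndarray     # windows
    window_centers: np.ndarray
    region_labels: list


def dynamic_gfc(dfc: DynamicFCSeries, partition: NetworkPartition) -> DynamicGFC:
    """Per-window GFC: mean off-diagonal Fisher z per region row."""
    stack = dfc.stack
    R = stack.shape[1]
    diag = np.einsum("wii->wi", stack)
    region = ((stack.sum(axis=2) - diag) / (R - 1)).T   # regions x windows
    network = {
        net: region[partition.members(net)].mean(axis=0)
        for net in partition.present_networks
    }
    return DynamicGFC(region, network, region.mean(axis=0),
                      dfc.window_centers, list(dfc.region_labels))


def intensity_to_window_grid(
    trace: IntensityTrace,
    window_centers_seconds: np.ndarray,
    injection_seconds: float,
    tr_seconds: float = 2.0,
    smooth_sd_seconds: float = COVARIATE_SMOOTH_SD_SECONDS,
) -> np.ndarray:
    """Resample per-minute ratings onto the window-center grid and smooth.

    Ratings are linearly interpolated to the window centers (seconds from
    scan start) and then convolved with the same 6-s Gaussian used for the
    sliding-window taper.
    """
    times = injection_seconds + trace.times * 60.0
    step = float(np.median(np.diff(window_centers_seconds)))
    values = np.interp(window_centers_seconds, times, trace.ratings)
    return gaussian_filter1d(values, smooth_sd_seconds / step, mode="nearest")


def lmm_vs_covariate(
    diff_traces: np.ndarray,
    covariate: np.ndarray,
    subjects,
    units,
    family: str = "regions",
) -> LMMResult:
    """Mixed model per unit: response = drug-placebo trace, predictor = covariate.

    ``diff_traces`` is subjects x units x windows; ``covariate`` is either
    windows (shared) or subjects x windows.  Random intercept and slope per
    subject; BH-FDR across units.
    """
    diff = np.asarray(diff_traces, dtype=float)
    n_subj, n_units, n_win = diff.shape
    cov = np.asarray(covariate, dtype=float)
    if cov.ndim == 1:
        cov = np.broadcast_to(cov, (n_subj, n_win))
    if cov.shape != (n_subj, n_win):
        raise ValueError("covariate grid misaligned with traces")
    if np.ptp(cov) == 0:
        raise ValueError("constant covariate")
    predictor = cov.reshape(-1)
    groups = np.repeat(np.asarray(subjects), n_win)
    responses = diff.transpose(1, 0, 2).reshape(n_units, -1)
    return lmm_per_unit(responses, predictor, groups, units, family=family)


def timepoint_cluster_contrast(
    traces_drug: np.ndarray,
    traces_placebo: np.ndarray,
    n_permutations: int = 1000,
    cluster_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Temporal cluster statistics on paired drug/placebo GFC traces.

    Pointwise paired t over subjects; contiguous supra-threshold runs form
    clusters; the null swaps condition labels per subject (sign flips of
    the difference traces).
    """
    drug = np.asarray(traces_drug, dtype=float)
    plac = np.asarray(traces_placebo, dtype=float)
    if drug.shape != plac.shape:
        raise ValueError("paired traces must share a grid")
    return signflip_cluster_test(drug - plac, n_permutations=n_permutations,
                                 cluster_p=cluster_p, rng=rng)


def receptor_association(
    beta_map: np.ndarray,
    receptors: ReceptorMap,
    region_labels,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pearson correlation of a per-region slope map with receptor density.

    Significance from a permutation of region labels (two-sided); the
    observed statistic counts toward the null.
    """
    if list(region_labels) != list(receptors.region_labels):
        raise ValueError("region label sets do not match")
    beta = np.asarray(beta_map, dtype=float)
    dens = receptors.density
    rng = rng or np.random.default_rng()
    r_obs = float(np.corrcoef(beta, dens)[0, 1])
    count = 0
    for _ in range(n_permutations):
        r_null = np.corrcoef(beta, rng.permutation(dens))[0, 1]
        if abs(r_null) >= abs(r_obs):
            count += 1
    return r_obs, (count + 1) / (n_permutations + 1)
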