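"""Channel-space and temporal cluster statistics for EEG measures.

Channel clusters form over a montage adjacency graph with a per-subject
sign-flip (condition label swap) null; temporal contrasts use the
circular-rotation null, which preserves each difference trace's
autocorrelation and spectral content.
"""

from __future__ import annotations

import warnings

import numpy as np

from .clusterperm import circular_cluster_test, signflip_cluster_test
from .containers import ClusterTestResult
from .stats import fisher_z

DEFAULT_N_PERMUTATIONS = 7500


def channel_cluster_permutation(
    diffs: np.ndarray,
    neighbors: dict,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    cluster_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Cluster-based permutation test over channels.

    ``diffs`` is subjects x channels of paired condition differences; the
    one-sample t per channel is thresholded, supra-threshold channels are
    joined through ``neighbors`` (index -> neighbor indices), and the null
    is built from random per-subject sign flips.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if diffs.shape[1] > 1 and not any(neighbors.get(i) for i in range(diffs.shape[1])):
        warnings.warn("empty adjacency: clusters degenerate to singletons",
                      RuntimeWarning)
    return signflip_cluster_test(
        diffs, n_permutations=n_permutations, cluster_p=cluster_p,
        neighbors=neighbors, rng=rng,
    )


def subject_channel_correlation(
    measure_diff: np.ndarray,
    covariate: np.ndarray,
) -> np.ndarray:
    """Per-subject, per-channel Pearson r of a measure with a covariate.

    ``measure_diff`` is subjects x channels x epochs (NaN = missing epoch);
    ``covariate`` is epochs (shared) or subjects x epochs.  Returns the
    Fisher-z matrix (subjects x channels); |r| at the clip cap marks a
    degenerate perfect correlation.
    """
    m = np.asarray(measure_diff, dtype=float)
    n_subj, n_ch, n_ep = m.shape
    cov = np.asarray(covariate, dtype=float)
    if cov.ndim == 1:
        cov = np.broadcast_to(cov, (n_subj, n_ep))
    z = np.empty((n_subj, n_ch))
    for s in range(n_subj):
        if np.ptp(cov[s][np.isfinite(cov[s])]) == 0:
            raise ValueError("constant covariate")
        for ch in range(n_ch):
            valid = np.isfinite(m[s, ch]) & np.isfinite(cov[s])
            r = np.corrcoef(m[s, ch, valid], cov[s, valid])[0, 1]
            z[s, ch] = fisher_z(r)
    return z


def dynamic_eeg_correlation(
    measure_diff: np.ndarray,
    covariate: np.ndarray,
    neighbors: dict,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    cluster_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ClusterTestResult]:
    """Group test of per-subject measure-covariate correlations over channels.

    Subject-level r per channel -> Fisher z -> one-sample channel cluster
    permutation against zero.
    """
    z = subject_channel_correlation(measure_diff, covariate)
    result = channel_cluster_permutation(
        z, neighbors, n_permutations=n_permutations, cluster_p=cluster_p, rng=rng,
    )
    return z, result


def temporal_cluster_circular(
    traces_drug: np.ndarray,
    traces_placebo: np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    cluster_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Temporal condition contrast with a circular-rotation null.

    Rotations are applied to the per-subject difference traces, which is
    equivalent to rotating one condition relative to the other.
    """
    drug = np.asarray(traces_drug, dtype=float)
    plac = np.asarray(traces_placebo, dtype=float)
    if drug.shape != plac.shape:
        raise ValueError("traces must have equal length")
    return circular_cluster_test(drug - plac, n_permutations=n_permutations,
                                 cluster_p=cluster_p, rng=rng)
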