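"""Cluster-based permutation engine shared by the fMRI and EEG statistics.

Supports the three null-generation schemes the analyses need:

* per-subject sign flips of paired condition differences (equivalent to
  swapping condition labels within subject),
* per-subject circular rotations of difference time series, which preserve
  each trace's autocorrelation and spectrum,
* and both temporal (contiguous-run) and channel-space (adjacency-graph)
  cluster formation.

Cluster mass is the signed sum of member t values; inference compares each
observed cluster's |mass| against the permutation distribution of the
maximum |mass|, and the observed statistic is included in the null, so
``p >= 1 / (n_permutations + 1)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .containers import Cluster, ClusterTestResult
from .stats import one_sample_t_matrix


def cluster_threshold(n_subjects: int, p: float = 0.05) -> float:
    """Two-sided cluster-forming t threshold at pointwise level ``p``."""
    return float(sps.t.ppf(1.0 - p / 2.0, n_subjects - 1))


def temporal_clusters(t: np.ndarray, threshold: float):
    """Contiguous supra-threshold runs, positive and negative separately."""
    clusters = []
    for sign in (1.0, -1.0):
        mask = sign * t > threshold
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            members = tuple(range(start, stop))
            clusters.append((members, float(t[start:stop].sum())))
    return clusters


def graph_clusters(t: np.ndarray, threshold: float, neighbors: dict):
    """Connected supra-threshold components on an adjacency graph.

    ``neighbors`` maps unit index -> iterable of neighbor indices.  With an
    empty graph every supra-threshold unit is its own singleton cluster.
    """
    clusters = []
    for sign in (1.0, -1.0):
        active = set(np.flatnonzero(sign * t > threshold).tolist())
        while active:
            seed = active.pop()
            comp = {seed}
            frontier = [seed]
            while frontier:
                u = frontier.pop()
                for v in neighbors.get(u, ()):
                    if v in active:
                        active.discard(v)
                        comp.add(v)
                        frontier.append(v)
            members = tuple(sorted(comp))
            clusters.append((members, float(t[list(members)].sum())))
    return clusters


def _max_mass(clusters) -> float:
    return max((abs(m) for _, m in clusters), default=0.0)


def _signflip_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for all sign-flip permutations at once.

    Sign flips leave each unit's second moment unchanged, so only the mean
    needs recomputation: a single matrix product covers every permutation.
    """
    n = diffs.shape[0]
    mean = signs @ diffs / n                       # perms x units
    msq = (diffs**2).mean(axis=0)                  # units
    var = (msq - mean**2) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var == 0, 0.0, t)


def _finish(observed, t_obs, null_max, threshold, n_permutations):
    # tiny tolerance so ties (e.g. the identity permutation) count as
    # exceedances regardless of floating-point summation order
    clusters = [
        Cluster(members, mass,
                float((1 + np.sum(null_max >= abs(mass) * (1 - 1e-12) - 1e-12))
                      / (n_permutations + 1)))
        for members, mass in observed
    ]
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterTestResult(clusters, t_obs, threshold, n_permutations)


def signflip_cluster_test(
    diffs: np.ndarray,
    n_permutations: int = 1000,
    cluster_p: float = 0.05,
    neighbors: dict | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Paired cluster test with a per-subject sign-flip null.

    ``diffs`` is subjects x units (channels or timepoints).  Temporal
    clustering is used unless an adjacency ``neighbors`` dict is given.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = rng or np.random.default_rng()
    thr = cluster_threshold(n, cluster_p)
    t_obs = one_sample_t_matrix(diffs)
    clusterer = (
        (lambda t: graph_clusters(t, thr, neighbors))
        if neighbors is not None
        else (lambda t: temporal_clusters(t, thr))
    )
    observed = clusterer(t_obs)
    signs = rng.integers(0, 2, size=(n_permutations, n)) * 2.0 - 1.0
    t_null = _signflip_t(diffs, signs)
    null_max = np.fromiter(
        (_max_mass(clusterer(t_null[p])) for p in range(n_permutations)),
        dtype=float, count=n_permutations,
    )
    return _finish(observed, t_obs, null_max, thr, n_permutations)


def circular_cluster_test(
    diffs: np.ndarray,
    n_permutations: int = 1000,
    cluster_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Paired temporal cluster test with a circular-rotation null.

    Each permutation independently rotates every subject's difference trace
    by a uniform random offset, preserving autocorrelation and spectrum.
    """
    diffs = np.asarray(diffs, dtype=float)
    n, T = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if T < 10:
        raise ValueError("traces must have at least 10 timepoints")
    rng = rng or np.random.default_rng()
    thr = cluster_threshold(n, cluster_p)
    t_obs = one_sample_t_matrix(diffs)
    observed = temporal_clusters(t_obs, thr)
    null_max = np.empty(n_permutations)
    base = np.arange(T)
    for p in range(n_permutations):
        offsets = rng.integers(0, T, size=n)
        idx = (base[None, :] + offsets[:, None]) % T
        rolled = np.take_along_axis(diffs, idx, axis=1)
        null_max[p] = _max_mass(temporal_clusters(one_sample_t_matrix(rolled), thr))
    return _finish(observed, t_obs, null_max, thr, n_permutations)
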