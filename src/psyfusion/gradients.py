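"""Cortical gradients: diffusion map embedding of FC-profile similarity.

Each unit's (region's) connectivity row is thresholded to its strongest
10% of entries, pairwise cosine similarity of the thresholded rows forms
the affinity matrix, and the anisotropic (alpha = 0.5) diffusion operator
is eigendecomposed.  At the default diffusion time 0 the component scores
carry the multiscale diffusion scaling (eigenvalue / (1 - eigenvalue)),
so embedding distances integrate over all walk lengths and the spread of
scores shrinks as the underlying structure mixes.  The first nontrivial component is the principal
gradient, running from unimodal sensorimotor to transmodal association
cortex.  Individual embeddings are aligned to a group template by
orthogonal Procrustes rotation, and condition contrasts include gradient
*compression* metrics (range and SD of principal-gradient scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.sparse.csgraph import connected_components

from .containers import FCMatrix, GradientSet, NetworkPartition
from .fc_static import paired_contrast


@dataclass
class GradientConfig:
    sparsity: float = 0.9        # fraction of each row zeroed
    alpha: float = 0.5           # anisotropic normalization exponent
    n_components: int = 10
    diffusion_time: float = 0.0  # eigenvalue power applied to scores

    def __post_init__(self) -> None:
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class AffinityMatrix:
    values: np.ndarray
    unit_labels: list
    sparsity: float


def build_affinity(fc: FCMatrix, cfg: GradientConfig | None = None) -> AffinityMatrix:
    """Row-threshold the z-matrix, then cosine similarity between rows.

    Per row, only the top ``1 - sparsity`` fraction of off-diagonal entries
    is retained.  Negative cosine similarities are clipped to zero (the
    affinity must be nonnegative for the diffusion operator).
    """
    cfg = cfg or GradientConfig()
    z = fc.values.copy()
    n = z.shape[0]
    np.fill_diagonal(z, 0.0)
    keep = max(1, int(round((1.0 - cfg.sparsity) * n)))
    thresholded = np.zeros_like(z)
    for i in range(n):
        idx = np.argpartition(z[i], -keep)[-keep:]
        thresholded[i, idx] = z[i, idx]
    if np.any(~thresholded.any(axis=1)):
        raise ValueError("row with no surviving connections after thresholding")
    norms = np.linalg.norm(thresholded, axis=1)
    cos = (thresholded @ thresholded.T) / np.outer(norms, norms)
    cos = np.clip(cos, 0.0, 1.0)
    cos = (cos + cos.T) / 2.0
    np.fill_diagonal(cos, 0.0)
    return AffinityMatrix(cos, list(fc.region_labels), cfg.sparsity)


def diffusion_embedding(aff: AffinityMatrix, cfg: GradientConfig | None = None) -> GradientSet:
    """Diffusion map embedding of a nonnegative affinity matrix.

    Anisotropic normalization ``W / (d^alpha d^alpha)`` with alpha = 0.5,
    row normalization to a Markov operator, eigendecomposition; the
    stationary (constant) eigenvector is dropped and components are
    ordered by decreasing eigenvalue.  With ``diffusion_time`` t > 0 the
    scores are scaled by ``eigenvalue**t``; the default t = 0 applies the
    multiscale scaling ``eigenvalue / (1 - eigenvalue)`` (the sum of the
    map over all diffusion times).  A disconnected affinity graph triggers a
    warning and the embedding is computed on the largest component
    (other units receive zero scores).
    """
    cfg = cfg or GradientConfig()
    W = np.asarray(aff.values, dtype=float)
    n = W.shape[0]
    n_comp_graph, labels = connected_components(W > 0, directed=False)
    keep = np.arange(n)
    if n_comp_graph > 1:
        warnings.warn(
            f"affinity graph has {n_comp_graph} components; "
            "embedding restricted to the largest", RuntimeWarning,
        )
        sizes = np.bincount(labels)
        keep = np.flatnonzero(labels == sizes.argmax())
        W = W[np.ix_(keep, keep)]

    d = W.sum(axis=1)
    d_alpha = d ** cfg.alpha
    Wa = W / np.outer(d_alpha, d_alpha)
    da = Wa.sum(axis=1)
    # symmetric conjugate of the Markov operator D^-1 Wa
    inv_sqrt = 1.0 / np.sqrt(da)
    S = Wa * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the Markov operator, referenced to the
    # stationary vector so the embedding scale is comparable across inputs
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]

    k = min(cfg.n_components, evals.size - 1)
    lam = evals[1 : k + 1]
    if cfg.diffusion_time > 0:
        scale = np.sign(lam) * np.abs(lam) ** cfg.diffusion_time
    else:
        # multiscale diffusion distance: sum over all walk lengths
        scale = lam / (1.0 - np.clip(lam, None, 1.0 - 1e-12))
    scores_kept = psi[:, 1 : k + 1] * scale
    gap = float(evals[1] - evals[2]) if evals.size > 2 else np.inf
    if abs(evals[1]) < 1e-12 or gap < 1e-10:
        warnings.warn("degenerate spectrum: no informative component "
                      "(eigen-gap ~ 0)", RuntimeWarning)
    scores = np.zeros((n, k))
    scores[keep] = scores_kept
    return GradientSet(scores, lam, list(aff.unit_labels))


def gradients_from_fc(fc: FCMatrix, cfg: GradientConfig | None = None) -> GradientSet:
    """Convenience chain: affinity construction + diffusion embedding."""
    cfg = cfg or GradientConfig()
    return diffusion_embedding(build_affinity(fc, cfg), cfg)


def procrustes_align(individual: GradientSet, template: GradientSet) -> GradientSet:
    """Orthogonal (rotation/reflection, no scaling) alignment to a template."""
    if individual.scores.shape != template.scores.shape:
        raise ValueError("gradient sets must share units and component count")
    R, _ = sla.orthogonal_procrustes(individual.scores, template.scores)
    aligned = individual.scores @ R
    # fix residual sign indeterminacy: each component correlates positively
    # with its template counterpart
    for j in range(aligned.shape[1]):
        if np.dot(aligned[:, j], template.scores[:, j]) < 0:
            aligned[:, j] = -aligned[:, j]
    return GradientSet(aligned, individual.eigenvalues.copy(),
                       list(individual.unit_labels), aligned_to="template")


def group_template(fcs, cfg: GradientConfig | None = None) -> GradientSet:
    """Template = embedding of the element-wise mean affinity across inputs."""
    cfg = cfg or GradientConfig()
    affs = [build_affinity(fc, cfg) for fc in fcs]
    mean_aff = AffinityMatrix(
        np.mean([a.values for a in affs], axis=0), affs[0].unit_labels, cfg.sparsity
    )
    return diffusion_embedding(mean_aff, cfg)


@dataclass
class GradientContrast:
    """Per-unit paired stats plus compression metrics per condition."""

    unit_stats: pd.DataFrame
    network_means: pd.DataFrame
    compression: pd.DataFrame       # subject, condition, range, sd


def gradient_contrast(
    drug: list,
    placebo: list,
    partition: NetworkPartition,
) -> GradientContrast:
    """Paired drug/placebo contrast of aligned principal-gradient scores.

    ``drug`` and ``placebo`` are per-subject aligned :class:`GradientSet`
    lists in matching subject order.  Compression = range and SD of each
    subject's principal-gradient scores.
    """
    if len(drug) != len(placebo) or not drug:
        raise ValueError("paired per-subject gradient sets required")
    if any(g.aligned_to is None for g in drug + placebo):
        raise ValueError("gradient sets must be aligned before contrasting")
    pg_drug = np.stack([g.principal for g in drug])      # subjects x units
    pg_plac = np.stack([g.principal for g in placebo])
    labels = drug[0].unit_labels
    contrast = paired_contrast(pg_drug, pg_plac, labels, family="gradient_units")
    unit_stats = contrast.to_frame()

    rows = []
    for cond, mat in (("drug", pg_drug), ("placebo", pg_plac)):
        for net in partition.present_networks:
            members = partition.members(net)
            rows.append({"condition": cond, "network": net,
                         "mean_score": float(mat[:, members].mean())})
    network_means = pd.DataFrame(rows)

    comp = []
    for cond, sets in (("drug", drug), ("placebo", placebo)):
        for s, g in enumerate(sets):
            pg = g.principal
            comp.append({"subject": s, "condition": cond,
                         "range": float(np.ptp(pg)), "sd": float(pg.std())})
    return GradientContrast(unit_stats, network_means, pd.DataFrame(comp))
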