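"""Time-averaged functional-connectivity statistics.

Pairwise Fisher-z connectivity over region pairs, global functional
connectivity (GFC) at region / network / whole-brain level, dual-regression
within-network integrity, between-network segregation, paired condition
contrasts with BH-FDR, and an optional global-signal-regression toggle.

The default analysis window for "static" condition contrasts is the 8-min
period starting at the injection (240 volumes at TR 2 s), configurable per
call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CORTICAL_NETWORKS,
    FCMatrix,
    NetworkPartition,
    ParcelTimeSeries,
)
from .stats import bh_fdr, fisher_z, paired_t

#: length of the default post-injection static window, in volumes at TR 2 s
POST_WINDOW_VOLUMES = 240


def post_injection_window(ts: ParcelTimeSeries, n_volumes: int = POST_WINDOW_VOLUMES):
    """The default 8-min analysis window starting at the injection."""
    start = ts.injection_index
    return slice(start, min(start + n_volumes, ts.n_volumes))


def pairwise_fc(ts: ParcelTimeSeries, window: slice | None = None) -> FCMatrix:
    """Pearson correlation between every region pair, Fisher z-transformed.

    Censored volumes inside the window are excluded.  Zero-variance regions
    are flagged by propagating NaN through their row/column.
    """
    if window is None:
        window = slice(0, ts.n_volumes)
    keep = ts.censor_mask[window]
    x = ts.data[window][keep]
    if x.shape[0] < 3:
        raise ValueError("window must contain at least 3 uncensored volumes")
    sd = x.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    z = fisher_z(r)
    np.fill_diagonal(z, fisher_z(1.0))
    z[degenerate, degenerate] = np.nan
    return FCMatrix(z, list(ts.region_labels))


@dataclass
class GFCMap:
    """Global functional connectivity at three aggregation levels."""

    region_gfc: np.ndarray          # mean off-diagonal z per region row
    network_gfc: dict               # network -> mean over member regions
    whole_brain: float              # mean over all regions
    region_labels: list


def gfc(fc: FCMatrix, partition: NetworkPartition) -> GFCMap:
    """Average Fisher-z of each region to all others, plus network means."""
    off = fc.offdiag()
    if np.any(np.all(np.isnan(off), axis=1)):
        raise ValueError("region with all-missing connectivity row")
    region = np.nanmean(off, axis=1)
    network = {
        net: float(region[partition.members(net)].mean())
        for net in partition.present_networks
    }
    return GFCMap(region, network, float(region.mean()), list(fc.region_labels))


def binary_templates(partition: NetworkPartition, networks=None) -> np.ndarray:
    """Binary network-membership maps (networks x regions)."""
    networks = list(networks) if networks is not None else list(partition.present_networks)
    return np.stack([partition.indicator(n).astype(float) for n in networks])


def network_templates(partition: NetworkPartition, networks=None) -> np.ndarray:
    """Graded network template maps (networks x regions) for dual regression.

    Member regions carry a deterministic linear ramp of weights (0.5 to
    1.5), emulating canonical ICA maps whose regions load unevenly.  Purely
    binary membership maps are degenerate at parcel level: the member
    average of stage-2 PEs then reproduces the stage-1 regressor exactly
    and integrity is identically 1, carrying no signal.  Graded weights
    break that identity, so the integrity PE tracks within-network
    coupling strength.
    """
    networks = list(networks) if networks is not None else list(partition.present_networks)
    maps = []
    for n in networks:
        members = partition.members(n)
        weights = np.zeros(len(partition))
        k = members.size
        ramp = np.linspace(0.5, 1.5, k) if k > 1 else np.array([1.0])
        weights[members] = ramp
        maps.append(weights)
    return np.stack(maps)


@dataclass
class IntegrityResult:
    networks: list
    pe: dict                        # network -> integrity parameter estimate
    stage1_timeseries: np.ndarray   # networks x volumes
    pe_maps: np.ndarray             # networks x regions


def dual_regression_stage1(data: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Spatial regression of template maps onto each volume -> network series.

    ``data`` is volumes x regions; ``templates`` networks x regions.
    Each volume's region pattern is modeled as a linear combination of the
    spatial templates; the coefficients over time are the network series.
    (No spatial intercept: membership templates already span the constant
    pattern when they tile the whole parcellation.)
    """
    design = templates.T
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("templates are rank deficient")
    coef, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return coef


def integrity_dual_regression(
    ts: ParcelTimeSeries,
    templates: np.ndarray,
    template_names,
    window: slice | None = None,
) -> IntegrityResult:
    """Two-stage dual regression; integrity = mean PE over a network's regions.

    Stage 1 regresses the spatial templates on each volume to get network
    time series; stage 2 regresses those time series (jointly, plus
    intercept) on each region's time series to get per-network PE maps.
    """
    if window is None:
        window = slice(0, ts.n_volumes)
    keep = ts.censor_mask[window]
    data = ts.data[window][keep]
    s1 = dual_regression_stage1(data, templates)
    design = np.column_stack([np.ones(s1.shape[1]), s1.T])
    pe_maps, *_ = np.linalg.lstsq(design, data, rcond=None)
    pe_maps = pe_maps[1:]           # networks x regions
    names = list(template_names)
    members = {n: np.asarray(templates[i], dtype=bool) for i, n in enumerate(names)}
    pe = {n: float(pe_maps[i, members[n]].mean()) for i, n in enumerate(names)}
    return IntegrityResult(names, pe, s1, pe_maps)


def segregation(network_ts: np.ndarray, network_names, partial: bool = False) -> pd.DataFrame:
    """Symmetric network-pair coupling matrix from stage-1 time series.

    For each ordered pair a GLM slope of one network's series on the other
    is estimated (simple pairwise regression by default; ``partial=True``
    additionally covaries the remaining networks); the two directed
    estimates are averaged.
    """
    x = np.asarray(network_ts, dtype=float)
    k = x.shape[0]
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant network time series")
    names = list(network_names)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if partial:
                others = [m for m in range(k) if m not in (i, j)]
                design = np.column_stack([np.ones(x.shape[1]), x[j], x[others].T])
            else:
                design = np.column_stack([np.ones(x.shape[1]), x[j]])
            coef, *_ = np.linalg.lstsq(design, x[i], rcond=None)
            out[i, j] = coef[1]
    sym = (out + out.T) / 2.0
    np.fill_diagonal(sym, np.nan)
    return pd.DataFrame(sym, index=names, columns=names)


@dataclass
class ContrastResult:
    """Paired condition contrast over a family of units."""

    units: list
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mean_diff: np.ndarray
    degenerate: np.ndarray
    family: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": self.units, "t": self.t, "p": self.p, "q": self.q,
                "mean_diff": self.mean_diff, "degenerate": self.degenerate,
            }
        )


def paired_contrast(drug: np.ndarray, placebo: np.ndarray, units, family: str) -> ContrastResult:
    """Two-sided paired t per unit (column), BH-FDR across the family.

    ``drug`` and ``placebo`` are subjects x units matrices.
    """
    drug = np.atleast_2d(np.asarray(drug, dtype=float))
    placebo = np.atleast_2d(np.asarray(placebo, dtype=float))
    if drug.shape != placebo.shape:
        raise ValueError("condition tables must have identical shape")
    if drug.shape[0] < 3:
        raise ValueError("need at least 3 complete subject pairs")
    k = drug.shape[1]
    t = np.empty(k)
    p = np.empty(k)
    md = np.empty(k)
    degen = np.zeros(k, dtype=bool)
    for i in range(k):
        res = paired_t(drug[:, i], placebo[:, i])
        t[i], p[i], md[i], degen[i] = res.t, res.p, res.mean_diff, res.degenerate
    q = bh_fdr(p, family=family).q_values
    return ContrastResult(list(units), t, p, q, md, degen, family)


def global_signal_regress(ts: ParcelTimeSeries) -> ParcelTimeSeries:
    """Regress the mean-across-regions signal (plus intercept) out of each region."""
    x = ts.data
    gs = x.mean(axis=1)
    design = np.column_stack([np.ones(x.shape[0]), gs])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    return ParcelTimeSeries(
        data=resid, tr_seconds=ts.tr_seconds, region_labels=list(ts.region_labels),
        subject=ts.subject, condition=ts.condition,
        injection_index=ts.injection_index, censor_mask=ts.censor_mask.copy(),
    )


def network_gfc_frame(maps: dict) -> pd.DataFrame:
    """Tidy frame from ``{(subject, condition): GFCMap}``."""
    rows = []
    for (subject, condition), m in maps.items():
        for net, val in m.network_gfc.items():
            rows.append({"subject": subject, "condition": condition,
                         "network": net, "gfc": val})
        rows.append({"subject": subject, "condition": condition,
                     "network": "whole_brain", "gfc": m.whole_brain})
    return pd.DataFrame(rows)
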