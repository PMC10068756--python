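"""Shared statistical primitives.

Fisher transform, Benjamini-Hochberg FDR, paired t contrasts, weighted
Pearson correlation, and the mixed-effects fitting contract used by the
dynamic-connectivity and EEG-fMRI fusion stages.

The mixed model is the random-intercept + random-slope Gaussian model

    y_ij = (b0 + u0_i) + (b1 + u1_i) x_ij + e_ij,
    (u0_i, u1_i) ~ N(0, S),  e_ij ~ N(0, s2),

fitted by profiled REML.  Because every analysis here shares the single
fixed covariate, the REML objective reduces to per-group 2x2 sufficient
statistics (Woodbury identity), which makes one fit cost microseconds
rather than the seconds a generic mixed-model routine needs; correctness
is pinned against an independent reference implementation in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

R_CLIP = 1.0 - 1e-7  # correlation magnitude cap before arctanh


def fisher_z(r):
    """Fisher z-transform with |r| clipped to ``R_CLIP`` first."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    return np.arctanh(r)


def fisher_z_inv(z):
    return np.tanh(np.asarray(z, dtype=float))


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

@dataclass
class FDRResult:
    p_values: np.ndarray
    q_values: np.ndarray
    rejected: np.ndarray
    level: float
    family: str
    family_size: int


def bh_fdr(pvals, level: float = 0.05, family: str = "unnamed") -> FDRResult:
    """Benjamini-Hochberg step-up procedure.

    ``q[i] = min_{j >= rank(i)} m * p_(j) / j`` and the rejection set is the
    classical step-up set; the family name and size are carried in the result
    so every corrected table records what it was corrected over.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    # step-up rejection: largest k with p_(k) <= k/m * level, reject 1..k
    below = p[order] <= np.arange(1, m + 1) / m * level
    rejected = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        rejected[order[: k + 1]] = True
    return FDRResult(p, q, rejected, level, family, m)


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

@dataclass
class PairedTResult:
    t: float
    p: float
    df: int
    mean_diff: float
    degenerate: bool = False


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired t test of ``a`` versus ``b``.

    A zero-variance, nonzero-mean difference vector is degenerate (the t
    statistic diverges); it is flagged and p is reported as the smallest
    positive float rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(0.0, 1.0, n - 1, 0.0)
        t = np.inf if md > 0 else -np.inf
        return PairedTResult(t, np.finfo(float).tiny, n - 1, md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), float(p), n - 1, float(md))


def one_sample_t_matrix(x: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t against 0 along axis 0 (observations)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    m = x.mean(axis=0)
    s = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
        degenerate = np.sign(m) * np.inf
        degenerate = np.where(m == 0, 0.0, degenerate)
    return np.where(s == 0, degenerate, t)


# ---------------------------------------------------------------------------
# weighted Pearson correlation
# ---------------------------------------------------------------------------

def weighted_pearson(x, y, w) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    sw = w.sum()
    if sw <= 0:
        raise ValueError("total weight must be positive")
    wn = w / sw
    mx = wn @ x
    my = wn @ y
    cov = wn @ ((x - mx) * (y - my))
    vx = wn @ ((x - mx) ** 2)
    vy = wn @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance")
    return float(cov / np.sqrt(vx * vy))


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    beta: float            # fixed slope
    se: float
    t: float
    p: float
    intercept: float
    sigma2: float          # residual variance
    re_cov: np.ndarray     # 2x2 random-effect covariance (intercept, slope)
    converged: bool
    flag: str              # full | intercept_only | ols | exact
    df: int
    loglik: float = np.nan


def _suffstats(y, x, groups):
    """Per-group sufficient statistics for the 2-column design [1, x]."""
    labels, idx = np.unique(groups, return_inverse=True)
    g = labels.size
    A = np.zeros((g, 2, 2))
    a = np.zeros((g, 2))
    c = np.zeros(g)
    n = np.zeros(g)
    np.add.at(n, idx, 1.0)
    np.add.at(A[:, 0, 1], idx, x)
    np.add.at(A[:, 1, 1], idx, x * x)
    A[:, 0, 0] = n
    A[:, 1, 0] = A[:, 0, 1]
    np.add.at(a[:, 0], idx, y)
    np.add.at(a[:, 1], idx, x * y)
    np.add.at(c, idx, y * y)
    return labels, A, a, c, n


def _reml_pieces(psi, A, a, c):
    """Aggregate REML quantities given scaled RE covariance ``psi`` (2x2)."""
    eye = np.eye(2)
    B = eye + A @ psi                      # g x 2 x 2
    det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
    if np.any(det <= 0):
        return None
    K = psi @ np.linalg.inv(B)             # g x 2 x 2 : (psi^-1 + A)^-1
    AK = A @ K
    G = (A - AK @ A).sum(axis=0)           # sum X'V^-1X
    g_vec = np.einsum("gij,gj->i", eye - AK, a)
    q = c.sum() - np.einsum("gi,gij,gj->", a, K, a)
    return G, g_vec, q, np.log(det).sum()


def _neg2_reml(theta, A, a, c, N):
    L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    psi = L @ L.T
    pieces = _reml_pieces(psi, A, a, c)
    if pieces is None:
        return np.inf
    G, g_vec, q, logdet = pieces
    sign, logdetG = np.linalg.slogdet(G)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(G, g_vec)
    rss = q - beta @ g_vec
    if rss <= 0:
        rss = 1e-300
    s2 = rss / (N - 2)
    return logdet + logdetG + (N - 2) * (1.0 + np.log(2 * np.pi * s2))


def fit_mixed_model(response, predictor, groups) -> MixedModelResult:
    """REML fit of a random-intercept + random-slope model.

    Parameters
    ----------
    response, predictor : 1-d arrays, aligned observations.
    groups : group (subject) label per observation.

    Returns the fixed-slope estimate with a Wald t test on
    ``n_groups - 1`` degrees of freedom.  Non-convergence of the full
    model falls back to a random-intercept-only fit (``flag``
    records which ladder rung produced the estimate); a singular or
    constant predictor raises.
    """
    y = np.asarray(response, dtype=float).ravel()
    x = np.asarray(predictor, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if not (y.size == x.size == groups.size):
        raise ValueError("response, predictor and groups must align")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: model is degenerate")
    labels, A, a, c, n = _suffstats(y, x, groups)
    g = labels.size
    if g < 3:
        raise ValueError("need at least 3 groups")
    N = y.size
    df = g - 1

    # OLS baseline (also the exact answer when residuals vanish)
    X = np.column_stack([np.ones(N), x])
    ols_beta, ols_rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_rss = float(ols_rss[0]) if np.size(ols_rss) else 0.0
    scale = float(y @ y) if y.any() else 1.0
    if ols_rss <= 1e-12 * max(scale, 1e-300):
        return MixedModelResult(
            beta=float(ols_beta[1]), se=0.0, t=np.inf * np.sign(ols_beta[1] or 1.0),
            p=0.0, intercept=float(ols_beta[0]), sigma2=0.0,
            re_cov=np.zeros((2, 2)), converged=True, flag="exact", df=df,
        )

    # start values from per-group OLS spread
    theta0 = np.array([np.log(0.3), 0.0, np.log(0.3)])
    res = optimize.minimize(
        _neg2_reml, theta0, args=(A, a, c, N), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600},
    )
    flag = "full"
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        # ladder rung 2: random intercept only
        res = optimize.minimize_scalar(
            lambda t0: _neg2_reml(np.array([t0, 0.0, np.log(1e-10)]), A, a, c, N),
            bounds=(-12, 6), method="bounded",
        )
        theta = np.array([res.x, 0.0, np.log(1e-10)])
        flag = "intercept_only"
        converged = bool(res.success)
    else:
        theta = res.x
    if not converged:
        # last rung: plain OLS slope with group-cluster-naive SE
        resid = y - X @ ols_beta
        s2 = resid @ resid / (N - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = float(np.sqrt(cov[1, 1]))
        t = float(ols_beta[1] / se)
        return MixedModelResult(
            beta=float(ols_beta[1]), se=se, t=t,
            p=float(2 * sps.t.sf(abs(t), df)), intercept=float(ols_beta[0]),
            sigma2=float(s2), re_cov=np.zeros((2, 2)), converged=False,
            flag="ols", df=df,
        )

    L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    psi = L @ L.T
    G, g_vec, q, _ = _reml_pieces(psi, A, a, c)
    beta = np.linalg.solve(G, g_vec)
    s2 = max((q - beta @ g_vec) / (N - 2), 1e-300)
    cov_beta = s2 * np.linalg.inv(G)
    se = float(np.sqrt(cov_beta[1, 1]))
    t = float(beta[1] / se)
    p = float(2 * sps.t.sf(abs(t), df))
    return MixedModelResult(
        beta=float(beta[1]), se=se, t=t, p=p, intercept=float(beta[0]),
        sigma2=float(s2), re_cov=s2 * psi, converged=converged, flag=flag,
        df=df, loglik=-0.5 * float(res.fun),
    )


@dataclass
class LMMResult:
    """Per-unit mixed-model slopes with a BH-corrected family."""

    units: list
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    converged: np.ndarray
    flags: list
    family: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "unit": self.units, "beta": self.beta, "se": self.se,
                "t": self.t, "p": self.p, "q": self.q,
                "converged": self.converged, "flag": self.flags,
            }
        )


def lmm_per_unit(responses, predictor, groups, units, family: str) -> LMMResult:
    """Fit ``fit_mixed_model`` independently for each unit (column set).

    ``responses`` is ``units x observations`` (each row a response vector on
    the shared observation grid); ``predictor`` and ``groups`` are length
    ``observations``.  BH-FDR is applied across units.
    """
    responses = np.asarray(responses, dtype=float)
    k = responses.shape[0]
    beta = np.full(k, np.nan)
    se = np.full(k, np.nan)
    t = np.full(k, np.nan)
    p = np.ones(k)
    conv = np.zeros(k, dtype=bool)
    flags = []
    for i in range(k):
        fit = fit_mixed_model(responses[i], predictor, groups)
        beta[i], se[i], t[i], p[i] = fit.beta, fit.se, fit.t, fit.p
        conv[i] = fit.converged
        flags.append(fit.flag)
    q = bh_fdr(p, family=family).q_values
    return LMMResult(list(units), beta, se, t, p, q, conv, flags, family)
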