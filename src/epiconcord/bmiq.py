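"""Beta-mixture quantile normalization (BMIQ) of Infinium arrays.

Type II probes have a compressed beta-value distribution relative to
type I probes on the same array.  BMIQ fits a three-state beta mixture
(unmethylated U, hemimethylated H, methylated M) separately to the type
I and type II values of each sample, then maps the type II U and M
states onto the corresponding type I states through inverse beta CDFs
and rescales the H state linearly between the mapped U/M anchors.
Type I values are the reference and pass through unchanged.

The EM fit uses exact weighted maximum-likelihood M-steps on the beta
sufficient statistics, so the log-likelihood trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, digamma, logsumexp
from scipy.stats import beta as beta_dist

from .containers import BetaMatrix

_CLAMP = 1e-6
STATE_LABELS = ("U", "H", "M")


class DegenerateFitError(ValueError):
    pass


@dataclass
class BetaMixtureFit:
    """A fitted K-state beta mixture, states ordered by ascending mean."""

    a: np.ndarray  # shape (K,)
    b: np.ndarray
    pi: np.ndarray
    posteriors: np.ndarray  # (n, K)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_states(self) -> int:
        return len(self.a)

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)


def _mom_shapes(x: np.ndarray) -> tuple[float, float]:
    """Method-of-moments beta shapes with guards for tiny variance."""
    mu = float(np.mean(x))
    var = float(np.var(x))
    mu = min(max(mu, 1e-4), 1 - 1e-4)
    var = max(var, 1e-6)
    common = mu * (1 - mu) / var - 1.0
    common = max(common, 0.1)
    a = max(mu * common, 1e-2)
    b = max((1 - mu) * common, 1e-2)
    return a, b


def _weighted_mle(t1: float, t2: float, r: float, a0: float, b0: float):
    """Maximize r-weighted beta log-likelihood from sufficient stats.

    loglik(a, b) = (a-1) t1 + (b-1) t2 - r * betaln(a, b); returns the
    optimum or the warm start, whichever scores higher.
    """

    def neg(theta):
        a, b = np.exp(theta)
        val = -((a - 1.0) * t1 + (b - 1.0) * t2 - r * betaln(a, b))
        dig = digamma(a + b)
        ga = -(t1 - r * (digamma(a) - dig)) * a  # chain rule through log a
        gb = -(t2 - r * (digamma(b) - dig)) * b
        return val, np.array([ga, gb])

    x0 = np.log([a0, b0])
    res = minimize(neg, x0, method="L-BFGS-B", jac=True, bounds=[(-4.6, 9.2)] * 2)
    if res.fun <= neg(x0)[0]:
        a, b = np.exp(res.x)
        return float(a), float(b)
    return a0, b0


def fit_beta_mixture(
    values: np.ndarray | pd.Series,
    n_states: int = 3,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> BetaMixtureFit:
    """EM fit of a beta mixture to methylation fractions.

    Values are clamped away from {0, 1}; initialization splits the
    sample at empirical quantiles with method-of-moments shapes.
    Convergence: log-likelihood gain < ``tol``.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 10 * n_states:
        raise ValueError(f"need at least {10 * n_states} values, got {len(x)}")
    if np.ptp(x) < 1e-12:
        raise DegenerateFitError("constant input: beta mixture is undefined")
    x = np.clip(x, _CLAMP, 1.0 - _CLAMP)
    n = len(x)

    # init: split at fixed methylation levels (0.25 / 0.75 for three
    # states) with method-of-moments shapes per block; beta-value
    # distributions are strongly bimodal, so value-scale cuts give a
    # far more reliable starting point than empirical quantiles, which
    # straddle the modes.  Blocks that come up empty fall back to the
    # corresponding quantile split.
    if n_states == 3:
        qs = np.array([-np.inf, 0.25, 0.75, np.inf])
        counts = np.histogram(x, bins=[0, 0.25, 0.75, 1.0])[0]
        if (counts < max(2, len(x) // 100)).any():
            qs = np.quantile(x, np.linspace(0, 1, n_states + 1))
            qs[0], qs[-1] = -np.inf, np.inf
    else:
        qs = np.quantile(x, np.linspace(0, 1, n_states + 1))
        qs[0], qs[-1] = -np.inf, np.inf
    a = np.empty(n_states)
    b = np.empty(n_states)
    pi = np.empty(n_states)
    for k in range(n_states):
        block = x[(x > qs[k]) & (x <= qs[k + 1])]
        if len(block) < 2:
            block = x
        a[k], b[k] = _mom_shapes(block)
        pi[k] = max(len(block), 1) / n
    pi /= pi.sum()

    logx = np.log(x)
    log1mx = np.log1p(-x)
    trace: list[float] = []
    converged = False
    resp = np.full((n, n_states), 1.0 / n_states)
    for _ in range(max_iter):
        # E-step
        logdens = (
            (a - 1.0) * logx[:, None]
            + (b - 1.0) * log1mx[:, None]
            - betaln(a, b)
            + np.log(pi)
        )
        norm = logsumexp(logdens, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logdens - norm[:, None])
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M-step (exact weighted MLE via sufficient statistics)
        r_k = resp.sum(axis=0)
        pi = np.maximum(r_k, 1e-12)
        pi /= pi.sum()
        for k in range(n_states):
            t1 = float(resp[:, k] @ logx)
            t2 = float(resp[:, k] @ log1mx)
            a[k], b[k] = _weighted_mle(t1, t2, float(r_k[k]), a[k], b[k])

    order = np.argsort(a / (a + b))
    return BetaMixtureFit(
        a=a[order],
        b=b[order],
        pi=pi[order],
        posteriors=resp[:, order],
        loglik_trace=trace,
        converged=converged,
    )


def classify_states(x: np.ndarray, fit: BetaMixtureFit) -> np.ndarray:
    """Assign each value to U/H/M (0/1/2) as contiguous intervals.

    Maximum-posterior assignment, then the two cut points are chosen to
    minimize disagreement with it so states are monotone in x (ties
    broken toward the lower state).
    """
    x = np.clip(np.asarray(x, dtype=float), _CLAMP, 1.0 - _CLAMP)
    logdens = (
        (fit.a - 1.0) * np.log(x)[:, None]
        + (fit.b - 1.0) * np.log1p(-x)[:, None]
        - betaln(fit.a, fit.b)
        + np.log(np.maximum(fit.pi, 1e-300))
    )
    # ties toward the lower state: reverse argmax on the flipped array
    k = fit.n_states
    raw = (k - 1) - np.argmax(logdens[:, ::-1], axis=1)
    if k == 1:
        return raw
    order = np.argsort(x, kind="stable")
    sorted_raw = raw[order]
    n = len(x)
    states_sorted = np.empty(n, dtype=int)
    cut_prev = 0
    for boundary in range(1, k):
        below = (sorted_raw[cut_prev:] < boundary).astype(int)
        # cost of cutting after position i: misclassified = (#>=boundary before) + (#<boundary after)
        cum_below = np.concatenate([[0], np.cumsum(below)])
        total_below = cum_below[-1]
        idx = np.arange(len(below) + 1)
        cost = (idx - cum_below) + (total_below - cum_below)
        cut = int(np.argmin(cost)) + cut_prev
        states_sorted[cut_prev:cut] = boundary - 1
        cut_prev = cut
    states_sorted[cut_prev:] = k - 1
    states = np.empty(n, dtype=int)
    states[order] = states_sorted
    return states


def _mixture_cdf(x: np.ndarray, fit: BetaMixtureFit) -> np.ndarray:
    return sum(
        pi * beta_dist.cdf(x, a, b) for a, b, pi in zip(fit.a, fit.b, fit.pi)
    )


def _mixture_quantile_map(
    x: np.ndarray, src: BetaMixtureFit, dst: BetaMixtureFit, grid_n: int = 4001
) -> np.ndarray:
    """Monotone map matching the source mixture CDF onto the target's."""
    p = np.clip(_mixture_cdf(x, src), 1e-12, 1.0 - 1e-12)
    grid = np.linspace(_CLAMP, 1.0 - _CLAMP, grid_n)
    cdf = _mixture_cdf(grid, dst)
    cdf[0], cdf[-1] = 0.0, 1.0
    return np.interp(p, cdf, grid)


def bmiq_normalize_sample(
    beta_column: pd.Series,
    probe_type: pd.Series,
    n_states: int = 3,
    tol: float = 1e-4,
    max_iter: int = 100,
    return_info: bool = False,
):
    """Normalize one sample's type II probes onto its type I distribution.

    Type I values are returned bitwise unchanged; NaNs pass through.
    The transformation is monotone within the type II probe set.
    """
    ptype = probe_type.reindex(beta_column.index)
    if ptype.isna().any():
        missing = beta_column.index[ptype.isna()]
        raise ValueError(f"probe_type missing for {len(missing)} probes")
    mask1 = (ptype == "I").to_numpy()
    mask2 = (ptype == "II").to_numpy()
    x1 = beta_column.to_numpy(dtype=float)[mask1]
    x2 = beta_column.to_numpy(dtype=float)[mask2]
    if (~np.isnan(x1)).sum() < 50 or (~np.isnan(x2)).sum() < 50:
        raise ValueError("need at least 50 non-missing probes of each design type")

    fit1 = fit_beta_mixture(x1, n_states=n_states, tol=tol, max_iter=max_iter)
    fit2 = fit_beta_mixture(x2, n_states=n_states, tol=tol, max_iter=max_iter)

    finite2 = ~np.isnan(x2)
    xv = np.clip(x2[finite2], _CLAMP, 1.0 - _CLAMP)

    # Degenerate fit guard: when the likelihood prefers a dominant
    # broad middle component (can happen on strongly compressed
    # samples), the U/M anchors are spike-like and the linear H
    # dilation misbehaves; map through the full mixture CDFs instead
    # (monotone, handles any shape).
    h_dominant = n_states == 3 and (fit2.pi[1] > 0.5 or fit1.pi[1] > 0.5)
    if h_dominant:
        out = _mixture_quantile_map(xv, fit2, fit1)
        states = classify_states(xv, fit2)
    else:
        states = classify_states(xv, fit2)
        out = np.array(xv, copy=True)

    sU = states == 0
    sH = states == 1
    sM = states == 2
    # U: lower-tail quantile map onto the type I U component
    if sU.any() and not h_dominant:
        p = beta_dist.cdf(xv[sU], fit2.a[0], fit2.b[0])
        out[sU] = beta_dist.ppf(p, fit1.a[0], fit1.b[0])
    # M: upper-tail quantile map onto the type I M component
    if sM.any() and not h_dominant:
        p = beta_dist.sf(xv[sM], fit2.a[-1], fit2.b[-1])
        out[sM] = beta_dist.isf(p, fit1.a[-1], fit1.b[-1])
    # H: linear dilation between the mapped U and M anchors
    if sH.any() and not h_dominant:
        lo = out[sU].max() if sU.any() else beta_dist.ppf(0.01, fit1.a[0], fit1.b[0])
        hi = out[sM].min() if sM.any() else beta_dist.isf(0.01, fit1.a[-1], fit1.b[-1])
        h = xv[sH]
        hmin, hmax = h.min(), h.max()
        if hmax - hmin < 1e-12:
            out[sH] = 0.5 * (lo + hi)
        else:
            out[sH] = lo + (h - hmin) / (hmax - hmin) * (hi - lo)

    n_clamped = int(((out < 0) | (out > 1)).sum())
    out = np.clip(out, 0.0, 1.0)

    result = beta_column.copy()
    vals = result.to_numpy(dtype=float)
    idx2 = np.where(mask2)[0][finite2]
    vals[idx2] = out
    result = pd.Series(vals, index=beta_column.index, name=beta_column.name)
    if return_info:
        info = {
            "n_clamped": n_clamped,
            "fit_type1": fit1,
            "fit_type2": fit2,
            "states": states,
        }
        return result, info
    return result


def normalize_matrix(
    beta: BetaMatrix,
    n_states: int = 3,
    tol: float = 1e-4,
    max_iter: int = 100,
    allow_passthrough: bool = False,
) -> BetaMatrix:
    """Apply BMIQ independently to every sample of a matrix.

    Per-sample failures raise unless ``allow_passthrough`` is set, in
    which case the failing sample is kept un-normalized and recorded in
    ``meta['bmiq_failed_samples']``.
    """
    if beta.probe_type is None:
        raise ValueError("probe_type annotation required for BMIQ")
    cols = {}
    failed = []
    clamped = {}
    for sid in beta.sample_ids:
        try:
            col, info = bmiq_normalize_sample(
                beta.values[sid],
                beta.probe_type,
                n_states=n_states,
                tol=tol,
                max_iter=max_iter,
                return_info=True,
            )
            cols[sid] = col
            clamped[sid] = info["n_clamped"]
        except (ValueError, DegenerateFitError):
            if not allow_passthrough:
                raise
            cols[sid] = beta.values[sid]
            failed.append(sid)
    meta = dict(beta.meta)
    meta["normalized"] = True
    meta["bmiq_failed_samples"] = failed
    meta["bmiq_clamped"] = {k: int(v) for k, v in clamped.items() if v}
    return BetaMatrix(
        values=pd.DataFrame(cols).loc[beta.probe_ids, beta.sample_ids],
        detection_p=beta.detection_p,
        bead_count=beta.bead_count,
        probe_type=beta.probe_type,
        meta=meta,
    )
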