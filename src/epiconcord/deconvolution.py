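"""Cell-type composition estimation from methylation beta values.

Two routes, matching how blood and oral tissues are handled:

* **Reference-based** (blood): each sample's beta vector over a panel
  of cell-discriminating probes is regressed onto known cell-type
  methylomes under the constraints w >= 0, sum(w) = 1 (constrained
  projection).  Solved exactly with an active-set quadratic program.

* **Reference-free** (buccal, saliva): the beta matrix over the most
  variable probes is factorized as Y ~ M Omega^T with M in [0,1]
  (latent cell-type methylomes) and Omega rows on the simplex (mixing
  proportions), by alternating projected-gradient least squares, so the
  objective is monotone non-increasing.  The number of latent cell
  types K is chosen by minimizing a quantile-trimmed mean of bootstrap
  deviances: for each bootstrap resample of samples the model is refit
  (warm-started) and the Gaussian deviance of the out-of-bag samples is
  evaluated under the bootstrap fit's per-probe residual variances;
  overfitted K deflates those variances and is penalized, giving an
  interior minimum at the generative K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import trim_mean

from .containers import BetaMatrix, CellComposition

_VAR_FLOOR = 1e-6


class DeconvolutionError(ValueError):
    pass


# ---------------------------------------------------------------------
# simplex geometry
# ---------------------------------------------------------------------


def project_rows_to_simplex(x: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    x = np.atleast_2d(x)
    n, k = x.shape
    u = np.sort(x, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    idx = np.arange(1, k + 1)
    cond = u - css / idx > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(x - theta[:, None], 0.0)


def simplex_lsq(r: np.ndarray, y: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Exact min ||y - R w||^2 s.t. w >= 0, sum(w) = 1 (active set).

    R is probes x K with K small; deterministic.
    """
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    k = r.shape[1]
    if k == 1:
        return np.ones(1)
    gram = r.T @ r
    rhs = r.T @ y
    support = np.ones(k, dtype=bool)
    for _ in range(max_iter):
        ks = int(support.sum())
        kkt = np.zeros((ks + 1, ks + 1))
        kkt[:ks, :ks] = 2.0 * gram[np.ix_(support, support)]
        kkt[:ks, ks] = 1.0
        kkt[ks, :ks] = 1.0
        b = np.concatenate([2.0 * rhs[support], [1.0]])
        sol, *_ = np.linalg.lstsq(kkt, b, rcond=None)
        w_s = sol[:ks]
        if (w_s >= -1e-12).all():
            w = np.zeros(k)
            w[support] = np.maximum(w_s, 0.0)
            # KKT check: allow re-entry of a zeroed coordinate whose
            # gradient beats the equality multiplier
            mu = sol[ks]
            grad = 2.0 * (gram @ w - rhs)
            viol = ~support & (grad + mu < -1e-9)
            if not viol.any():
                total = w.sum()
                return w / total if total > 0 else np.full(k, 1.0 / k)
            support[np.argmin(np.where(viol, grad + mu, np.inf))] = True
            continue
        # drop the most negative coordinate
        idx = np.where(support)[0]
        support[idx[np.argmin(w_s)]] = False
        if not support.any():
            return np.full(k, 1.0 / k)
    return project_rows_to_simplex(w_s_full(gram, rhs, k))[0]


def w_s_full(gram: np.ndarray, rhs: np.ndarray, k: int) -> np.ndarray:
    sol, *_ = np.linalg.lstsq(2.0 * gram, 2.0 * rhs, rcond=None)
    return sol.reshape(1, k)


# ---------------------------------------------------------------------
# reference-based
# ---------------------------------------------------------------------


@dataclass
class CellReference:
    """Probe x cell-type mean-beta reference panel."""

    table: pd.DataFrame
    tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = self.table.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise DeconvolutionError("reference betas outside [0, 1]")
        if self.table.shape[1] < 2:
            raise DeconvolutionError("need at least 2 cell types")


def estimate_reference_based(
    beta: BetaMatrix | pd.DataFrame,
    ref: CellReference,
    max_missing_fraction: float = 0.2,
) -> CellComposition:
    """Constrained projection of each sample onto reference methylomes."""
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    shared = ref.table.index.intersection(values.index)
    missing_frac = 1.0 - len(shared) / len(ref.table.index)
    if missing_frac > max_missing_fraction:
        raise DeconvolutionError(
            f"{missing_frac:.1%} of reference probes absent from data "
            f"(cap {max_missing_fraction:.0%})"
        )
    r = ref.table.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(r) < r.shape[1]:
        raise DeconvolutionError("rank-deficient cell reference")
    rows = {}
    for sid in values.columns:
        y = values.loc[shared, sid].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        rows[sid] = simplex_lsq(r[ok], y[ok])
    props = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(ref.table.columns)
    )
    return CellComposition(
        proportions=props, method="reference", k=ref.table.shape[1]
    )


# ---------------------------------------------------------------------
# reference-free
# ---------------------------------------------------------------------


def select_variable_probes(
    beta: BetaMatrix | pd.DataFrame, n: int = 10000
) -> pd.Index:
    """The n probes with largest across-sample variance (ties: probe id)."""
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    if values.shape[0] < n:
        raise DeconvolutionError(
            f"only {values.shape[0]} probes available, asked for {n}"
        )
    var = values.var(axis=1, ddof=1, skipna=True)
    order = sorted(values.index, key=lambda pid: (-var[pid], pid))
    return pd.Index(order[:n])


def _objective(y: np.ndarray, m: np.ndarray, omega: np.ndarray) -> float:
    resid = y - m @ omega.T
    return float(np.sum(resid * resid))


def _init_cluster(y: np.ndarray, k: int) -> np.ndarray:
    """Cluster samples (columns) hierarchically; M0 = cluster means."""
    if k == 1:
        return y.mean(axis=1, keepdims=True)
    z = linkage(y.T, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    m0 = np.empty((y.shape[0], k))
    for j in range(1, k + 1):
        cols = labels == j
        m0[:, j - 1] = y[:, cols].mean(axis=1) if cols.any() else y.mean(axis=1)
    return m0


def fit_reference_free(
    beta_sub: pd.DataFrame | np.ndarray,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    n_inner: int = 5,
    init_m: np.ndarray | None = None,
):
    """Alternating constrained least squares Y ~ M Omega^T.

    M entries in [0,1]; Omega rows on the simplex.  Each half-update is
    a projected-gradient descent step with a 1/L step size, so the
    objective trace is monotone non-increasing.  Returns
    ``(M, Omega, info)`` with the objective trace and convergence flag.
    """
    is_df = isinstance(beta_sub, pd.DataFrame)
    y = beta_sub.to_numpy(dtype=float) if is_df else np.asarray(beta_sub, float)
    n_probes, n_samples = y.shape
    if k < 1:
        raise DeconvolutionError("K must be >= 1")
    if k > n_samples:
        raise DeconvolutionError(f"K={k} exceeds {n_samples} samples")

    if k == 1:
        m = y.mean(axis=1, keepdims=True)
        omega = np.ones((n_samples, 1))
        info = {"objective": [_objective(y, m, omega)], "converged": True}
    else:
        m = np.clip(init_m if init_m is not None else _init_cluster(y, k), 0.0, 1.0)
        omega = np.vstack([simplex_lsq(m, y[:, j]) for j in range(n_samples)])
        trace = [_objective(y, m, omega)]
        converged = False
        for _ in range(max_iter):
            # Omega half-step(s)
            gram_m = m.T @ m
            lip = 2.0 * max(np.linalg.eigvalsh(gram_m)[-1], 1e-12)
            ytm = y.T @ m
            for _ in range(n_inner):
                grad = 2.0 * (omega @ gram_m - ytm)
                omega = project_rows_to_simplex(omega - grad / lip)
            # M half-step(s)
            gram_o = omega.T @ omega
            lip = 2.0 * max(np.linalg.eigvalsh(gram_o)[-1], 1e-12)
            yo = y @ omega
            for _ in range(n_inner):
                grad = 2.0 * (m @ gram_o - yo)
                m = np.clip(m - grad / lip, 0.0, 1.0)
            obj = _objective(y, m, omega)
            trace.append(obj)
            # decrease measured relative to the starting objective so the
            # criterion stays meaningful when the fit is near-exact
            if trace[-2] - obj < tol * max(trace[0], 1e-12):
                converged = True
                break
        if not converged:
            warnings.warn(
                f"reference-free fit (K={k}) did not converge in {max_iter} "
                "iterations; returning best iterate",
                stacklevel=2,
            )
        info = {"objective": trace, "converged": converged}

    comp_names = [f"component{j + 1}" for j in range(k)]
    if is_df:
        m_out = pd.DataFrame(m, index=beta_sub.index, columns=comp_names)
        omega_out = pd.DataFrame(omega, index=beta_sub.columns, columns=comp_names)
    else:
        m_out, omega_out = m, omega
    return m_out, omega_out, info


def _as_array(x) -> np.ndarray:
    return x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)


def _gaussian_deviance_per_column(resid: np.ndarray, var: np.ndarray) -> float:
    """Mean per-column -2 log-likelihood under probe-wise Gaussians."""
    n_cols = resid.shape[1]
    quad = float(np.sum(resid * resid / var[:, None]))
    logdet = float(np.sum(np.log(2.0 * np.pi * var)))
    return quad / n_cols + logdet


@dataclass
class DevianceProfile:
    """Bootstrap deviance profile over candidate K values."""

    k_values: list[int]
    boot_deviances: pd.DataFrame  # K x n_boot
    trimmed_mean: pd.Series  # per K
    in_sample: pd.Series  # per K
    chosen_k: int
    trim: float
    n_boot: int


def choose_k(
    beta_sub: pd.DataFrame | np.ndarray,
    k_range=range(1, 16),
    n_boot: int = 1000,
    trim: float = 0.25,
    seed: int = 0,
    fit_max_iter: int = 200,
    boot_max_iter: int = 40,
    tol: float = 1e-6,
) -> DevianceProfile:
    """Pick the number of latent cell types by trimmed bootstrap deviance.

    For each K: fit on the full data; then for each bootstrap draw of
    samples (columns, with replacement) refit warm-started from the
    full fit and score the out-of-bag samples' Gaussian deviance under
    the bootstrap fit.  Chosen K minimizes the per-tail-trimmed mean
    over bootstraps.  Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise DeconvolutionError("n_boot must be >= 2")
    if not 0.0 <= trim < 0.5:
        raise DeconvolutionError("trim must lie in [0, 0.5)")
    y = _as_array(beta_sub)
    n_probes, n_samples = y.shape
    k_values = [int(k) for k in k_range]
    if max(k_values) > n_samples:
        raise DeconvolutionError("k_range exceeds the number of samples")

    # common bootstrap draws across K: the per-draw deviances are then
    # paired, so differences between K values are not swamped by
    # draw-to-draw variation
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n_samples, size=n_samples)
            oob = np.setdiff1d(np.arange(n_samples), idx)
            if len(oob):
                break
        draws.append((idx, oob))

    boot_rows = {}
    in_sample = {}
    for k in k_values:
        m_full, omega_full, _ = fit_reference_free(
            y, k, tol=tol, max_iter=fit_max_iter, seed=seed
        )
        resid_full = y - m_full @ omega_full.T
        var_full = np.maximum((resid_full**2).mean(axis=1), _VAR_FLOOR)
        in_sample[k] = _gaussian_deviance_per_column(resid_full, var_full)

        devs = np.empty(n_boot)
        for b, (idx, oob) in enumerate(draws):
            # cold (cluster-based) init on the bootstrap columns: with
            # K above the generative rank the refit chases bootstrap-
            # specific structure, which the out-of-bag deviance punishes
            m_b, omega_b, _ = fit_reference_free(
                y[:, idx],
                k,
                tol=1e-5,
                max_iter=boot_max_iter,
                seed=seed,
            )
            m_b = _as_array(m_b)
            resid_b = y[:, idx] - m_b @ _as_array(omega_b).T
            var_b = np.maximum((resid_b**2).mean(axis=1), _VAR_FLOOR)
            omega_oob = np.vstack([simplex_lsq(m_b, y[:, j]) for j in oob])
            resid_oob = y[:, oob] - m_b @ omega_oob.T
            devs[b] = _gaussian_deviance_per_column(resid_oob, var_b)
        boot_rows[k] = devs

    boot = pd.DataFrame.from_dict(boot_rows, orient="index")
    trimmed = pd.Series(
        {k: float(trim_mean(boot.loc[k], proportiontocut=trim)) for k in k_values}
    )
    chosen = int(trimmed.idxmin())
    return DevianceProfile(
        k_values=k_values,
        boot_deviances=boot,
        trimmed_mean=trimmed,
        in_sample=pd.Series(in_sample),
        chosen_k=chosen,
        trim=trim,
        n_boot=n_boot,
    )
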