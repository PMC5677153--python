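"""REML fitting of the hybrid mixed model and Wald tests of fixed blocks.

Model: y = X b + Z_D u_D + Z_F u_F + e with u_D ~ N(0, I sigma2_D),
u_F ~ N(0, I sigma2_F), e ~ N(0, I sigma2_e). The residual variance is
profiled out and the two variance ratios are maximized by bounded
quasi-Newton with multiple starts; fixed effects follow by GLS at the
optimum. Wald tests of coefficient blocks are conditional (added-last)
chi-square tests on the GLS coefficient covariance; with both variance
components fixed at zero they reduce exactly to df x the OLS F statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

_LOG10 = np.log(10.0)
_RANK_TOL = 1e-9


@dataclass
class VarianceComponents:
    sigma2_D: float
    sigma2_F: float
    sigma2_e: float
    loglik: float
    converged: bool
    boundary: bool  # a component sits at the zero bound
    confounded: bool  # a parental incidence is the identity (variance inseparable)


@dataclass
class MixedFit:
    """REML solution with enough state to whiten further columns."""

    vc: VarianceComponents
    beta: np.ndarray
    cov_beta: np.ndarray
    names: list[str]
    chol_V0: np.ndarray | None  # cholesky of I + tD K_D + tF K_F; None = identity
    y: np.ndarray
    X: np.ndarray
    y_white: np.ndarray  # whitened by chol_V0 only (residual variance excluded)
    X_white: np.ndarray

    def whiten(self, M: np.ndarray) -> np.ndarray:
        if self.chol_V0 is None:
            return M
        return linalg.solve_triangular(self.chol_V0, M, lower=True)

    def fixed_predictions(self, X: np.ndarray | None = None) -> np.ndarray:
        return (self.X if X is None else X) @ self.beta


def _neg_reml(theta: np.ndarray, y: np.ndarray, X: np.ndarray, K_D: np.ndarray, K_F: np.ndarray) -> float:
    n, p = X.shape
    V0 = np.eye(n) + theta[0] * K_D + theta[1] * K_F
    try:
        L = linalg.cholesky(V0, lower=True)
    except linalg.LinAlgError:
        return np.inf
    Xs = linalg.solve_triangular(L, X, lower=True)
    ys = linalg.solve_triangular(L, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    rss = float(np.sum((ys - Xs @ beta) ** 2))
    if rss <= 0:
        return np.inf
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdetXtX = np.linalg.slogdet(Xs.T @ Xs)
    if sign <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    ll = -0.5 * (logdetV + logdetXtX + (n - p) * (np.log(sigma2) + 1.0))
    return -ll


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z_D: np.ndarray | None,
    Z_F: np.ndarray | None,
    names: list[str] | None = None,
    n_starts: int = 3,
    fix_zero: bool = False,
    fixed_theta: tuple[float, float] | None = None,
    max_ratio: float = 1e4,
) -> MixedFit:
    """REML over (sigma2_D, sigma2_F, sigma2_e) with non-negativity.

    ``fix_zero`` pins both parental components at zero (pure OLS), used for
    fixed-effects-only analyses and the Wald/F identity. ``fixed_theta``
    holds the variance ratios (sigma2_D/sigma2_e, sigma2_F/sigma2_e) at given
    values and only profiles the residual variance and the GLS fixed effects
    (the fast path for scans that estimate components once). Boundary
    solutions are flagged, not errors. A design in which every parent appears
    exactly once makes its component inseparable from the residual; the fit
    proceeds but carries ``confounded=True``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} must exceed rank of the fixed design ({p})")
    names = names or [f"b{j}" for j in range(p)]
    confounded = False
    for Z in (Z_D, Z_F):
        if Z is not None and Z.shape[1] >= Z.shape[0]:
            confounded = True

    if fix_zero or Z_D is None or Z_F is None:
        theta = np.zeros(2)
        converged = True
        beta0, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss0 = float(np.sum((y - X @ beta0) ** 2))
        sign, logdetXtX = np.linalg.slogdet(X.T @ X)
        sigma2 = rss0 / (n - p)
        nll = 0.5 * (logdetXtX + (n - p) * (np.log(sigma2) + 1.0))
        K_D = K_F = None
    elif fixed_theta is not None:
        theta = np.asarray(fixed_theta, dtype=float)
        converged = True
        K_D = Z_D @ Z_D.T
        K_F = Z_F @ Z_F.T
        nll = _neg_reml(theta, y, X, K_D, K_F)
    else:
        K_D = Z_D @ Z_D.T
        K_F = Z_F @ Z_F.T
        starts = [(0.1, 0.1), (1.0, 1.0), (0.01, 0.5)][:n_starts]
        best = None
        converged = False
        for s in starts:
            res = optimize.minimize(
                _neg_reml,
                x0=np.asarray(s),
                args=(y, X, K_D, K_F),
                method="L-BFGS-B",
                bounds=[(0.0, max_ratio)] * 2,
                options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 200},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            converged = converged or bool(res.success)
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("REML optimization failed to produce a finite likelihood")
        theta = best.x
        nll = best.fun
        if not converged:
            raise RuntimeError(f"REML did not converge: {best.message}")

    if np.all(theta == 0.0):
        L = None
        Xs, ys = X, y
    else:
        V0 = np.eye(n) + theta[0] * K_D + theta[1] * K_F
        L = linalg.cholesky(V0, lower=True)
        Xs = linalg.solve_triangular(L, X, lower=True)
        ys = linalg.solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    rss = float(np.sum((ys - Xs @ beta) ** 2))
    sigma2_e = rss / (n - p)
    cov_beta = sigma2_e * linalg.pinvh(Xs.T @ Xs)
    vc = VarianceComponents(
        sigma2_D=float(theta[0] * sigma2_e),
        sigma2_F=float(theta[1] * sigma2_e),
        sigma2_e=float(sigma2_e),
        loglik=float(-nll),
        converged=converged,
        boundary=bool(np.any(theta <= 1e-8)),
        confounded=confounded,
    )
    return MixedFit(vc, beta, cov_beta, names, L, y, X, ys, Xs)


@dataclass
class WaldResult:
    W: float
    df: int
    p: float
    neglog10p: float


def wald_from_cov(beta: np.ndarray, cov: np.ndarray, idx: np.ndarray) -> WaldResult:
    """Chi-square Wald test of H0: beta[idx] = 0 using the coefficient covariance.

    A singular contrast covariance is handled by its pseudo-inverse with the
    degrees of freedom reduced to the covariance rank.
    """
    b = beta[idx]
    C = cov[np.ix_(idx, idx)]
    vals, vecs = linalg.eigh(C)
    tol = max(C.shape[0], 1) * np.max(np.abs(vals), initial=0.0) * _RANK_TOL
    keep = vals > tol
    df = int(keep.sum())
    if df == 0:
        return WaldResult(0.0, 0, 1.0, 0.0)
    z = vecs[:, keep].T @ b
    W = float(np.sum(z**2 / vals[keep]))
    logp = stats.chi2.logsf(W, df)
    return WaldResult(W, df, float(np.exp(logp)), float(-logp / _LOG10))


def added_block_test(
    y_res: np.ndarray,
    block_res: np.ndarray,
    sigma2_e: float,
    components: dict[str, np.ndarray] | None = None,
    residual_dof: int | None = None,
) -> tuple[WaldResult, dict[str, WaldResult], np.ndarray]:
    """Wald test of a fixed block added last to a whitened model.

    ``y_res`` and ``block_res`` are the whitened response and block columns
    residualized against everything already in the model; by partitioned
    regression the block's GLS coefficients and covariance in the full model
    are recovered from this reduced problem. When ``residual_dof`` (the
    residual degrees of freedom of the conditioning model, n - p) is given,
    the residual variance is re-profiled under the full model including the
    block, which makes the statistic reduce exactly to df x the OLS F under
    an identity covariance. Returns the global test, the per-component tests
    and the block coefficients.
    """
    G = block_res.T @ block_res
    g = block_res.T @ y_res
    vals, vecs = linalg.eigh(G)
    tol = max(G.shape[0], 1) * np.max(np.abs(vals), initial=0.0) * _RANK_TOL
    keep = vals > tol
    Ginv = (vecs[:, keep] / vals[keep]) @ vecs[:, keep].T
    b = Ginv @ g
    df = int(keep.sum())
    if residual_dof is not None and residual_dof - df > 0:
        rss1 = float(y_res @ y_res - b @ g)
        sigma2_e = max(rss1 / (residual_dof - df), 1e-300)
    cov = sigma2_e * Ginv
    W = float(b @ g) / sigma2_e
    if df == 0:
        global_res = WaldResult(0.0, 0, 1.0, 0.0)
    else:
        logp = stats.chi2.logsf(W, df)
        global_res = WaldResult(W, df, float(np.exp(logp)), float(-logp / _LOG10))
    comp_res = {}
    if components:
        for name, idx in components.items():
            comp_res[name] = wald_from_cov(b, cov, np.asarray(idx))
    return global_res, comp_res, b
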