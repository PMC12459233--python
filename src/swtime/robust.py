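"""Model-based and cluster-robust variance estimators for estimand contrasts.

All variances target a scalar contrast ``c' betahat`` of a fitted model, on the
cluster-period-mean scale on which estimation is performed.

Model-based
    ``c' (Z' Vhat^-1 Z)^-1 c`` with the working covariance at its estimated
    overall scale; intervals use normal quantiles by default (a t reference with
    ``I - Q`` degrees of freedom is available).

Cluster-robust (sandwich)
    ``sum_i (c' B Z_i' W_i A_i ehat_i)^2`` with bread ``B = (Z' W Z)^-1``,
    working weights ``W = V^-1`` and per-cluster residual adjustments:

    * CR0 — raw residuals, ``A_i = I``;
    * CR2 — bias-reduced linearization: the symmetric-square-root-type adjustment
      that makes the estimator exactly unbiased when the working covariance is
      correct.  With GLS weights the residual covariance block is
      ``S_i = Phi_i - Z_i B Z_i'``, and ``A_i = Phi^{1/2} T^{-1/2} Phi^{-1/2}``
      with ``T = Phi^{-1/2} S_i Phi^{-1/2}`` satisfies
      ``A_i S_i A_i' = Phi_i`` exactly;
    * CR3 — "approximate jackknife": the full inverse ``A_i = (I - H_ii)^{-1}``
      of the leverage block ``H_ii = Z_i B Z_i' W_i``.

    CR2 and CR3 intervals use Satterthwaite degrees of freedom computed from the
    working covariance of the full residual vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .correlation import cluster_block, cluster_block_inverse_coeffs
from .gls import GLSFit, GLSWorkspace, EstimationError

ROBUST_TYPES = ("CR0", "CR2", "CR3")


@dataclass(frozen=True)
class VarianceReport:
    estimator_type: str  # "model", "CR0", "CR2", or "CR3"
    variance: float
    dof: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def _interval(estimate: float, variance: float, dof: float) -> tuple[float, float]:
    se = np.sqrt(variance)
    crit = stats.norm.ppf(0.975) if np.isinf(dof) else stats.t.ppf(0.975, dof)
    return float(estimate - crit * se), float(estimate + crit * se)


def model_variance(
    fit: GLSFit, contrast: np.ndarray, *, use_t: bool = False
) -> VarianceReport:
    """Model-based variance and 95% CI of the contrast ``c' betahat``."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.coef.size,):
        raise EstimationError(
            f"contrast length {c.size} does not match {fit.coef.size} coefficients"
        )
    var = float(c @ fit.vcov_model @ c)
    if var < 0:
        raise EstimationError(f"model-based variance is negative ({var:.3e})")
    if use_t:
        dof = float(fit.n_clusters - fit.design.Q)
        if dof <= 0:
            raise EstimationError(
                f"no degrees of freedom for a t interval: I={fit.n_clusters}, "
                f"Q={fit.design.Q}"
            )
    else:
        dof = np.inf
    est = float(c @ fit.coef)
    lo, hi = _interval(est, var, dof)
    return VarianceReport("model", var, dof, lo, hi)


def cluster_robust_variance(
    fit: GLSFit,
    data=None,
    contrast: np.ndarray | None = None,
    type: str = "CR2",
) -> VarianceReport:
    """Cluster-robust variance and 95% CI for ``c' betahat``.

    ``data`` may supply long trial data from which residuals are recomputed;
    by default the residuals stored on the fit are used.
    """
    if type not in ROBUST_TYPES:
        raise EstimationError(f"unknown robust type {type!r}; expected {ROBUST_TYPES}")
    if contrast is None:
        raise EstimationError("a contrast vector is required")
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.coef.size,):
        raise EstimationError(
            f"contrast length {c.size} does not match {fit.coef.size} coefficients"
        )
    design = fit.design
    if design.I < 2:
        raise EstimationError("cluster-robust variance requires at least 2 clusters")
    if data is not None:
        from .gls import cluster_period_means, fit_gls

        ybar = cluster_period_means(data, design)
        refit = fit_gls(ybar, design, fit.kind, fit.gamma_used)
        resid = refit.residuals
    else:
        resid = fit.residuals

    I, J = design.I, design.J
    ws = GLSWorkspace(design, fit.kind)
    Z = ws.Z
    a, b = cluster_block_inverse_coeffs(J, fit.gamma_used)
    W = a * np.eye(J) + b * np.ones((J, J))  # unit-scale working V^-1 block
    Phi = cluster_block(J, fit.gamma_used)  # unit-scale working covariance block
    from .gls import _spd_inverse

    B = _spd_inverse(ws.normal_matrix(fit.gamma_used), ws.names)  # (Z'WZ)^-1, unit scale

    u_rows = np.empty((I, J))  # u_i' with variance = sum_i (u_i' e_i)^2
    for i in range(I):
        Zi = Z[i * J : (i + 1) * J]
        Ai = _adjustment(type, Zi, W, Phi, B, cluster=i + 1)
        u_rows[i] = (c @ B) @ Zi.T @ W @ Ai
    e = resid.reshape(I, J)
    var = float(np.sum((u_rows * e).sum(axis=1) ** 2))

    if type in ("CR2", "CR3"):
        dof = _satterthwaite_dof(u_rows, Z, W, Phi, B, I, J)
    else:
        dof = float(I - 1)
    est = float(c @ fit.coef)
    lo, hi = _interval(est, var, dof)
    return VarianceReport(type, var, dof, lo, hi)


def _adjustment(
    type: str, Zi: np.ndarray, W: np.ndarray, Phi: np.ndarray, B: np.ndarray, cluster: int
) -> np.ndarray:
    J = Zi.shape[0]
    if type == "CR0":
        return np.eye(J)
    Hii = Zi @ B @ Zi.T @ W
    if type == "CR3":
        try:
            return np.linalg.inv(np.eye(J) - Hii)
        except np.linalg.LinAlgError:
            raise EstimationError(
                f"cluster {cluster} is fully leveraged; CR3 adjustment is singular"
            ) from None
    # CR2: A Phi^... exactly unbiased under the working covariance
    Phi_half = _sym_power(Phi, 0.5)
    Phi_nhalf = _sym_power(Phi, -0.5)
    S = Phi - Zi @ B @ Zi.T
    T = Phi_nhalf @ S @ Phi_nhalf
    T = (T + T.T) / 2
    vals, vecs = np.linalg.eigh(T)
    if np.any(vals < 1e-12):
        raise EstimationError(
            f"cluster {cluster} is fully leveraged; CR2 adjustment is singular"
        )
    T_nhalf = (vecs / np.sqrt(vals)) @ vecs.T
    return Phi_half @ T_nhalf @ Phi_nhalf


def _sym_power(A: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh((A + A.T) / 2)
    return (vecs * vals**power) @ vecs.T


def _satterthwaite_dof(
    u_rows: np.ndarray, Z: np.ndarray, W: np.ndarray, Phi: np.ndarray,
    B: np.ndarray, I: int, J: int,
) -> float:
    """Satterthwaite dof of sum_i (u_i' ehat_i)^2 under the working covariance.

    With ``ehat = (I - H) y`` and ``Cov(y) = blockdiag(Phi)``, the estimator is a
    quadratic form whose component covariance matrix is
    ``Omega_il = u_i' [(I - H) Phi_full (I - H)']_il u_l``;
    dof = tr(Omega)^2 / tr(Omega^2).  Scale-free, so unit-scale blocks suffice.
    """
    n = I * J
    Wfull = np.kron(np.eye(I), W)
    H = Z @ B @ Z.T @ Wfull
    G = np.eye(n) - H
    # columns l: G' restricted to block l applied to u_l -> n x I matrix
    U = np.zeros((n, I))
    for l in range(I):
        U[:, l] = G[l * J : (l + 1) * J].T @ u_rows[l]
    Phi_full = np.kron(np.eye(I), Phi)
    Omega = U.T @ Phi_full @ U
    tr = np.trace(Omega)
    tr2 = np.sum(Omega * Omega.T)
    if tr2 <= 0:
        return float(I - 1)
    return float(tr**2 / tr2)
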