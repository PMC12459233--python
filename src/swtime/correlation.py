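"""Variance components and the nested exchangeable covariance of cluster-period means.

The outcome model carries a cluster random intercept ``alpha_i ~ N(0, tau_alpha^2)``,
a cluster-period interaction ``omega_ij ~ N(0, tau_omega^2)`` and residuals
``eps_ijk ~ N(0, sigma_e^2)``.  With ``K`` individuals per cell the cluster-period
means ``Ybar_ij`` then have variance ``tau_alpha^2 + tau_omega^2 + sigma_e^2 / K``
and within-cluster correlation

    gamma = tau_alpha^2 / (tau_alpha^2 + tau_omega^2 + sigma_e^2 / K)

so each cluster's J x J covariance block is
``Var(Ybar) * ((1 - gamma) I_J + gamma J_J)`` with ``J_J`` the all-ones matrix.
``gamma = 0`` is the independence working model, ``tau_omega^2 = 0`` the
exchangeable one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CorrelationError(ValueError):
    """Invalid variance components or correlation parameters."""


@dataclass(frozen=True)
class VarianceComponents:
    tau_alpha_sq: float
    tau_omega_sq: float
    sigma_e_sq: float

    def __post_init__(self) -> None:
        vals = (self.tau_alpha_sq, self.tau_omega_sq, self.sigma_e_sq)
        if not all(np.isfinite(v) for v in vals):
            raise CorrelationError(f"variance components must be finite, got {vals}")
        if self.tau_alpha_sq < 0 or self.tau_omega_sq < 0:
            raise CorrelationError(f"random-effect variances must be >= 0, got {vals}")
        if self.sigma_e_sq <= 0:
            raise CorrelationError(
                f"residual variance must be > 0, got sigma_e_sq={self.sigma_e_sq}"
            )

    def total_mean_variance(self, K: int) -> float:
        """Var(Ybar_ij) = tau_alpha^2 + tau_omega^2 + sigma_e^2 / K."""
        if K < 1:
            raise CorrelationError(f"cell size must be >= 1, got K={K}")
        return self.tau_alpha_sq + self.tau_omega_sq + self.sigma_e_sq / K


def gamma(vc: VarianceComponents, K: int) -> float:
    """Within-cluster correlation of cluster-period means."""
    denom = vc.total_mean_variance(K)
    if denom <= 0:
        raise CorrelationError("total cluster-period-mean variance must be positive")
    return vc.tau_alpha_sq / denom


def icc_summaries(vc: VarianceComponents) -> tuple[float, float]:
    """Return (within-period ICC, cluster autocorrelation).

    wpICC = (tau_alpha^2 + tau_omega^2) / (tau_alpha^2 + tau_omega^2 + sigma_e^2);
    CAC   = tau_alpha^2 / (tau_alpha^2 + tau_omega^2), an error when both
    random-effect variances are zero.
    """
    cluster_var = vc.tau_alpha_sq + vc.tau_omega_sq
    total = cluster_var + vc.sigma_e_sq
    if total <= 0:
        raise CorrelationError("total variance must be positive")
    wpicc = cluster_var / total
    if cluster_var == 0:
        raise CorrelationError(
            "CAC undefined: tau_alpha^2 + tau_omega^2 = 0 (no cluster-level variance)"
        )
    cac = vc.tau_alpha_sq / cluster_var
    return wpicc, cac


def solve_components(wpicc: float, cac: float, sigma_e_sq: float) -> VarianceComponents:
    """Invert icc_summaries: components from (wpICC, CAC, sigma_e^2).

    wpICC = T / (T + sigma_e^2) with T = tau_alpha^2 + tau_omega^2 gives
    T = sigma_e^2 * wpICC / (1 - wpICC); CAC then splits T.  When wpICC is 0 the
    components are (0, 0) and CAC is ignored.
    """
    if not 0 <= wpicc < 1:
        raise CorrelationError(f"wpICC must lie in [0, 1), got {wpicc}")
    if sigma_e_sq <= 0:
        raise CorrelationError(f"sigma_e_sq must be > 0, got {sigma_e_sq}")
    if wpicc == 0:
        return VarianceComponents(0.0, 0.0, float(sigma_e_sq))
    if not 0 < cac <= 1:
        raise CorrelationError(f"CAC must lie in (0, 1], got {cac}")
    total_cluster = sigma_e_sq * wpicc / (1.0 - wpicc)
    return VarianceComponents(
        tau_alpha_sq=cac * total_cluster,
        tau_omega_sq=(1.0 - cac) * total_cluster,
        sigma_e_sq=float(sigma_e_sq),
    )


def cluster_block(J: int, gamma: float, total_var: float = 1.0) -> np.ndarray:
    """J x J covariance block ``total_var * ((1 - gamma) I_J + gamma J_J)``."""
    _check_gamma(gamma)
    if total_var <= 0:
        raise CorrelationError(f"total_var must be > 0, got {total_var}")
    return total_var * ((1.0 - gamma) * np.eye(J) + gamma * np.ones((J, J)))


def cluster_block_inverse_coeffs(J: int, gamma: float) -> tuple[float, float]:
    """Coefficients (a, b) with block^{-1} = a I_J + b J_J, for unit total_var.

    Standard compound-symmetry inverse: a = 1/(1-gamma),
    b = -gamma / ((1-gamma)(1 + (J-1) gamma)).
    """
    _check_gamma(gamma)
    a = 1.0 / (1.0 - gamma)
    b = -gamma / ((1.0 - gamma) * (1.0 + (J - 1) * gamma))
    return a, b


def cluster_block_logdet(J: int, gamma: float) -> float:
    """log-determinant of the unit-total_var block: eigenvalues ``1 - gamma``
    (multiplicity J-1) and ``1 + (J-1) gamma`` (multiplicity 1)."""
    _check_gamma(gamma)
    return (J - 1) * np.log1p(-gamma) + np.log1p((J - 1) * gamma)


def _check_gamma(gamma: float) -> None:
    if not (0.0 <= gamma < 1.0):
        raise CorrelationError(f"gamma must lie in [0, 1), got {gamma}")
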