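"""GLS / feasible-GLS / OLS estimation of SW-CRT treatment-effect models.

Estimation operates on cluster-period means, which are sufficient for the fixed
effects under a complete balanced design: ``betahat = (Z' V^-1 Z)^-1 Z' V^-1 Ybar``
with ``V = I_I (x) R_i`` block diagonal and
``R_i = Var(Ybar) ((1-gamma) I_J + gamma J_J)``.  The overall scale ``Var(Ybar)``
cancels from the point estimator, so solves are done with unit-scale blocks; the
scale re-enters only in the model-based covariance, where it is estimated from the
GLS residuals.  ``gamma = 0`` reproduces ordinary least squares on the means
exactly (the independence working model).

Feasible GLS estimates the variance components from the data: the residual
variance ``sigma_e^2`` by the pooled within-cell sample variance (exact under
balance, where within-cell contrasts depend on no other component) and
``(gamma, Var(Ybar))`` by restricted maximum likelihood on the cluster-period
means, a one-dimensional profile over gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .correlation import (
    VarianceComponents,
    cluster_block_inverse_coeffs,
    cluster_block_logdet,
)
from .design import Design, Kind, TreatmentStructure, design_matrix, _check_kind

logger = logging.getLogger(__name__)

ESTIMAND_LABEL = {"IT": "IT", "ETI": "ETATE", "CTI": "CTATE"}


class EstimationError(RuntimeError):
    """Estimation failed (singular system, malformed data, non-convergence)."""


# ---------------------------------------------------------------------------
# trial data handling
# ---------------------------------------------------------------------------

def cluster_period_means(data: pd.DataFrame, design: Design) -> np.ndarray:
    """Collapse long trial data to the canonical vector of cluster-period means.

    ``data`` must contain columns (cluster, period) plus either individual
    outcomes ``y`` (exactly K rows per cell) or precomputed means ``ybar`` (one
    row per cell).  A ``sequence`` column, if present, is validated against the
    design's allocation.  Returns means ordered cluster-major, period-minor.
    """
    required = {"cluster", "period"}
    if not required <= set(data.columns):
        raise EstimationError(f"data must contain columns {sorted(required)}")
    if "sequence" in data.columns:
        seq_map = data.groupby("cluster")["sequence"].agg(["min", "max"])
        if not (seq_map["min"] == seq_map["max"]).all():
            raise EstimationError("inconsistent sequence labels within a cluster")
        expected = design.seq_of_cluster
        for i, q in seq_map["min"].items():
            if not 1 <= int(i) <= design.I or int(q) != expected[int(i) - 1]:
                raise EstimationError(
                    f"cluster {i} labelled sequence {q}, design expects "
                    f"{expected[int(i) - 1] if 1 <= int(i) <= design.I else '?'}"
                )
    value_col = "ybar" if "ybar" in data.columns else "y"
    if value_col not in data.columns:
        raise EstimationError("data must contain a 'y' or 'ybar' column")
    counts = data.groupby(["cluster", "period"], sort=True)[value_col].agg(
        ["count", "mean"]
    )
    expected_rows = 1 if value_col == "ybar" else design.K
    if len(counts) != design.n_cells or not (counts["count"] == expected_rows).all():
        raise EstimationError(
            f"unbalanced data: expected every one of {design.n_cells} "
            f"(cluster, period) cells with exactly {expected_rows} row(s)"
        )
    full = counts["mean"].unstack("period")
    full = full.reindex(index=range(1, design.I + 1), columns=range(1, design.J + 1))
    ybar = full.to_numpy(dtype=float).ravel()
    if not np.all(np.isfinite(ybar)):
        raise EstimationError("missing or non-finite cluster-period cells")
    return ybar


def pooled_within_cell_variance(data: pd.DataFrame, design: Design) -> float:
    """Pooled within-(cluster, period) sample variance of individual outcomes."""
    if "y" not in data.columns:
        raise EstimationError("individual-level 'y' column required")
    if design.K < 2:
        raise EstimationError("cell size K >= 2 required to estimate sigma_e^2")
    g = data.groupby(["cluster", "period"])["y"]
    ss = (g.var(ddof=1)).mean()
    return float(ss)


# ---------------------------------------------------------------------------
# workspace: reusable per-(design, kind) linear algebra
# ---------------------------------------------------------------------------

class GLSWorkspace:
    """Precomputed matrices for repeated GLS solves on one (design, kind).

    With block inverse ``a I + b J`` per cluster, the normal matrix is
    ``Z' V^-1 Z = a Z'Z + b S'S`` where row i of ``S`` holds cluster i's column
    sums of ``Z``; right-hand sides collapse analogously.  Repeated fits (new
    outcome vectors or new gamma) therefore cost only small-matrix work.
    """

    def __init__(self, design: Design, kind: Kind):
        _check_kind(kind)
        self.design = design
        self.kind = kind
        self.Z, self.names = design_matrix(design, kind)
        self.n, self.p = self.Z.shape
        self.n_treat = design.n_treatment_columns(kind)
        self.ZtZ = self.Z.T @ self.Z
        # per-cluster column sums of Z: shape (I, p)
        self.S = self.Z.reshape(design.I, design.J, self.p).sum(axis=1)

    def normal_matrix(self, gamma: float) -> np.ndarray:
        a, b = cluster_block_inverse_coeffs(self.design.J, gamma)
        return a * self.ZtZ + b * (self.S.T @ self.S)

    def solve(self, ybar: np.ndarray, gamma: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Return (coef, M, gls_rss) where M = (Z' V^-1 Z)^-1 at unit scale."""
        a, b = cluster_block_inverse_coeffs(self.design.J, gamma)
        A = self.normal_matrix(gamma)
        t = ybar.reshape(self.design.I, self.design.J).sum(axis=1)
        rhs = a * (self.Z.T @ ybar) + b * (self.S.T @ t)
        M = _spd_inverse(A, self.names)
        coef = M @ rhs
        resid = ybar - self.Z @ coef
        rt = resid.reshape(self.design.I, self.design.J).sum(axis=1)
        rss = a * float(resid @ resid) + b * float(rt @ rt)
        return coef, M, rss

    def hat_matrix(self, gamma: float) -> np.ndarray:
        """p x n matrix H with ``coef = H @ ybar`` (linear estimator rows)."""
        a, b = cluster_block_inverse_coeffs(self.design.J, gamma)
        M = _spd_inverse(self.normal_matrix(gamma), self.names)
        ZtVinv = a * self.Z.T.copy()
        for i in range(self.design.I):
            sl = slice(i * self.design.J, (i + 1) * self.design.J)
            ZtVinv[:, sl] += b * self.S[i][:, None]
        return M @ ZtVinv

    def reml_gamma(self, ybar: np.ndarray) -> tuple[float, float]:
        """REML estimate of (gamma, Var(Ybar)) on the cluster-period means."""
        dof = self.n - self.p
        if dof <= 0:
            raise EstimationError("no residual degrees of freedom for REML")

        def neg2reml(g: float) -> float:
            A = self.normal_matrix(g)
            _, M, rss = self.solve(ybar, g)
            sign, logdet_A = np.linalg.slogdet(A)
            if sign <= 0 or rss <= 0:
                return np.inf
            return (
                dof * np.log(rss / dof)
                + self.design.I * cluster_block_logdet(self.design.J, g)
                + logdet_A
            )

        res = minimize_scalar(neg2reml, bounds=(0.0, 0.999), method="bounded",
                              options={"xatol": 1e-10})
        if not res.success or not np.isfinite(res.fun):
            raise EstimationError(f"REML profile over gamma failed: {res.message}")
        # the bounded minimizer never evaluates the boundary exactly; snap to 0
        # when the profile is monotone increasing there
        g = float(res.x)
        if g < 1e-8 or neg2reml(0.0) <= res.fun:
            g = 0.0
        _, _, rss = self.solve(ybar, g)
        return g, rss / dof


def _spd_inverse(A: np.ndarray, names: list[str]) -> np.ndarray:
    """Inverse of the SPD normal matrix; pseudo-inverse fallback with rank check."""
    try:
        L = np.linalg.cholesky(A)
        Linv = np.linalg.inv(L)
        return Linv.T @ Linv
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(A, tol=1e-10 * np.linalg.norm(A))
        if rank < A.shape[0]:
            raise EstimationError(
                f"singular normal equations (rank {rank} < {A.shape[0]}) "
                f"for columns {names}"
            ) from None
        return np.linalg.pinv(A)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class GLSFit:
    """A fitted treatment-effect model on cluster-period means."""

    kind: Kind
    correlation: str  # "nested_exchangeable" or "independence"
    coef: np.ndarray
    coef_names: list[str]
    gamma_used: float
    scale: float  # estimated Var(Ybar) at unit-scale working blocks
    vcov_model: np.ndarray
    n_clusters: int
    design: Design
    ybar: np.ndarray
    residuals: np.ndarray
    components: VarianceComponents | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_treat(self) -> int:
        return self.design.n_treatment_columns(self.kind)

    @property
    def coef_treatment(self) -> np.ndarray:
        return self.coef[: self.n_treat]

    @property
    def coef_period(self) -> np.ndarray:
        return self.coef[self.n_treat:]

    def summary_dict(self) -> dict:
        label, est = aggregate_estimands(self)
        c = estimand_contrast(self.design, self.kind)
        out = {
            "kind": self.kind,
            "correlation": self.correlation,
            "gamma_used": self.gamma_used,
            "coefficients": dict(zip(self.coef_names, map(float, self.coef))),
            "estimand": label,
            "estimate": est,
            "model_se": float(np.sqrt(c @ self.vcov_model @ c)),
            "n_clusters": self.n_clusters,
        }
        if self.components is not None:
            out["variance_components"] = {
                "tau_alpha_sq": self.components.tau_alpha_sq,
                "tau_omega_sq": self.components.tau_omega_sq,
                "sigma_e_sq": self.components.sigma_e_sq,
            }
        return out


def fit_gls(
    data: pd.DataFrame | np.ndarray,
    design: Design,
    kind: Kind,
    gamma: float,
    *,
    workspace: GLSWorkspace | None = None,
    total_var: float | None = None,
) -> GLSFit:
    """GLS fit at a known working correlation ``gamma``.

    ``data`` may be a long DataFrame (individual rows or cell means) or the
    canonical cluster-period-mean vector itself.  ``total_var`` overrides the
    residual-based estimate of Var(Ybar) used in the model-based covariance.
    """
    ws = workspace or GLSWorkspace(design, kind)
    ybar = data if isinstance(data, np.ndarray) else cluster_period_means(data, design)
    if ybar.shape != (design.n_cells,):
        raise EstimationError(
            f"mean vector has shape {ybar.shape}, expected ({design.n_cells},)"
        )
    coef, M, rss = ws.solve(ybar, gamma)
    dof = ws.n - ws.p
    scale = total_var if total_var is not None else (rss / dof if dof > 0 else np.nan)
    return GLSFit(
        kind=kind,
        correlation="independence" if gamma == 0 else "nested_exchangeable",
        coef=coef,
        coef_names=ws.names,
        gamma_used=float(gamma),
        scale=float(scale),
        vcov_model=scale * M,
        n_clusters=design.I,
        design=design,
        ybar=ybar,
        residuals=ybar - ws.Z @ coef,
    )


def fit_fgls(
    data: pd.DataFrame,
    design: Design,
    kind: Kind,
    *,
    workspace: GLSWorkspace | None = None,
) -> GLSFit:
    """Feasible GLS: estimate variance components, then fit at the implied gamma.

    Requires individual-level data (K >= 2 per cell) so the residual variance is
    estimable from within-cell spread.  Components are floored at zero.
    """
    ws = workspace or GLSWorkspace(design, kind)
    ybar = cluster_period_means(data, design)
    sigma_e_sq = pooled_within_cell_variance(data, design)
    return fgls_from_means(ybar, sigma_e_sq, design, kind, workspace=ws)


def fgls_from_means(
    ybar: np.ndarray,
    sigma_e_sq: float,
    design: Design,
    kind: Kind,
    *,
    workspace: GLSWorkspace | None = None,
) -> GLSFit:
    """Feasible GLS from precomputed cell means and residual-variance estimate."""
    ws = workspace or GLSWorkspace(design, kind)
    g_hat, total_var = ws.reml_gamma(ybar)
    tau_alpha_sq = g_hat * total_var
    tau_omega_sq = total_var - tau_alpha_sq - sigma_e_sq / design.K
    if tau_omega_sq < 0:
        logger.info(
            "cluster-period interaction variance estimated negative (%.3g); floored at 0",
            tau_omega_sq,
        )
        tau_omega_sq = 0.0
    fit = fit_gls(ybar, design, kind, g_hat, workspace=ws, total_var=total_var)
    fit.correlation = "nested_exchangeable"
    fit.components = VarianceComponents(
        tau_alpha_sq=max(tau_alpha_sq, 0.0),
        tau_omega_sq=tau_omega_sq,
        sigma_e_sq=sigma_e_sq,
    )
    return fit


# ---------------------------------------------------------------------------
# estimands
# ---------------------------------------------------------------------------

def estimand_contrast(design: Design, kind: Kind) -> np.ndarray:
    """Contrast vector c with c'coef = the aggregated estimand for ``kind``.

    IT: the single treatment coefficient.  ETI: the unweighted mean of the
    exposure-time effects (the ETATE).  CTI: the unweighted mean of the
    identifiable calendar-time effects (the CTATE).
    """
    n_treat = design.n_treatment_columns(kind)
    c = np.zeros(n_treat + design.J)
    c[:n_treat] = 1.0 / n_treat
    return c


def aggregate_estimands(fit: GLSFit) -> tuple[str, float]:
    """(label, estimate): IT -> theta-hat, ETI -> ETATE-hat, CTI -> CTATE-hat."""
    c = estimand_contrast(fit.design, fit.kind)
    return ESTIMAND_LABEL[fit.kind], float(c @ fit.coef)


def estimand_truth(structure: TreatmentStructure, design: Design) -> float:
    """Discrete time-averaged estimand of a treatment-effect structure.

    IT returns theta; ETI the unweighted mean of delta over s = 1..J-1; CTI the
    unweighted mean of xi over the design's identifiable periods.
    """
    structure.validate_for(design)
    return float(np.mean(structure.effects))
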