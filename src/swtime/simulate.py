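"""Data generation and the replicate study of bias, precision, and coverage.

Outcomes follow the linear model
``Y_ijk = (treatment contribution) + phi_j + alpha_i + omega_ij + eps_ijk`` with
mutually independent normal cluster intercepts, cluster-period interactions, and
residuals.  The treatment contribution is ``theta`` once treated (IT truth),
``delta_s`` at exposure time s (ETI truth), or ``xi_j`` in calendar period j
(CTI truth, with the unidentifiable final-period effect fixed at zero).

Randomness uses one root seed with per-replicate child streams spawned through
``numpy.random.SeedSequence(seed, spawn_key=(rep,))`` so replicates are
order-independent and the whole study is bitwise reproducible.

The bundled reference study mirrors a realistic cross-sectional SW-CRT:
I = 18 clusters, J = 10 periods, K = 30 individuals per cell, variance
components (tau_alpha^2, tau_omega^2, sigma_e^2) = (0.1, 1/90, 1) so that
wpICC = 0.1, CAC = 0.9 and gamma ~= 0.69, a linear secular trend phi = (5..14),
and effect curves theta = 6, delta = (0, 0, 0.5, 1, 2, 4, 6, 6, 6)
(ETATE 2.83...), xi = (6, 3, 1, 0.5, 0.1, 0, 0, 0) (CTATE 1.325).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .correlation import VarianceComponents, gamma as _gamma
from .design import Design, Kind, TreatmentStructure, _treatment_matrix
from .gls import (
    ESTIMAND_LABEL,
    GLSWorkspace,
    aggregate_estimands,
    estimand_contrast,
    estimand_truth,
    fgls_from_means,
    fit_gls,
)
from .robust import ROBUST_TYPES, cluster_robust_variance, model_variance

logger = logging.getLogger(__name__)

CORRELATIONS = ("nested_exchangeable", "independence")


class StudyError(RuntimeError):
    """The replicate study failed (too many per-replicate estimation failures)."""


@dataclass(frozen=True)
class SimulationScenario:
    """One data-generating configuration of the replicate study."""

    design: Design
    structure: TreatmentStructure
    vc: VarianceComponents
    trend: np.ndarray
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        trend = np.asarray(self.trend, dtype=float)
        if trend.shape != (self.design.J,):
            raise ValueError(
                f"trend must have length J={self.design.J}, got {trend.shape}"
            )
        object.__setattr__(self, "trend", trend)
        self.structure.validate_for(self.design)
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")

    @property
    def gamma(self) -> float:
        return _gamma(self.vc, self.design.K)

    def expected_cell_means(self) -> np.ndarray:
        """E[Ybar_ij] in canonical order: treatment contribution plus trend."""
        X = _treatment_matrix(self.design, self.structure.kind)
        per = np.tile(np.arange(self.design.J), self.design.I)
        return X @ self.structure.effects + self.trend[per]

    def to_config(self) -> dict:
        return {
            "design": self.design.to_config(),
            "structure": {
                "kind": self.structure.kind,
                "effects": [float(v) for v in self.structure.effects],
            },
            "variance_components": {
                "tau_alpha_sq": self.vc.tau_alpha_sq,
                "tau_omega_sq": self.vc.tau_omega_sq,
                "sigma_e_sq": self.vc.sigma_e_sq,
            },
            "trend": [float(v) for v in self.trend],
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


def replicate_rng(seed: int, rep_index: int) -> np.random.Generator:
    """Independent child stream for one replicate of a study."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(rep_index,)))
    )


def _simulate_individuals(
    scenario: SimulationScenario, rng: np.random.Generator
) -> np.ndarray:
    """(I*J, K) array of individual outcomes, rows in canonical cell order."""
    d = scenario.design
    mu = scenario.expected_cell_means()
    alpha = rng.normal(0.0, np.sqrt(scenario.vc.tau_alpha_sq), size=d.I)
    omega = rng.normal(0.0, np.sqrt(scenario.vc.tau_omega_sq), size=d.n_cells)
    eps = rng.normal(0.0, np.sqrt(scenario.vc.sigma_e_sq), size=(d.n_cells, d.K))
    cell_level = mu + np.repeat(alpha, d.J) + omega
    return cell_level[:, None] + eps


def generate_trial(scenario: SimulationScenario, rep_index: int) -> pd.DataFrame:
    """One simulated trial in long form: (cluster, sequence, period, individual, y).

    Deterministic given ``(scenario.seed, rep_index)``.
    """
    d = scenario.design
    y = _simulate_individuals(scenario, replicate_rng(scenario.seed, rep_index))
    idx = d.cell_index.loc[d.cell_index.index.repeat(d.K)].reset_index(drop=True)
    idx["individual"] = np.tile(np.arange(1, d.K + 1), d.n_cells)
    idx["y"] = y.ravel()
    return idx


@dataclass(frozen=True)
class AnalysisSpec:
    """One analysis arm: fitted structure, working correlation, variance types.

    ``nested_exchangeable`` arms are fitted by feasible GLS (REML variance
    components); ``independence`` arms by OLS on the cluster-period means.
    """

    kind: Kind
    correlation: str = "nested_exchangeable"
    variance_estimators: tuple[str, ...] = ("model",)

    def __post_init__(self) -> None:
        if self.correlation not in CORRELATIONS:
            raise ValueError(
                f"correlation must be one of {CORRELATIONS}, got {self.correlation!r}"
            )
        bad = [v for v in self.variance_estimators if v != "model" and v not in ROBUST_TYPES]
        if bad:
            raise ValueError(f"unknown variance estimator types: {bad}")


@dataclass
class SimulationSummary:
    """Replicate-study metrics per (estimator, correlation, variance type)."""

    summary: pd.DataFrame
    estimates: dict  # (kind, correlation) -> np.ndarray of replicate estimates
    truth: float
    n_reps: int
    n_failures: int
    seed: int
    scenario: SimulationScenario = None

    def to_json_dict(self) -> dict:
        return {
            "truth": self.truth,
            "n_reps": self.n_reps,
            "n_failures": self.n_failures,
            "seed": self.seed,
            "rows": self.summary.to_dict(orient="records"),
        }


def run_study(
    scenario: SimulationScenario,
    analyses: list[AnalysisSpec],
    *,
    collect_replicates: bool = False,
) -> SimulationSummary:
    """Run the replicate study and summarize bias, precision, and coverage.

    For each replicate and analysis arm: fit the model, aggregate the estimand,
    and compute each requested variance with its 95% interval.  Summaries report
    percent relative bias ``100 (mean estimate - truth) / truth``, precision as
    the reciprocal of the average estimated variance, coverage of the true
    estimand, and the empirical variance of the estimates.  Per-replicate
    estimation failures are logged; more than 1% aborts the study.
    """
    d = scenario.design
    truth = estimand_truth(scenario.structure, d)
    if truth == 0:
        raise StudyError("percent relative bias undefined: true estimand is 0")
    workspaces = {a.kind: GLSWorkspace(d, a.kind) for a in analyses}
    contrasts = {a.kind: estimand_contrast(d, a.kind) for a in analyses}

    est: dict[tuple, list] = {(a.kind, a.correlation): [] for a in analyses}
    var: dict[tuple, list] = {}
    cover: dict[tuple, list] = {}
    for a in analyses:
        for v in a.variance_estimators:
            var[(a.kind, a.correlation, v)] = []
            cover[(a.kind, a.correlation, v)] = []
    failures = 0
    rep_rows = [] if collect_replicates else None

    for rep in range(scenario.n_reps):
        y = _simulate_individuals(scenario, replicate_rng(scenario.seed, rep))
        ybar = y.mean(axis=1)
        sigma_e_hat = float(y.var(axis=1, ddof=1).mean())
        for a in analyses:
            key = (a.kind, a.correlation)
            try:
                if a.correlation == "independence":
                    fit = fit_gls(ybar, d, a.kind, 0.0, workspace=workspaces[a.kind])
                else:
                    fit = fgls_from_means(
                        ybar, sigma_e_hat, d, a.kind, workspace=workspaces[a.kind]
                    )
                _, estimate = aggregate_estimands(fit)
                c = contrasts[a.kind]
                reports = {}
                for v in a.variance_estimators:
                    if v == "model":
                        reports[v] = model_variance(fit, c)
                    else:
                        reports[v] = cluster_robust_variance(fit, contrast=c, type=v)
            except Exception as exc:  # noqa: BLE001 - logged and thresholded
                failures += 1
                logger.warning("replicate %d, %s/%s failed: %s", rep, *key, exc)
                continue
            est[key].append(estimate)
            for v, rpt in reports.items():
                var[key + (v,)].append(rpt.variance)
                cover[key + (v,)].append(rpt.ci_low <= truth <= rpt.ci_high)
            if collect_replicates:
                row = {"rep": rep, "kind": a.kind, "correlation": a.correlation,
                       "estimate": estimate, "gamma_used": fit.gamma_used}
                for v, rpt in reports.items():
                    row[f"var_{v}"] = rpt.variance
                rep_rows.append(row)

    n_attempts = scenario.n_reps * len(analyses)
    if failures > 0.01 * n_attempts:
        raise StudyError(
            f"{failures} of {n_attempts} replicate analyses failed (> 1%)"
        )

    rows = []
    for a in analyses:
        key = (a.kind, a.correlation)
        e = np.asarray(est[key])
        for v in a.variance_estimators:
            vv = np.asarray(var[key + (v,)])
            cc = np.asarray(cover[key + (v,)])
            rows.append(
                {
                    "estimator": ESTIMAND_LABEL[a.kind],
                    "kind": a.kind,
                    "correlation": a.correlation,
                    "variance": v,
                    "mean_estimate": float(e.mean()),
                    "percent_bias": float(100.0 * (e.mean() - truth) / truth),
                    "precision": float(1.0 / vv.mean()),
                    "coverage": float(cc.mean()),
                    "empirical_variance": float(e.var(ddof=1)),
                    "n_reps": int(e.size),
                }
            )
    summary = pd.DataFrame(rows)
    out = SimulationSummary(
        summary=summary,
        estimates={k: np.asarray(v) for k, v in est.items()},
        truth=float(truth),
        n_reps=scenario.n_reps,
        n_failures=failures,
        seed=scenario.seed,
        scenario=scenario,
    )
    if collect_replicates:
        out.summary.attrs["replicates"] = pd.DataFrame(rep_rows)
    return out


# ---------------------------------------------------------------------------
# bundled reference study conditions
# ---------------------------------------------------------------------------

REFERENCE_VC = VarianceComponents(
    tau_alpha_sq=0.1, tau_omega_sq=float(Fraction(1, 90)), sigma_e_sq=1.0
)
REFERENCE_EFFECTS = {
    "IT": np.array([6.0]),
    "ETI": np.array([0.0, 0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 6.0, 6.0]),
    "CTI": np.array([6.0, 3.0, 1.0, 0.5, 0.1, 0.0, 0.0, 0.0]),
}


def reference_scenario(true_kind: Kind, n_reps: int = 200, seed: int = 0) -> SimulationScenario:
    """The package's reference study conditions for one true effect structure.

    I = 18, J = 10, K = 30; components (0.1, 1/90, 1); linear trend 5..14; effect
    curves as documented in the module docstring.
    """
    design = Design(I=18, J=10, K=30)
    return SimulationScenario(
        design=design,
        structure=TreatmentStructure(true_kind, REFERENCE_EFFECTS[true_kind]),
        vc=REFERENCE_VC,
        trend=np.arange(5.0, 15.0),
        n_reps=n_reps,
        seed=seed,
    )
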