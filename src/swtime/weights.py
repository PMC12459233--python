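"""Estimand weights of (possibly misspecified) SW-CRT treatment-effect estimators.

Every GLS estimator considered here is linear in the cluster-period means, so its
conditional expectation under any true treatment-effect structure is a weighted
sum of the true effect-curve values:

* fitted IT under a true exposure-time curve delta:  ``E[IT-hat] = sum_s w1(Q, gamma, s) delta_s``
* fitted IT under a true calendar-time curve xi:     ``E[IT-hat] = sum_j w2(Q, j) xi_j``
  (w2 does not depend on gamma and is never negative)
* fitted ETI (ETATE) under a true calendar curve:    weights w3(Q, gamma, j)
* fitted CTI (CTATE) under a true exposure curve:    weights w4(Q, gamma, s)

w1 and w2 have printed closed forms; w3 and w4 are computed numerically from the
fitted model's hat matrix, with printed closed forms available for two small
designs.  Each weight family sums to one (a constant true effect is recovered
exactly), but individual weights can be negative when ``gamma > 0``, which is how
a misspecified estimator can converge to a value of the opposite sign of the
true time-averaged effect.  At ``gamma = 0`` (independence working model) all
families are elementwise nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Design, Kind, TreatmentStructure, _check_kind, _treatment_matrix, period_matrix
from .gls import GLSWorkspace, estimand_contrast


class WeightError(ValueError):
    """Invalid arguments or internal consistency failure in the weight engine."""


# ---------------------------------------------------------------------------
# printed closed forms
# ---------------------------------------------------------------------------

def w1_closed_form(Q: int, gamma: float, s):
    """Weight of the true exposure-time effect delta_s in the fitted-IT expectation.

    ``w1(Q, gamma, s) = 6 (s - Q - 1) ((1 + 2 gamma Q) s - (1 + gamma + gamma Q) Q)
    / (Q (Q + 1) (gamma Q^2 + 2 Q - gamma Q - 2))``.  At gamma = 0 this reduces to
    ``6 (s - Q - 1)(s - Q) / (Q (Q + 1)(2 Q - 2))``, nonnegative for all s.
    """
    _check_Q(Q)
    _check_gamma(gamma)
    s = np.asarray(s, dtype=float)
    if np.any(s < 1) or np.any(s > Q):
        raise WeightError(f"exposure time s must lie in 1..{Q}")
    denom = Q * (Q + 1) * (gamma * Q**2 + 2 * Q - gamma * Q - 2)
    if denom == 0:
        raise WeightError(f"degenerate denominator at Q={Q}, gamma={gamma}")
    num = 6 * (s - Q - 1) * ((1 + 2 * gamma * Q) * s - (1 + gamma + gamma * Q) * Q)
    out = num / denom
    return float(out) if out.ndim == 0 else out


def w2_closed_form(Q: int, j):
    """Weight of the true calendar-time effect xi_j in the fitted-IT expectation.

    ``w2(Q, j) = 6 (j - 1)(Q + 1 - j) / (Q (Q + 1)(Q - 1))``, independent of
    gamma and nonnegative for all valid (Q, j).
    """
    _check_Q(Q)
    j = np.asarray(j, dtype=float)
    if np.any(j < 2) or np.any(j > Q):
        raise WeightError(f"calendar period j must lie in 2..{Q}")
    out = 6 * (j - 1) * (Q + 1 - j) / (Q * (Q + 1) * (Q - 1))
    return float(out) if out.ndim == 0 else out


def it_sequence_period_weights(Q: int, gamma: float) -> np.ndarray:
    """(Q, J) table of fitted-IT weights on the sequence-period means Ybar_qj.

    The IT estimator in a standard design (J = Q + 1) is the weighted sum
    ``IT-hat = C sum_{q,j} [Q 1(j > q) - j + 1 + gamma Q (2q - Q - 1) /
    (2 (1 + gamma Q))] Ybar_qj`` with
    ``C = 12 (1 + gamma Q) / (Q (Q + 1)(gamma Q^2 + 2 Q - gamma Q - 2))``.
    Row q, column j-1 holds the weight for sequence q in period j; each period's
    weights sum to zero, so period effects drop out.
    """
    _check_Q(Q)
    _check_gamma(gamma)
    J = Q + 1
    q = np.arange(1, Q + 1)[:, None]
    j = np.arange(1, J + 1)[None, :]
    C = 12 * (1 + gamma * Q) / (Q * (Q + 1) * (gamma * Q**2 + 2 * Q - gamma * Q - 2))
    cell = (
        Q * (j > q).astype(float)
        - j + 1
        + gamma * Q * (2 * q - Q - 1) / (2 * (1 + gamma * Q))
    )
    return C * cell


def w3_small_design_closed_form(gamma: float) -> tuple[float, float]:
    """ETATE-estimator weights (on xi_2, xi_3) in the 3-sequence, 4-period design.

    ``((-9 g^2 + 30 g + 12), (27 g^2 + 48 g + 14)) / (2 (9 g^2 + 39 g + 13))``;
    the two weights sum to one identically.
    """
    _check_gamma(gamma)
    g = gamma
    denom = 2 * (9 * g**2 + 39 * g + 13)
    return ((-9 * g**2 + 30 * g + 12) / denom, (27 * g**2 + 48 * g + 14) / denom)


def w4_small_design_closed_form(gamma: float) -> tuple[float, float]:
    """CTATE-estimator weights (on delta_1, delta_2) in the 3-sequence, 3-period
    truncated design (a 3-sequence, 4-period trial with its final period removed).

    ``((9 g^2 + 15 g + 6), (-3 g^2 + g + 2)) / (2 (3 g^2 + 8 g + 4))``; the two
    weights sum to one identically.
    """
    _check_gamma(gamma)
    g = gamma
    denom = 2 * (3 * g**2 + 8 * g + 4)
    return ((9 * g**2 + 15 * g + 6) / denom, (-3 * g**2 + g + 2) / denom)


# ---------------------------------------------------------------------------
# numerical engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimandWeights:
    """Weights mapping true effect-curve values to a fitted estimator's expectation.

    ``index`` holds the true structure's effect indices (exposure times 1..J-1
    for ETI truth; identifiable calendar periods for CTI truth) and ``weights``
    the matching coefficients.  ``lambda_cells`` is the underlying per-(cluster,
    period) weight table applied to the cluster-period means.
    """

    fitted_kind: Kind
    true_kind: Kind
    Q: int
    gamma: float
    index: np.ndarray
    weights: np.ndarray
    lambda_cells: np.ndarray  # (I, J)
    design: Design

    @property
    def lambda_sequence_cells(self) -> np.ndarray:
        """(Q, J) table: lambda summed over the identical clusters per sequence."""
        per_seq = self.lambda_cells.reshape(
            self.Q, self.design.clusters_per_sequence, self.design.J
        )
        return per_seq.sum(axis=1)


def numerical_weights(
    design: Design,
    gamma: float,
    fitted_kind: Kind,
    true_kind: Kind,
    *,
    workspace: GLSWorkspace | None = None,
) -> EstimandWeights:
    """Estimand weights of a fitted model's aggregated estimator via its hat matrix.

    Builds the linear row ``c' (Z'V^-1 Z)^-1 Z'V^-1`` of the fitted model's
    aggregated estimand, verifies that period effects carry zero weight (two
    arbitrary trend vectors must leave the weights unchanged), and projects the
    row onto the indicator columns of the true structure.
    """
    _check_kind(fitted_kind)
    _check_kind(true_kind)
    if true_kind not in ("ETI", "CTI"):
        raise WeightError("true_kind must be ETI or CTI (an effect curve)")
    _check_gamma(gamma)
    ws = workspace or GLSWorkspace(design, fitted_kind)
    row = estimand_contrast(design, fitted_kind) @ ws.hat_matrix(gamma)
    # period-effect invariance: the row must annihilate any calendar trend
    P = period_matrix(design)
    for phi in (np.zeros(design.J), np.arange(1.0, design.J + 1)):
        drift = float(row @ (P @ phi))
        if abs(drift) > 1e-9 * max(1.0, float(np.abs(row).sum())):
            raise WeightError(
                f"period-effect invariance violated (drift {drift:.3e}) for "
                f"fitted={fitted_kind}; the weight row is not trend-free"
            )
    X_true = _treatment_matrix(design, true_kind)
    w = row @ X_true
    total = float(w.sum())
    if abs(total - 1.0) > 1e-6:
        raise WeightError(
            f"weights sum to {total:.8f}, not 1: constant-effect recovery failed "
            f"for fitted={fitted_kind}, true={true_kind}"
        )
    index = design.eti_exposures if true_kind == "ETI" else design.cti_periods
    return EstimandWeights(
        fitted_kind=fitted_kind,
        true_kind=true_kind,
        Q=design.Q,
        gamma=float(gamma),
        index=index.copy(),
        weights=w,
        lambda_cells=row.reshape(design.I, design.J),
        design=design,
    )


def expected_estimate(weights: EstimandWeights, structure: TreatmentStructure) -> float:
    """Conditional expectation of the fitted estimator under a true effect curve."""
    if structure.kind != weights.true_kind:
        raise WeightError(
            f"structure kind {structure.kind} does not match weights' true kind "
            f"{weights.true_kind}"
        )
    if structure.effects.size != weights.weights.size:
        raise WeightError(
            f"effect vector length {structure.effects.size} does not match "
            f"{weights.weights.size} weights"
        )
    return float(weights.weights @ structure.effects)


def weight_table(
    design: Design, gammas, fitted_kind: Kind, true_kind: Kind
) -> "pd.DataFrame":
    """Long weight table over a gamma grid (one row per gamma x effect index)."""
    import pandas as pd

    ws = GLSWorkspace(design, fitted_kind)
    rows = []
    for g in np.atleast_1d(np.asarray(gammas, dtype=float)):
        ew = numerical_weights(design, float(g), fitted_kind, true_kind, workspace=ws)
        for idx, w in zip(ew.index, ew.weights):
            rows.append(
                {
                    "fitted_kind": fitted_kind,
                    "true_kind": true_kind,
                    "Q": design.Q,
                    "gamma": float(g),
                    "index": int(idx),
                    "weight": float(w),
                }
            )
    return pd.DataFrame(rows)


def _check_Q(Q: int) -> None:
    if Q < 2:
        raise WeightError(f"need at least 2 sequences, got Q={Q}")


def _check_gamma(gamma: float) -> None:
    if not (0.0 <= gamma < 1.0):
        raise WeightError(f"gamma must lie in [0, 1), got {gamma}")
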