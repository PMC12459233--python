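"""Complete balanced stepped-wedge layouts and treatment-effect parameterizations.

A standard complete stepped-wedge cluster randomized trial (SW-CRT) has ``Q = J - 1``
sequences over ``J`` periods; the clusters randomized to sequence ``q`` cross from
control to treatment at the start of period ``j = q + 1``, so every cluster is
untreated in period 1 and treated in period ``J``.  Three fixed-effect treatment
structures are supported:

``IT``
    immediate treatment: a single sustained effect ``theta`` once treated.
``ETI``
    exposure time indicators: one effect ``delta_s`` per exposure time
    ``s = 1..J-1`` (periods elapsed since crossover; ``s = 0`` is control).
``CTI``
    calendar time indicators: one effect ``xi_j`` per calendar period in which both
    treated and untreated clusters are observed.  In the standard design that is
    ``j = 2..J-1``; the final-period effect ``xi_J`` is collinear with the period
    effect ``phi_J`` (all clusters are treated in period ``J``) and is fixed to zero
    by dropping its column at construction time.

All matrices are laid out cluster-major, period-minor: row ``(i - 1) * J + (j - 1)``
holds cluster ``i``, period ``j``.  Clusters are 1-based and sorted by sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Kind = Literal["IT", "ETI", "CTI"]

KINDS: tuple[str, ...] = ("IT", "ETI", "CTI")


class DesignError(ValueError):
    """Invalid or unsupported trial layout."""


@dataclass(frozen=True)
class Design:
    """A complete, balanced SW-CRT layout.

    Parameters
    ----------
    I : int
        Number of clusters; must be an exact multiple of ``Q``.
    J : int
        Number of calendar periods.
    K : int
        Individuals per cluster-period cell (constant).
    Q : int, optional
        Number of sequences.  Defaults to ``J - 1`` (standard complete design).
    truncated : bool
        Admits the one non-standard layout needed for calendar-effect diagnostics:
        a standard ``Q``-sequence design observed only through period ``J = Q``
        (its original final period removed), so the last sequence is never treated
        inside the observation window.  Requires ``Q == J``.
    """

    I: int
    J: int
    K: int
    Q: int = -1  # sentinel: fill with J - 1
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.Q == -1:
            object.__setattr__(self, "Q", self.J - 1)
        if self.J < 2:
            raise DesignError(f"need at least 2 periods, got J={self.J}")
        if self.K < 1:
            raise DesignError(f"cell size must be >= 1, got K={self.K}")
        if self.truncated:
            if self.Q != self.J:
                raise DesignError(
                    f"truncated layout requires Q == J, got Q={self.Q}, J={self.J}"
                )
        elif self.Q != self.J - 1:
            raise DesignError(
                "only standard complete designs (Q = J - 1) are supported; "
                f"got Q={self.Q}, J={self.J}. For the final-period-removed layout "
                "pass truncated=True with Q == J."
            )
        if self.I % self.Q != 0 or self.I < self.Q:
            raise DesignError(
                f"cluster count I={self.I} must be a positive multiple of Q={self.Q}"
            )

    # -- bookkeeping ---------------------------------------------------------

    @property
    def clusters_per_sequence(self) -> int:
        return self.I // self.Q

    @property
    def n_cells(self) -> int:
        return self.I * self.J

    @property
    def seq_of_cluster(self) -> np.ndarray:
        """1-based sequence of each cluster, clusters sorted by sequence."""
        return 1 + (np.arange(self.I) // self.clusters_per_sequence)

    def sequence_of(self, i: int) -> int:
        if not 1 <= i <= self.I:
            raise DesignError(f"cluster index {i} out of range 1..{self.I}")
        return int(self.seq_of_cluster[i - 1])

    @property
    def cell_index(self) -> "pd.DataFrame":
        """Long (cluster, sequence, period) frame in canonical row order."""
        import pandas as pd

        cluster = np.repeat(np.arange(1, self.I + 1), self.J)
        period = np.tile(np.arange(1, self.J + 1), self.I)
        sequence = np.repeat(self.seq_of_cluster, self.J)
        return pd.DataFrame(
            {"cluster": cluster, "sequence": sequence, "period": period}
        )

    @property
    def eti_exposures(self) -> np.ndarray:
        """Exposure times with a dedicated indicator column (1..J-1)."""
        return np.arange(1, self.J)

    @property
    def cti_periods(self) -> np.ndarray:
        """Calendar periods with an identifiable treatment indicator.

        A period gets a ``xi_j`` column iff it contains both treated and untreated
        cells: ``j = 2..J-1`` in the standard design, ``j = 2..J`` in the truncated
        layout (the last sequence stays untreated, keeping a within-period control).
        """
        treated_counts = np.array(
            [np.sum(j > np.arange(1, self.Q + 1)) for j in range(1, self.J + 1)]
        )
        mask = (treated_counts > 0) & (treated_counts < self.Q)
        return np.arange(1, self.J + 1)[mask]

    def n_treatment_columns(self, kind: Kind) -> int:
        _check_kind(kind)
        if kind == "IT":
            return 1
        if kind == "ETI":
            return len(self.eti_exposures)
        return len(self.cti_periods)

    def to_config(self) -> dict:
        return {"I": self.I, "J": self.J, "Q": self.Q, "K": self.K,
                "allocation": "equal", "truncated": self.truncated}

    @classmethod
    def from_config(cls, cfg: dict) -> "Design":
        known = {"I", "J", "Q", "K", "allocation", "truncated"}
        extra = set(cfg) - known
        if extra:
            raise DesignError(f"unknown design config keys: {sorted(extra)}")
        if cfg.get("allocation", "equal") != "equal":
            raise DesignError("only equal allocation of clusters is supported")
        return cls(I=int(cfg["I"]), J=int(cfg["J"]), K=int(cfg["K"]),
                   Q=int(cfg.get("Q", cfg["J"] - 1 + int(bool(cfg.get("truncated"))))),
                   truncated=bool(cfg.get("truncated", False)))


@dataclass(frozen=True)
class TreatmentStructure:
    """A treatment-effect structure and its effect values.

    ``effects`` is a scalar ``theta`` for kind IT, the vector
    ``delta = (delta_1, .., delta_{J-1})`` indexed by exposure time for ETI, or the
    vector ``xi`` indexed by the design's identifiable calendar periods for CTI
    (``xi_2 .. xi_{J-1}`` in a standard design; ``xi_J`` is fixed to zero).
    """

    kind: Kind
    effects: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        _check_kind(self.kind)
        eff = np.atleast_1d(np.asarray(self.effects, dtype=float))
        if not np.all(np.isfinite(eff)):
            raise DesignError("treatment effects must be finite reals")
        if self.kind == "IT" and eff.size != 1:
            raise DesignError("IT structure takes a single scalar effect")
        object.__setattr__(self, "effects", eff)

    @property
    def theta(self) -> float:
        if self.kind != "IT":
            raise DesignError("theta is only defined for the IT structure")
        return float(self.effects[0])

    def validate_for(self, design: Design) -> None:
        n = design.n_treatment_columns(self.kind)
        if self.effects.size != n:
            raise DesignError(
                f"{self.kind} effect vector has length {self.effects.size}, "
                f"expected {n} for this design"
            )


def _check_kind(kind: str) -> None:
    if kind not in KINDS:
        raise DesignError(f"unknown treatment structure kind {kind!r}; expected one of {KINDS}")


def exposure_time(design: Design, i: int, j: int) -> int:
    """Exposure time ``s = max(j - q_i, 0)`` of cluster ``i`` in period ``j``."""
    if not 1 <= j <= design.J:
        raise DesignError(f"period index {j} out of range 1..{design.J}")
    return max(j - design.sequence_of(i), 0)


def treatment_indicators(design: Design, kind: Kind) -> "pd.DataFrame":
    """Indicator table, one row per (cluster, period) in canonical order.

    Columns beyond (cluster, sequence, period): ``treat`` for IT; ``expo_s`` for
    each exposure time s for ETI; ``cal_j`` for each identifiable period j for CTI.
    """
    _check_kind(kind)
    idx = design.cell_index
    X = _treatment_matrix(design, kind)
    for name, col in zip(treatment_column_names(design, kind), X.T):
        idx[name] = col.astype(int)
    return idx


def treatment_column_names(design: Design, kind: Kind) -> list[str]:
    _check_kind(kind)
    if kind == "IT":
        return ["treat"]
    if kind == "ETI":
        return [f"expo_{s}" for s in design.eti_exposures]
    return [f"cal_{j}" for j in design.cti_periods]


def _treatment_matrix(design: Design, kind: Kind, *, drop_unidentifiable: bool = True) -> np.ndarray:
    seq = np.repeat(design.seq_of_cluster, design.J)
    per = np.tile(np.arange(1, design.J + 1), design.I)
    s = np.maximum(per - seq, 0)
    if kind == "IT":
        return (s > 0).astype(float)[:, None]
    if kind == "ETI":
        return (s[:, None] == design.eti_exposures[None, :]).astype(float)
    periods = design.cti_periods
    if not drop_unidentifiable:
        treated_any = np.array(
            [np.any(j > np.arange(1, design.Q + 1)) for j in range(1, design.J + 1)]
        )
        periods = np.arange(1, design.J + 1)[treated_any]
    return ((s[:, None] > 0) & (per[:, None] == periods[None, :])).astype(float)


def period_matrix(design: Design) -> np.ndarray:
    """Exact one-hot encoding of calendar period (spans the intercept)."""
    per = np.tile(np.arange(1, design.J + 1), design.I)
    return (per[:, None] == np.arange(1, design.J + 1)[None, :]).astype(float)


def design_matrix(
    design: Design, kind: Kind, *, drop_unidentifiable: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Full fixed-effects matrix: treatment columns, then J period indicators.

    With ``drop_unidentifiable=False`` the CTI block keeps a column for every
    period containing any treated cell (including the all-treated final period),
    which is rank-deficient in the standard design and raises ``DesignError``
    naming the offending columns.
    """
    X = _treatment_matrix(design, kind, drop_unidentifiable=drop_unidentifiable)
    P = period_matrix(design)
    Z = np.hstack([X, P])
    if kind == "CTI" and not drop_unidentifiable:
        names = [f"cal_{j}" for j in np.arange(2, design.J + 1)
                 if np.any(j > np.arange(1, design.Q + 1))]
    else:
        names = treatment_column_names(design, kind)
    names = names + [f"period_{j}" for j in range(1, design.J + 1)]
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify offending columns: those whose removal restores full rank
        bad = [
            names[c]
            for c in range(Z.shape[1])
            if np.linalg.matrix_rank(np.delete(Z, c, axis=1)) == rank
        ]
        raise DesignError(
            f"design matrix for kind={kind} is rank deficient "
            f"(rank {rank} < {Z.shape[1]} columns); collinear columns: {bad}"
        )
    return Z, names
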