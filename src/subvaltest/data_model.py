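"""Domain containers and validation of raw trial tables.

The package works on two observational units: ``{X, A, Y}`` for an uncensored
continuous outcome and ``{X, A, U, Delta}`` for a right-censored time-to-event,
where ``A`` is a binary treatment indicator (1 = active treatment) and larger
outcomes are preferred.  For survival data the outcome scale is the restricted
mean survival time (RMST) up to a truncation time ``L``, and the containers
carry the derived quantities ``UL = min(U, L)`` and
``DeltaL = Delta + (1 - Delta) * 1(U >= L)`` — a subject censored after ``L``
is fully observed on the RMST scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "ConfigError",
    "UncensoredTrialData",
    "SurvivalTrialData",
    "Partition",
    "ChunkResult",
    "TestResult",
    "validate_uncensored",
    "validate_survival",
]


class DataError(ValueError):
    """Raised when input data violate the contract of the test."""


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent."""


def _check_binary(name: str, v: np.ndarray) -> np.ndarray:
    vals = np.unique(v)
    if not np.all(np.isin(vals, [0, 1])):
        raise DataError(f"{name} must be coded 0/1, found values {vals!r}")
    return v.astype(np.int64)


def _check_pi(known_pi) -> float | None:
    if known_pi is None:
        return None
    known_pi = float(known_pi)
    if not 0.0 < known_pi < 1.0:
        raise ConfigError(f"known_pi must lie in (0, 1), got {known_pi}")
    return known_pi


@dataclass
class UncensoredTrialData:
    """iid copies of ``O = {X, A, Y}`` with an optional known randomization
    probability ``pi = pr(A = 1)``."""

    X: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    known_pi: float | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.A = _check_binary("A", np.asarray(self.A))
        self.Y = np.asarray(self.Y, dtype=float)
        self.known_pi = _check_pi(self.known_pi)
        n = self.X.shape[0]
        if self.A.shape != (n,) or self.Y.shape != (n,):
            raise DataError("X, A, Y must share the same number of rows")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise DataError("X and Y must be finite with no missing values")
        if len(np.unique(self.A)) < 2:
            raise DataError("degenerate treatment assignment: only one arm present")
        if self.covariate_names is None:
            self.covariate_names = [f"X{k + 1}" for k in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "UncensoredTrialData":
        return UncensoredTrialData(
            self.X[idx], self.A[idx], self.Y[idx],
            known_pi=self.known_pi, covariate_names=self.covariate_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.covariate_names)
        df.insert(0, "A", self.A)
        df.insert(1, "Y", self.Y)
        return df


@dataclass
class SurvivalTrialData:
    """iid copies of ``O = {X, A, U, Delta}`` with truncation time ``L``.

    ``Delta = 1`` marks an observed event, ``Delta = 0`` censoring.  The
    derived ``UL``/``DeltaL`` arrays are attached on construction.
    """

    X: np.ndarray
    A: np.ndarray
    U: np.ndarray
    Delta: np.ndarray
    L: float
    known_pi: float | None = None
    covariate_names: list[str] | None = None
    UL: np.ndarray = field(init=False)
    DeltaL: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.A = _check_binary("A", np.asarray(self.A))
        self.U = np.asarray(self.U, dtype=float)
        self.Delta = _check_binary("Delta", np.asarray(self.Delta))
        self.known_pi = _check_pi(self.known_pi)
        self.L = float(self.L)
        n = self.X.shape[0]
        if self.A.shape != (n,) or self.U.shape != (n,) or self.Delta.shape != (n,):
            raise DataError("X, A, U, Delta must share the same number of rows")
        if not (np.isfinite(self.X).all() and np.isfinite(self.U).all()):
            raise DataError("X and U must be finite with no missing values")
        if (self.U < 0).any():
            raise DataError("observed times U must be nonnegative")
        if self.L <= 0:
            raise ConfigError("truncation time L must be positive")
        if not (self.U >= self.L).any():
            raise DataError(
                "L violates positivity: no subject has U >= L "
                f"(L={self.L}, max U={self.U.max():g})"
            )
        if len(np.unique(self.A)) < 2:
            raise DataError("degenerate treatment assignment: only one arm present")
        self.UL = np.minimum(self.U, self.L)
        self.DeltaL = self.Delta | (self.U >= self.L).astype(np.int64)
        if self.covariate_names is None:
            self.covariate_names = [f"X{k + 1}" for k in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "SurvivalTrialData":
        return SurvivalTrialData(
            self.X[idx], self.A[idx], self.U[idx], self.Delta[idx], self.L,
            known_pi=self.known_pi, covariate_names=self.covariate_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.covariate_names)
        df.insert(0, "A", self.A)
        df.insert(1, "U", self.U)
        df.insert(2, "Delta", self.Delta)
        return df


@dataclass
class Partition:
    """Ordered chunking of subject indices: the initial fitting chunk ``C0``
    (size ``ln`` plus any remainder) followed by ``rn`` analysis chunks of
    exactly ``m`` subjects each."""

    initial: np.ndarray
    chunks: list[np.ndarray]

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=np.int64)
        self.chunks = [np.asarray(c, dtype=np.int64) for c in self.chunks]
        sizes = {len(c) for c in self.chunks}
        if len(sizes) > 1:
            raise ConfigError(f"analysis chunks must share one size m, got {sizes}")
        all_idx = np.concatenate([self.initial, *self.chunks]) if self.chunks else self.initial
        if len(np.unique(all_idx)) != len(all_idx):
            raise ConfigError("partition chunks must be pairwise disjoint")

    @property
    def rn(self) -> int:
        return len(self.chunks)

    @property
    def m(self) -> int:
        return len(self.chunks[0]) if self.chunks else 0

    @property
    def n(self) -> int:
        return len(self.initial) + sum(len(c) for c in self.chunks)


@dataclass
class ChunkResult:
    """Per-chunk value-difference estimate and its history-conditional SD."""

    j: int
    psi_hat: float
    sigma_hat: float
    n_hist: int

    def to_dict(self) -> dict:
        return {"j": self.j, "psi_hat": self.psi_hat,
                "sigma_hat": self.sigma_hat, "n_hist": self.n_hist}


@dataclass
class TestResult:
    """Outcome of the one-step value-difference test.

    ``T`` is asymptotically standard normal under the null of no benefiting
    subgroup, including at the exceptional law; the test is one-sided with
    ``p = 1 - Phi(T)`` and rejects when ``T > z_{1-alpha}``.
    ``psi_pooled`` is the sigma^{-1}-weighted average of the per-chunk value
    differences, an estimate of Psi(d_opt) = V(d_opt) - V(0).
    """

    T: float
    p_value: float
    psi_pooled: float
    chunk_trace: list[ChunkResult]
    alpha: float
    rejected: bool
    estimator: str = ""
    chunking: str = ""
    n_truncated_kc: int = 0
    warnings: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "T": self.T,
            "p_value": self.p_value,
            "psi_pooled": self.psi_pooled,
            "alpha": self.alpha,
            "rejected": bool(self.rejected),
            "estimator": self.estimator,
            "chunking": self.chunking,
            "n_truncated_kc": self.n_truncated_kc,
            "warnings": list(self.warnings),
            "chunk_trace": [c.to_dict() for c in self.chunk_trace],
            "config": self.config,
        }


def _extract(
    table: pd.DataFrame,
    treatment_col: str,
    value_cols: list[str],
    covariate_cols: list[str] | None,
):
    """Drop rows with any missing value among the used columns; return the
    retained frame, covariate column list and exclusion count."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    for col in [treatment_col, *value_cols]:
        if col not in table.columns:
            raise DataError(f"required column {col!r} missing from input table")
    if covariate_cols is None:
        covariate_cols = [c for c in table.columns
                          if c not in {treatment_col, *value_cols}]
    if not covariate_cols:
        raise DataError("at least one covariate column is required")
    used = table[[treatment_col, *value_cols, *covariate_cols]]
    keep = used.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("excluded %d row(s) with missing values", n_dropped)
    return used.loc[keep], covariate_cols, n_dropped


def validate_uncensored(
    table: pd.DataFrame,
    treatment_col: str = "A",
    outcome_col: str = "Y",
    covariate_cols: list[str] | None = None,
    known_pi: float | None = None,
) -> UncensoredTrialData:
    """Validate a raw table into an :class:`UncensoredTrialData` container.

    Rows with any missing value among the used columns are excluded (and
    counted in the log); a non-binary treatment column or single-arm data
    raise :class:`DataError`.
    """
    kept, cov_cols, _ = _extract(table, treatment_col, [outcome_col], covariate_cols)
    return UncensoredTrialData(
        X=kept[cov_cols].to_numpy(dtype=float),
        A=kept[treatment_col].to_numpy(),
        Y=kept[outcome_col].to_numpy(dtype=float),
        known_pi=known_pi,
        covariate_names=list(cov_cols),
    )


def validate_survival(
    table: pd.DataFrame,
    L: float,
    treatment_col: str = "A",
    time_col: str = "U",
    status_col: str = "Delta",
    covariate_cols: list[str] | None = None,
    known_pi: float | None = None,
) -> SurvivalTrialData:
    """Validate a raw table into a :class:`SurvivalTrialData` container.

    Status convention: 1 = event, 0 = censored.  The derived ``UL`` and
    ``DeltaL`` arrays are attached by the container.
    """
    kept, cov_cols, _ = _extract(table, treatment_col, [time_col, status_col],
                                 covariate_cols)
    return SurvivalTrialData(
        X=kept[cov_cols].to_numpy(dtype=float),
        A=kept[treatment_col].to_numpy(),
        U=kept[time_col].to_numpy(dtype=float),
        Delta=kept[status_col].to_numpy(),
        L=L,
        known_pi=known_pi,
        covariate_names=list(cov_cols),
    )
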