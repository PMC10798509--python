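"""Performance-weighted least squares (PWLS) polynomial regression.

PWLS fits, for each control parameter y_i, a degree-m polynomial P_i(v) of
walking velocity by minimizing the performance-weighted squared error

    E_PWLS = || beta (.) (y - V w) ||^2

where V is the n x (m+1) Vandermonde matrix of velocities, (.) the Hadamard
product, and beta_j a per-record weight derived from the record's cost of
transport relative to the local (moving-average) CoT:

    beta_j = A ** ((CoTbar_j - CoT_j) / CoTbar_j)

with CoTbar_j the mean CoT over the 2M+1 velocity-sorted neighbours of
record j.  A >= 1 sets the strength of the bias toward energy-efficient
records; A = 1 recovers ordinary least squares.  Large A drives the fitted
polynomial through the most efficient records at each velocity, which is how
the modulator "inherits" efficiency from the dataset.

The explicit normal-equations solution

    w = ((B(.)V)^T (B(.)V))^-1 (B(.)V)^T (beta(.)y)

is mathematically exact but ill-conditioned for m = 6 on raw velocities;
this module solves the identical problem by a QR/least-squares factorization
of diag(beta) V on a centred and scaled velocity basis, then transforms the
coefficients back to the raw power basis.  Weights are computed in log space
and renormalized by their maximum (allowed by scale invariance of the
minimizer) so extreme A never overflows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .modulator import Modulator, PolynomialModel
from .registry import N_PARAMS, PARAM_NAMES, ParameterVector

__all__ = [
    "GaitRecord",
    "GaitDataset",
    "WeightConfig",
    "SingularFitError",
    "moving_average_cot",
    "performance_weights",
    "compute_weights",
    "fit_pwls",
    "fit_modulator",
]


class SingularFitError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient for the requested degree."""


@dataclass(frozen=True)
class GaitRecord:
    """(v_x, Y, CoT): one admitted walking trial."""

    v_x: float
    Y: ParameterVector
    cot: float

    def __post_init__(self) -> None:
        if self.v_x <= 0:
            raise ValueError(f"v_x must be positive, got {self.v_x}")
        if self.cot <= 0:
            raise ValueError(f"cot must be positive, got {self.cot}")


@dataclass
class GaitDataset:
    """Velocity-sorted collection of gait records.

    Stored columnar: velocities ``v_x`` (n,), costs ``cot`` (n,) and the
    parameter matrix ``Y`` (n, 56) in registry order.  Construction sorts
    ascending by velocity with a stable sort (ties keep insertion order).
    """

    v_x: np.ndarray
    cot: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.v_x = np.asarray(self.v_x, dtype=float)
        self.cot = np.asarray(self.cot, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = len(self.v_x)
        if self.cot.shape != (n,) or self.Y.shape != (n, N_PARAMS):
            raise ValueError("inconsistent dataset shapes")
        order = np.argsort(self.v_x, kind="stable")
        self.v_x = self.v_x[order]
        self.cot = self.cot[order]
        self.Y = self.Y[order]

    @classmethod
    def from_records(cls, records: Sequence[GaitRecord]) -> "GaitDataset":
        if not records:
            raise ValueError("dataset must contain at least one record")
        return cls(
            v_x=np.array([r.v_x for r in records]),
            cot=np.array([r.cot for r in records]),
            Y=np.vstack([r.Y.values for r in records]),
        )

    def __len__(self) -> int:
        return len(self.v_x)

    def __getitem__(self, j: int) -> GaitRecord:
        return GaitRecord(
            v_x=float(self.v_x[j]),
            Y=ParameterVector(self.Y[j].copy()),
            cot=float(self.cot[j]),
        )

    def parameter_series(self, name: str) -> np.ndarray:
        from .registry import index_of

        return self.Y[:, index_of(name)]

    # -- CSV round-trip ----------------------------------------------------
    def to_csv(self, path: str | Path | io.IOBase) -> None:
        df = pd.DataFrame(self.Y, columns=list(PARAM_NAMES))
        df.insert(0, "cot", self.cot)
        df.insert(0, "v_x", self.v_x)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.IOBase) -> "GaitDataset":
        df = pd.read_csv(path)
        expected = ["v_x", "cot", *PARAM_NAMES]
        if list(df.columns) != expected:
            raise ValueError("dataset CSV header does not match registry order")
        return cls(
            v_x=df["v_x"].to_numpy(),
            cot=df["cot"].to_numpy(),
            Y=df[list(PARAM_NAMES)].to_numpy(),
        )


@dataclass(frozen=True)
class WeightConfig:
    """Performance-weight settings: bias strength A and half-window M."""

    A: float = 1e6
    M_window: int = 125

    def __post_init__(self) -> None:
        if self.A < 1:
            raise ValueError(f"A must be >= 1, got {self.A}")
        if self.M_window < 0:
            raise ValueError(f"M_window must be >= 0, got {self.M_window}")


def moving_average_cot(dataset: GaitDataset, j: int, M_window: int) -> float:
    """Mean CoT over the velocity-sorted window [j-M, j+M].

    The window is clipped to the dataset boundaries (it shrinks at the
    edges); at full width it covers 2M+1 records.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("dataset is empty")
    if not 0 <= j < n:
        raise IndexError(f"index {j} out of range for dataset of {n}")
    lo = max(0, j - M_window)
    hi = min(n - 1, j + M_window)
    return float(dataset.cot[lo : hi + 1].mean())


def performance_weights(cot, cot_bar, A: float):
    """beta = A ** ((CoTbar - CoT) / CoTbar); > 1 iff better than local mean."""
    cot_bar = np.asarray(cot_bar, dtype=float)
    if np.any(cot_bar <= 0):
        raise ValueError("cot_bar must be positive")
    if A < 1:
        raise ValueError(f"A must be >= 1, got {A}")
    exponent = (cot_bar - np.asarray(cot, dtype=float)) / cot_bar
    return A**exponent


def compute_weights(dataset: GaitDataset, config: WeightConfig) -> np.ndarray:
    """Per-record weights beta, computed in log space and max-normalized.

    Normalizing by max(beta) leaves the PWLS minimizer unchanged (uniform
    rescaling invariance) while keeping diag(beta) V representable for
    arbitrarily large A.
    """
    n = len(dataset)
    cot_bar = np.array(
        [moving_average_cot(dataset, j, config.M_window) for j in range(n)]
    )
    log_beta = ((cot_bar - dataset.cot) / cot_bar) * np.log(config.A)
    return np.exp(log_beta - log_beta.max())


def _power_matrix(v: np.ndarray, m: int) -> np.ndarray:
    return np.vander(v, m + 1, increasing=True)


def fit_pwls(
    v: np.ndarray, y: np.ndarray, beta: np.ndarray, m: int
) -> PolynomialModel:
    """Minimize ||beta (.) (y - V w)||^2 over degree-m coefficients w.

    Internally fits on a centred/scaled velocity basis via a stable
    orthogonal factorization (numpy lstsq on diag(beta) V), then converts the
    coefficients back to raw powers of velocity, so the returned model
    follows the raw-basis convention P(v) = w0 + w1 v + ... + wm v^m.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = len(v)
    if not (len(y) == len(beta) == n):
        raise ValueError("v, y, beta must share length")
    if np.any(beta <= 0):
        raise ValueError("all weights must be positive")
    if n < m + 1:
        raise SingularFitError(
            f"need at least {m + 1} records for degree {m}, got {n}"
        )
    if len(np.unique(v)) < m + 1:
        raise SingularFitError(
            f"need at least {m + 1} distinct velocities for degree {m}, "
            f"got {len(np.unique(v))}"
        )
    beta = beta / beta.max()  # scale invariance; guards extreme magnitudes
    center = v.mean()
    scale = max(v.std(), np.finfo(float).eps)
    vs = (v - center) / scale
    design = beta[:, None] * _power_matrix(vs, m)
    coef_scaled, _, rank, _ = np.linalg.lstsq(design, beta * y, rcond=None)
    if rank < m + 1:
        raise SingularFitError("design matrix is rank deficient")
    # compose with the affine map v -> (v - center)/scale to recover raw basis
    raw = Polynomial(coef_scaled)(Polynomial([-center / scale, 1.0 / scale]))
    omega = np.zeros(m + 1)
    omega[: len(raw.coef)] = raw.coef
    return PolynomialModel(degree=m, omega=omega)


def fit_modulator(
    dataset: GaitDataset, m: int = 6, config: WeightConfig = WeightConfig()
) -> Modulator:
    """Fit all 56 parameter polynomials sharing one performance-weight vector.

    Degree 6 is the default: the smallest degree found to express the
    velocity dependence of the reflex parameters without overfitting.
    """
    n = len(dataset)
    if n <= m:
        raise SingularFitError(f"need more than {m} records, got {n}")
    beta = compute_weights(dataset, config)
    polys: dict[str, PolynomialModel] = {}
    for name in PARAM_NAMES:
        try:
            polys[name] = fit_pwls(dataset.v_x, dataset.parameter_series(name), beta, m)
        except SingularFitError as err:
            raise SingularFitError(f"fit failed for parameter {name!r}: {err}") from err
    return Modulator(
        polynomials=polys,
        velocity_range=(float(dataset.v_x.min()), float(dataset.v_x.max())),
        degree=m,
        A=config.A,
        M_window=config.M_window,
    )
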