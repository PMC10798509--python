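"""Velocity-indexed parameter modulator.

A modulator is a bank of 56 polynomials P_i(v), one per registry entry,
mapping a target walking velocity to a full reflex control parameter set
Y_tar.  Hybrid modulators for circuit-substitution experiments copy selected
parameter functions from a donor into a base modulator.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from . import registry
from .registry import CIRCUIT_GROUPS, PARAM_NAMES, ParameterVector

__all__ = [
    "PolynomialModel",
    "Modulator",
    "CircuitGroup",
    "modulate",
    "substitute_functions",
    "VelocityRangeError",
]

logger = logging.getLogger(__name__)


class VelocityRangeError(ValueError):
    """Target velocity outside the modulator's fitted range."""


@dataclass(frozen=True)
class PolynomialModel:
    """Degree-m polynomial, coefficients ascending in raw velocity powers."""

    degree: int
    omega: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", omega)
        if omega.shape != (self.degree + 1,):
            raise ValueError(
                f"degree-{self.degree} polynomial needs {self.degree + 1} "
                f"coefficients, got {omega.shape}"
            )
        if not np.all(np.isfinite(omega)):
            raise ValueError("polynomial coefficients must be finite")

    def __call__(self, v_x) -> float | np.ndarray:
        return npoly.polyval(v_x, self.omega)


def predict_polynomial(model: PolynomialModel, v_x):
    """Evaluate P(v_x) = sum_j omega_j v_x^j."""
    return model(v_x)


@dataclass(frozen=True)
class CircuitGroup:
    """A named group of control parameters forming one reflex circuit."""

    name: str
    parameters: tuple[str, ...]

    def __post_init__(self) -> None:
        registry.validate_names(self.parameters)


#: The two swing-phase circuits driving the hip flexor.
CIRCUIT1 = CircuitGroup("circuit1", CIRCUIT_GROUPS["circuit1"])
CIRCUIT2 = CircuitGroup("circuit2", CIRCUIT_GROUPS["circuit2"])

_SCHEMA_VERSION = 1


@dataclass
class Modulator:
    """Per-parameter polynomials plus fit metadata."""

    polynomials: dict[str, PolynomialModel]
    velocity_range: tuple[float, float]
    degree: int
    A: float = 1.0
    M_window: int = 125
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.polynomials)
        extra = set(self.polynomials) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(
                f"modulator must carry one polynomial per registry entry; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        lo, hi = self.velocity_range
        if not lo < hi:
            raise ValueError("velocity_range must be non-empty")

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": _SCHEMA_VERSION,
            "degree": self.degree,
            "velocity_range": list(self.velocity_range),
            "A": self.A,
            "M_window": self.M_window,
            "provenance": self.provenance,
            "coefficients": {
                name: self.polynomials[name].omega.tolist() for name in PARAM_NAMES
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Modulator":
        payload = json.loads(Path(path).read_text())
        degree = int(payload["degree"])
        polys = {
            name: PolynomialModel(degree, np.asarray(coefs, dtype=float))
            for name, coefs in payload["coefficients"].items()
        }
        return cls(
            polynomials=polys,
            velocity_range=tuple(payload["velocity_range"]),
            degree=degree,
            A=float(payload["A"]),
            M_window=int(payload["M_window"]),
            provenance=dict(payload.get("provenance", {})),
        )


def modulate(
    mod: Modulator, v_tar: float, clamp_range: bool = True
) -> ParameterVector:
    """Evaluate the full parameter set Y_tar = {P_i(v_tar)} at one velocity.

    Out-of-range targets are clamped to the fitted velocity range (with a
    warning) unless ``clamp_range`` is False, in which case they raise.
    Values escaping registry bounds are clamped to the bounds.
    """
    lo, hi = mod.velocity_range
    v = float(v_tar)
    if not lo <= v <= hi:
        if not clamp_range:
            raise VelocityRangeError(
                f"target velocity {v} outside fitted range [{lo}, {hi}]"
            )
        logger.warning(
            "target velocity %.3f outside fitted range [%.3f, %.3f]; clamping",
            v, lo, hi,
        )
        v = min(max(v, lo), hi)
    values = np.array([float(mod.polynomials[name](v)) for name in PARAM_NAMES])
    clipped = np.clip(values, registry.LOWER, registry.UPPER)
    if np.any(clipped != values):
        out_names = [n for n, a, b in zip(PARAM_NAMES, values, clipped) if a != b]
        logger.warning("modulated values clamped to bounds: %s", out_names)
    return ParameterVector(clipped)


def substitute_functions(
    base: Modulator, donor: Modulator, names: Iterable[str]
) -> Modulator:
    """Hybrid modulator: ``base`` with the named entries taken from ``donor``."""
    if base.degree != donor.degree:
        raise ValueError("base and donor modulators must share polynomial degree")
    names = registry.validate_names(names)
    polys = dict(base.polynomials)
    provenance = dict(base.provenance)
    for name in names:
        polys[name] = donor.polynomials[name]
        provenance[name] = "donor"
    lo = max(base.velocity_range[0], donor.velocity_range[0])
    hi = min(base.velocity_range[1], donor.velocity_range[1])
    return Modulator(
        polynomials=polys,
        velocity_range=(lo, hi),
        degree=base.degree,
        A=base.A,
        M_window=base.M_window,
        provenance=provenance,
    )


def group_names(groups: Sequence[CircuitGroup]) -> list[str]:
    """Union of parameter names over circuit groups, order-preserving."""
    seen: list[str] = []
    for g in groups:
        for n in g.parameters:
            if n not in seen:
                seen.append(n)
    return seen
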