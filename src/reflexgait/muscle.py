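"""Hill-type muscle actuator: force production and activation dynamics.

Each actuator is a contractile element in series with an inelastic tendon of
rest length ``l0``.  Force is the product of the maximum isometric force F0
with an activation-scaled force-length / force-velocity term plus a passive
term::

    F(l~, v~, a) = { a * Fl(l~) * Fv(v~) + Fp(l~) } * F0

where ``l~ = l / l0`` and ``v~ = v / l0`` are the length and velocity scaled
by the rest length.  The curve shapes follow the standard reflex-walking
conventions: a bell-shaped force-length curve peaking at the rest length, a
hyperbolic Hill force-velocity curve (1 at isometric, 0 at the maximum
shortening speed, >1 eccentric plateau), and a passive force that is zero at
or below rest length and grows quadratically above it.  The exact curve
constants are an adopted-form assumption collected in :class:`MuscleCurves`.

Activation low-pass filters the stimulation u with the asymmetric
excitation/deactivation time constant

    tau(u, a) = 0.01 * (0.5 + 1.5 a)   if u > a
    tau(u, a) = 0.04 / (0.5 + 1.5 a)   if u <= a
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MuscleParams",
    "MuscleState",
    "MuscleCurves",
    "DEFAULT_CURVES",
    "DEFAULT_F0",
    "default_muscle_params",
    "scale_state",
    "force_factors",
    "actuator_force",
    "activation_time_constant",
    "activation_step",
]

#: Maximum isometric forces per muscle [N].
DEFAULT_F0: dict[str, float] = {
    "SOL": 4000.0,
    "TA": 800.0,
    "GAS": 1500.0,
    "VAS": 6000.0,
    "HAM": 3000.0,
    "RF": 1000.0,
    "GLU": 1500.0,
    "HFL": 2000.0,
}

#: Sensory pathway delays [s]: longest for the ankle, shortest for the hip.
DEFAULT_DELAYS: dict[str, float] = {
    "SOL": 0.020,
    "TA": 0.020,
    "GAS": 0.020,
    "VAS": 0.010,
    "HAM": 0.005,
    "RF": 0.005,
    "GLU": 0.005,
    "HFL": 0.005,
}


@dataclass(frozen=True)
class MuscleParams:
    """Per-muscle constants."""

    name: str
    F0: float  # maximum isometric force [N]
    l0: float = 0.1  # tendon/actuator rest length [m]
    delay: float = 0.01  # sensory time delay [s]

    def __post_init__(self) -> None:
        if self.F0 <= 0:
            raise ValueError(f"F0 must be positive, got {self.F0}")
        if self.l0 <= 0:
            raise ValueError(f"l0 must be positive, got {self.l0}")
        if self.delay < 0:
            raise ValueError(f"delay must be non-negative, got {self.delay}")


@dataclass
class MuscleState:
    """Dynamic muscle state: scaled length, scaled velocity, activation."""

    l_scaled: float = 1.0
    v_scaled: float = 0.0
    a: float = 0.0

    def __post_init__(self) -> None:
        if self.l_scaled <= 0:
            raise ValueError(f"l_scaled must be positive, got {self.l_scaled}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"activation must lie in [0, 1], got {self.a}")


@dataclass(frozen=True)
class MuscleCurves:
    """Adopted closed-form constants for the Fl / Fv / Fp curves.

    width: force-length bell half-width; at ``l~ = 1 +- width`` the active
    force drops to ``c_residual``.  v_max: maximum shortening speed in rest
    lengths per second.  K: Hill curvature.  N: eccentric force plateau.
    """

    width: float = 0.56
    c_residual: float = 0.05
    v_max: float = 12.0
    K: float = 5.0
    N: float = 1.5

    def fl(self, l_scaled):
        c = np.log(self.c_residual)
        return np.exp(c * np.abs((np.asarray(l_scaled) - 1.0) / self.width) ** 3)

    def fv(self, v_scaled):
        # sign convention: v~ < 0 is shortening
        v = np.asarray(v_scaled, dtype=float)
        short = (self.v_max + v) / (self.v_max - self.K * v)
        ecc = self.N + (self.N - 1.0) * (self.v_max + v) / (
            7.56 * self.K * v - self.v_max
        )
        out = np.where(v <= 0.0, np.maximum(short, 0.0), ecc)
        return out

    def fp(self, l_scaled):
        l = np.asarray(l_scaled, dtype=float)
        return np.where(l > 1.0, ((l - 1.0) / self.width) ** 2, 0.0)


DEFAULT_CURVES = MuscleCurves()


def default_muscle_params(
    l0: float = 0.1, delays: dict[str, float] | None = None
) -> dict[str, MuscleParams]:
    """Standard parameter table for the eight muscles of one leg."""
    delays = DEFAULT_DELAYS if delays is None else delays
    return {
        name: MuscleParams(name=name, F0=F0, l0=l0, delay=delays.get(name, 0.01))
        for name, F0 in DEFAULT_F0.items()
    }


def scale_state(l: float, v: float, l0: float) -> tuple[float, float]:
    """Scale muscle length and velocity by the rest length l0."""
    if l0 <= 0:
        raise ValueError(f"l0 must be positive, got {l0}")
    return l / l0, v / l0


def force_factors(
    l_scaled, v_scaled, curves: MuscleCurves = DEFAULT_CURVES
):
    """Return the (Fl, Fv, Fp) force factors at a scaled state.

    Fl is in (0, 1] and peaks at ``l~ = 1``; Fv(0) = 1, decreasing with
    shortening speed; Fp >= 0, zero at or below the rest length.
    """
    if np.any(np.asarray(l_scaled) <= 0):
        raise ValueError("l_scaled must be positive")
    return curves.fl(l_scaled), curves.fv(v_scaled), curves.fp(l_scaled)


def actuator_force(
    state: MuscleState,
    params: MuscleParams,
    curves: MuscleCurves = DEFAULT_CURVES,
) -> float:
    """Total actuator force [N]; affine in activation at fixed kinematics."""
    fl, fv, fp = force_factors(state.l_scaled, state.v_scaled, curves)
    return float((state.a * fl * fv + fp) * params.F0)


def activation_time_constant(u: float, a: float) -> float:
    """Asymmetric excitation/deactivation time constant tau(u, a) [s]."""
    if u > a:
        return 0.01 * (0.5 + 1.5 * a)
    return 0.04 / (0.5 + 1.5 * a)


def activation_step(u: float, a: float, dt: float) -> float:
    """One explicit-Euler step of the activation ODE, clamped to [0, 1]."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"stimulation must lie in [0, 1], got {u}")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activation must lie in [0, 1], got {a}")
    tau = activation_time_constant(u, a)
    a_new = a + dt * (u - a) / tau
    return float(min(1.0, max(0.0, a_new)))
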