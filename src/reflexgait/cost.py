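"""Trial evaluation: rewards, fall penalty, metabolic energy, CoT, objective.

A candidate parameter set is scored by simulating a walking trial of at most
T timesteps and accumulating

    f(Y) = sum_{t=1..T'} [ r_alive + r_forward + r_torso ] + r_fall
           + alpha_E * (CoT - 0.3)

where r_alive = -1 rewards staying upright, r_forward = min(1, alpha_v *
|v_x - v_x_tar|^2) penalizes velocity-tracking error, r_torso = alpha_t *
theta_t^2 penalizes torso lean, r_fall adds 5000 if the model falls within
the first 700 steps, and the final term prices the trial's cost of transport
CoT = J / (M g Dd) against a 0.3 offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .muscle import MuscleParams

__all__ = [
    "CostWeights",
    "MetabolicConfig",
    "TrialTrace",
    "step_reward",
    "fall_cost",
    "metabolic_rate",
    "cot",
    "trial_cost",
]


@dataclass(frozen=True)
class CostWeights:
    """Objective weights and trial limits."""

    alpha_E: float = 5000.0  # CoT weight
    alpha_v: float = 5.0  # velocity-tracking weight
    alpha_t: float = 1.0  # torso-lean weight
    cot_offset: float = 0.3  # CoT deviation constant
    T: int = 5000  # trial length cap [steps]
    fall_window: int = 700  # early-fall penalty window [steps]
    fall_penalty: float = 5000.0
    cot_cap: float = 10.0  # CoT stand-in when Dd <= 0 (immediate fall)
    forward_lower_limit: bool = False  # subtract 1 from r_forward (range [-1, 0])


@dataclass(frozen=True)
class MetabolicConfig:
    """Constants of the adopted muscle metabolic-energy model.

    Per-muscle rate [W] = basal + activation/maintenance heat + shortening
    heat + positive mechanical work; every term is non-negative and
    non-decreasing in activation at fixed kinematics.
    """

    basal: float = 0.5  # [W] per muscle
    c_act: float = 40.0  # activation + maintenance heat scale [W per unit F0*l0]
    c_short: float = 0.25  # shortening heat scale


@dataclass
class TrialTrace:
    """Per-timestep record of one gait evaluation."""

    dt: float
    v_x: np.ndarray  # horizontal velocity per step [m/s]
    theta_t: np.ndarray  # torso angle per step [rad]
    step_distance: np.ndarray  # distance increment per step [m]
    muscle_energy: np.ndarray  # (T', n_muscles) energy increments [J]
    muscle_names: tuple[str, ...]
    fell: bool = False

    def __post_init__(self) -> None:
        self.v_x = np.asarray(self.v_x, dtype=float)
        self.theta_t = np.asarray(self.theta_t, dtype=float)
        self.step_distance = np.asarray(self.step_distance, dtype=float)
        self.muscle_energy = np.atleast_2d(np.asarray(self.muscle_energy, dtype=float))
        n = len(self.v_x)
        if not (len(self.theta_t) == len(self.step_distance) == n):
            raise ValueError("trace arrays must share length T'")
        if self.muscle_energy.shape[0] != n:
            raise ValueError("muscle_energy must have one row per step")
        if np.any(self.muscle_energy < 0):
            raise ValueError("energy increments must be non-negative")

    @property
    def T_prime(self) -> int:
        return len(self.v_x)

    @property
    def distance(self) -> float:
        return float(self.step_distance.sum())

    @property
    def total_energy(self) -> float:
        return float(self.muscle_energy.sum())

    @property
    def mean_velocity(self) -> float:
        return float(self.distance / (self.T_prime * self.dt))

    def cumulative_distance(self) -> np.ndarray:
        return np.cumsum(self.step_distance)


def step_reward(
    v_x: float, v_x_tar: float, theta_t: float, weights: CostWeights
) -> tuple[float, float, float]:
    """Per-step reward components (r_alive, r_forward, r_torso)."""
    r_alive = -1.0
    r_forward = min(1.0, weights.alpha_v * abs(v_x - v_x_tar) ** 2)
    if weights.forward_lower_limit:
        r_forward -= 1.0
    r_torso = weights.alpha_t * theta_t**2
    return r_alive, r_forward, r_torso


def fall_cost(fell: bool, T_prime: int, weights: CostWeights) -> float:
    """Early-fall penalty: fall_penalty if a fall occurs within the window."""
    if T_prime < 0:
        raise ValueError("T_prime must be non-negative")
    return weights.fall_penalty if (fell and T_prime <= weights.fall_window) else 0.0


def metabolic_rate(
    a: np.ndarray,
    l_scaled: np.ndarray,
    v_scaled: np.ndarray,
    force: np.ndarray,
    params: list[MuscleParams],
    dt: float,
    config: MetabolicConfig = MetabolicConfig(),
) -> np.ndarray:
    """Per-muscle metabolic energy increments [J] for one timestep.

    The model sums a basal rate, an activation/maintenance heat rate scaled
    by F0*l0 and increasing in activation, a shortening heat proportional to
    activation and shortening speed, and the positive mechanical work done by
    the muscle (force times shortening velocity when shortening).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=float)
    v_scaled = np.asarray(v_scaled, dtype=float)
    force = np.asarray(force, dtype=float)
    F0 = np.array([p.F0 for p in params])
    l0 = np.array([p.l0 for p in params])

    heat_am = config.c_act * F0 * l0 * a * (0.5 + 0.5 * a) * 1e-3
    heat_short = config.c_short * F0 * l0 * a * np.maximum(0.0, -v_scaled) * 1e-3
    # mechanical power: muscle shortens at v = v~ * l0, does positive work
    work_pos = np.maximum(0.0, force * (-v_scaled * l0))
    rate = config.basal + heat_am + heat_short + work_pos
    return rate * dt


def cot(J: float, mass: float, gravity: float, distance: float) -> float:
    """Cost of transport: J / (M g Dd), dimensionless."""
    if mass <= 0 or gravity <= 0:
        raise ValueError("mass and gravity must be positive")
    if distance <= 0:
        raise ValueError(f"distance must be positive, got {distance}")
    return J / (mass * gravity * distance)


def trial_cost(
    trace: TrialTrace,
    v_x_tar: float,
    weights: CostWeights,
    mass: float = 80.0,
    gravity: float = 9.81,
) -> float:
    """Total objective f for one trial (lower is better)."""
    r_alive, r_forward, r_torso = (
        np.full(trace.T_prime, -1.0),
        np.minimum(1.0, weights.alpha_v * np.abs(trace.v_x - v_x_tar) ** 2),
        weights.alpha_t * trace.theta_t**2,
    )
    if weights.forward_lower_limit:
        r_forward = r_forward - 1.0
    running = float(r_alive.sum() + r_forward.sum() + r_torso.sum())
    penalty = fall_cost(trace.fell, trace.T_prime, weights)
    if trace.distance > 0:
        cot_val = cot(trace.total_energy, mass, gravity, trace.distance)
        cot_val = min(cot_val, weights.cot_cap)
    else:
        cot_val = weights.cot_cap
    return running + penalty + weights.alpha_E * (cot_val - weights.cot_offset)
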