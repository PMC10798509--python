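"""Deterministic surrogate gait evaluator and fixture generators.

The surrogate is explicitly NOT a physics model.  It encodes only the
structural assumptions the modulation method exploits:

* for every velocity there is an optimal parameter set ``y*(v)`` (a bank of
  smooth curves in bound-normalized coordinates);
* cost of transport follows a concave-up quadratic of velocity, with an
  additive penalty growing with the (weighted) deviation of the candidate
  parameters from ``y*(v)`` — an efficiency-graded neighbourhood;
* candidates too far from the optimum fall (instability);
* achieved velocity tracks the target with a deviation-dependent bias.

The deviation weights make the two swing-phase hip-flexor circuits
(``circuit1``/``circuit2``) the most efficiency-critical parameters, so the
substitution analysis has a ground truth to recover.  Everything is
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import registry
from .cost import TrialTrace
from .pwls import GaitDataset
from .registry import MUSCLES, N_PARAMS, PARAM_NAMES, ParameterVector

__all__ = [
    "SurrogateConfig",
    "SurrogateEvaluator",
    "truth_normalized",
    "truth_parameters",
    "make_two_level_dataset",
    "generate_dataset",
]

# fixed per-parameter phases/frequencies for the ground-truth curves;
# derived from the registry index, NOT from any run seed
_IDX = np.arange(N_PARAMS)
_FREQ = 0.8 + 0.15 * (_IDX % 5)
_PHASE = 0.7 * _IDX

#: deviation weights: the two key circuits dominate the efficiency penalty
_PENALTY_WEIGHTS = np.full(N_PARAMS, 0.15)
for _name in registry.CIRCUIT_GROUPS["circuit1"] + registry.CIRCUIT_GROUPS["circuit2"]:
    _PENALTY_WEIGHTS[registry.index_of(_name)] = 3.0
_PENALTY_WEIGHTS /= _PENALTY_WEIGHTS.sum()

#: fixed per-muscle shares used to distribute trace energy (hip muscles
#: dominate, echoing the swing/stance balance-of-effort of real gaits)
_ENERGY_SHARES = np.array([0.16, 0.05, 0.10, 0.17, 0.16, 0.05, 0.15, 0.16])
_ENERGY_SHARES /= _ENERGY_SHARES.sum()


def truth_normalized(v: float) -> np.ndarray:
    """Velocity-dependent optimal parameters in normalized [0,1] coordinates."""
    return np.clip(0.5 + 0.25 * np.sin(_FREQ * v + _PHASE), 0.05, 0.95)


def truth_parameters(v: float) -> ParameterVector:
    """Optimal parameter set y*(v) in raw registry units."""
    return ParameterVector(registry.denormalize(truth_normalized(v)))


@dataclass(frozen=True)
class SurrogateConfig:
    """Constants of the surrogate gait model."""

    cot_curve: tuple[float, float, float] = (0.55, -1.4, 1.2)  # (c2, c1, c0)
    penalty_scale: float = 6.0  # excess CoT per unit squared deviation
    bias_scale: float = 0.35  # achieved-velocity bias per unit deviation
    stability_radius: float = 0.18  # weighted-rms deviation causing a fall
    noise_v: float = 0.01  # sd of achieved-velocity noise [m/s]
    noise_cot: float = 0.005  # sd of CoT noise
    T: int = 5000  # trial cap [steps]
    dt: float = 0.005  # timestep [s]
    mass: float = 80.0  # [kg]
    gravity: float = 9.81  # [m/s^2]

    def __post_init__(self) -> None:
        if self.cot_curve[0] <= 0:
            raise ValueError("CoT quadratic must be concave-up (c2 > 0)")
        if self.stability_radius <= 0:
            raise ValueError("stability_radius must be positive")

    def cot_of_velocity(self, v) -> np.ndarray:
        c2, c1, c0 = self.cot_curve
        return c2 * np.asarray(v) ** 2 + c1 * np.asarray(v) + c0


def _deviation(Y: ParameterVector, v_tar: float) -> float:
    """Weighted-rms deviation from the optimum, in normalized coordinates."""
    delta = registry.normalize(Y.values) - truth_normalized(v_tar)
    return float(np.sqrt(np.sum(_PENALTY_WEIGHTS * delta**2)))


class SurrogateEvaluator:
    """Callable (Y, v_tar, seed) -> TrialTrace gait evaluator."""

    def __init__(self, config: SurrogateConfig | None = None) -> None:
        self.config = config or SurrogateConfig()

    def __call__(
        self, Y: ParameterVector, v_tar: float, seed: int
    ) -> TrialTrace:
        cfg = self.config
        rng = np.random.default_rng(seed)
        d = _deviation(Y, v_tar)
        fell = d > cfg.stability_radius

        v_x = (
            v_tar
            - cfg.bias_scale * d
            + (cfg.noise_v * rng.standard_normal() if cfg.noise_v else 0.0)
        )
        v_x = max(v_x, 0.05)
        cot_val = (
            float(cfg.cot_of_velocity(v_x))
            + cfg.penalty_scale * d**2
            + (cfg.noise_cot * abs(rng.standard_normal()) if cfg.noise_cot else 0.0)
        )

        if fell:
            # fall time shrinks as the candidate strays further
            frac = min(1.0, cfg.stability_radius / d)
            T_prime = max(1, int(cfg.T * 0.14 * frac))
        else:
            T_prime = cfg.T

        step_d = np.full(T_prime, v_x * cfg.dt)
        distance = float(step_d.sum())
        total_J = cot_val * cfg.mass * cfg.gravity * distance
        energy = np.outer(np.full(T_prime, total_J / T_prime), _ENERGY_SHARES)
        theta_t = np.full(T_prime, 0.04 + 0.2 * d)
        return TrialTrace(
            dt=cfg.dt,
            v_x=np.full(T_prime, v_x),
            theta_t=theta_t,
            step_distance=step_d,
            muscle_energy=energy,
            muscle_names=MUSCLES,
            fell=fell,
        )


# ---------------------------------------------------------------------------
# fixture generators
# ---------------------------------------------------------------------------

def make_two_level_dataset(
    parameter: str = "G_HFL",
    n_velocities: int = 18,
    n_levels: int = 9,
    v_range: tuple[float, float] = (0.4, 2.1),
    cot_low: float = 0.5,
    cot_high: float = 1.0,
) -> GaitDataset:
    """Two-CoT-level toy dataset on an 18 x 9 velocity/parameter-value grid.

    For one control parameter the grid spans its registry bounds; at each
    velocity the grid point closest to the ground-truth curve y*(v) gets the
    low CoT (efficient) and the rest the high CoT.  The efficient subset
    therefore traces a known smooth curve, which a strongly biased PWLS fit
    should follow.
    """
    idx = registry.index_of(parameter)
    lo, hi = registry.LOWER[idx], registry.UPPER[idx]
    velocities = np.linspace(*v_range, n_velocities)
    levels = np.linspace(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo), n_levels)

    v_out, cot_out, Y_out = [], [], []
    for v in velocities:
        target = registry.denormalize(truth_normalized(v))[idx]
        best = int(np.argmin(np.abs(levels - target)))
        for k, level in enumerate(levels):
            Y = registry.DEFAULTS.copy()
            Y[idx] = level
            v_out.append(v)
            cot_out.append(cot_low if k == best else cot_high)
            Y_out.append(Y)
    return GaitDataset(
        v_x=np.array(v_out), cot=np.array(cot_out), Y=np.vstack(Y_out)
    )


def efficient_subset_mask(dataset: GaitDataset, cot_low: float = 0.5) -> np.ndarray:
    """Boolean mask of the efficient (low-CoT) records of a two-level fixture."""
    return np.isclose(dataset.cot, cot_low)


def make_polynomial_dataset(
    velocities: np.ndarray,
    degree: int = 6,
    seed: int = 0,
    cot_config: SurrogateConfig | None = None,
) -> tuple[GaitDataset, dict[str, np.ndarray]]:
    """Noise-free dataset whose parameter curves ARE known polynomials.

    Each registry entry follows a random degree-``degree`` polynomial of
    velocity kept strictly inside its bounds; the returned coefficient table
    (raw ascending-power basis) is the exact ground truth, so a fitted
    modulator of the same degree must recover it regardless of the weight
    bias A.
    """
    from numpy.polynomial import Polynomial

    cfg = cot_config or SurrogateConfig()
    v = np.asarray(velocities, dtype=float)
    rng = np.random.default_rng(seed)
    center, halfspan = v.mean(), max(v.max() - v.mean(), v.mean() - v.min())
    s = (v - center) / halfspan

    coeffs: dict[str, np.ndarray] = {}
    Y = np.empty((len(v), N_PARAMS))
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = registry.LOWER[i], registry.UPPER[i]
        mid, amp = (lo + hi) / 2.0, 0.3 * (hi - lo)
        c = rng.uniform(-1.0, 1.0, degree + 1)
        q = Polynomial(c)
        qs = q(s)
        q_max = max(np.abs(q(np.linspace(-1, 1, 201))).max(), 1e-12)
        # compose with the affine map to get raw-velocity coefficients
        raw = (amp / q_max) * q(Polynomial([-center / halfspan, 1.0 / halfspan]))
        raw = raw + Polynomial([mid])
        omega = np.zeros(degree + 1)
        omega[: len(raw.coef)] = raw.coef
        coeffs[name] = omega
        Y[:, i] = mid + (amp / q_max) * qs
    cot_vals = cfg.cot_of_velocity(v)
    return GaitDataset(v_x=v.copy(), cot=np.asarray(cot_vals), Y=Y), coeffs


def generate_dataset(
    n: int,
    config: SurrogateConfig | None = None,
    seed: int = 0,
    v_range: tuple[float, float] = (0.4, 2.0),
    param_noise: float = 0.05,
) -> GaitDataset:
    """Bulk synthetic dataset: records scattered around y*(v).

    Velocities are uniform over ``v_range``; parameters are the ground truth
    plus Gaussian noise (sd ``param_noise`` in normalized coordinates); CoT
    follows the configured quadratic plus the deviation penalty and a
    half-normal noise term.  ``param_noise = 0`` puts every record exactly on
    the generating curves.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = config or SurrogateConfig()
    rng = np.random.default_rng(seed)
    v = rng.uniform(*v_range, size=n)
    Y_norm = np.vstack([truth_normalized(vi) for vi in v])
    if param_noise > 0:
        Y_norm = np.clip(
            Y_norm + param_noise * rng.standard_normal(Y_norm.shape), 0.0, 1.0
        )
    dev2 = np.sum(
        _PENALTY_WEIGHTS
        * (Y_norm - np.vstack([truth_normalized(vi) for vi in v])) ** 2,
        axis=1,
    )
    cot_vals = cfg.cot_of_velocity(v) + cfg.penalty_scale * dev2
    if cfg.noise_cot > 0 and param_noise > 0:
        cot_vals = cot_vals + cfg.noise_cot * np.abs(rng.standard_normal(n))
    Y = np.vstack([registry.denormalize(row) for row in Y_norm])
    return GaitDataset(v_x=v, cot=np.asarray(cot_vals), Y=Y)
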