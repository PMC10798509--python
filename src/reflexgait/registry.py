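"""Named registry of the 56 reflex control parameters.

The reflex controller for a planar 8-muscle-per-leg walker exposes a single
flat parameter vector Y with 56 named entries: feedback gains, target muscle
lengths, PD gains and target joint angles for torso balance and stance
preparation, pre-stimulation offsets, foot-placement (SIMBICON) coefficients
and gait-phase thresholds.  The registry fixes the canonical order, the
feasible bounds and a default value per entry, so that parameter vectors
round-trip losslessly to ordered 56-element arrays.

The five parameters that name the two swing-phase length-feedback circuits
(``G_HFL``, ``l_HFL_tar``, ``G_HAM_HFL``, ``l_HAM_HFL_tar``) and the torso
reference angle (``theta_t_tar``) are mandatory names; everything else follows
the stance/swing wiring of the controller (see :mod:`reflexgait.reflex`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MUSCLES",
    "ParamSpec",
    "REGISTRY",
    "PARAM_NAMES",
    "N_PARAMS",
    "ParameterVector",
    "CIRCUIT_GROUPS",
]

#: Muscle identifiers, one leg (controller is left/right symmetric).
MUSCLES = ("SOL", "TA", "GAS", "VAS", "HAM", "RF", "GLU", "HFL")


@dataclass(frozen=True)
class ParamSpec:
    """One named control parameter: default value and feasible bounds."""

    name: str
    default: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.default <= self.upper:
            raise ValueError(
                f"default for {self.name!r} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )


def _p(name: str, default: float, lower: float, upper: float) -> ParamSpec:
    return ParamSpec(name, default, lower, upper)


# Stance-phase reflexes: positive force feedback on the anti-gravity muscles,
# ankle length feedback with SOL suppression, and muscle-driven PD torso
# balance at the hip (HFL drives the torso forward, GLU/HAM backward).
_STANCE = [
    _p("G_SOL_st", 1.2, 0.0, 5.0),
    _p("G_VAS_st", 1.0, 0.0, 5.0),
    _p("G_GAS_st", 1.1, 0.0, 5.0),
    _p("G_GLU_st", 0.5, 0.0, 5.0),
    _p("G_TA_st", 1.1, 0.0, 5.0),
    _p("l_TA_st_tar", 0.71, 0.4, 1.5),
    _p("G_SOL_TA", 0.3, 0.0, 5.0),
    _p("K_HFL_st", 1.9, 0.0, 10.0),
    _p("D_HFL_st", 0.25, 0.0, 2.0),
    _p("K_GLU_st", 1.9, 0.0, 10.0),
    _p("D_GLU_st", 0.25, 0.0, 2.0),
    _p("K_HAM_st", 1.9, 0.0, 10.0),
    _p("D_HAM_st", 0.25, 0.0, 2.0),
    _p("theta_t_tar", 0.105, -0.3, 0.3),
    # knee-overextension guard on VAS
    _p("G_VAS_k", 2.0, 0.0, 10.0),
    _p("theta_k_off", 2.97, 1.5, 3.1),
]

# Swing-phase reflexes: hip-flexor length feedback suppressed by hamstring
# stretch (the two key circuits), braking force feedback on GLU/HAM and toe
# clearance via TA length feedback.
_SWING = [
    _p("G_HFL", 0.5, 0.0, 5.0),
    _p("l_HFL_tar", 0.6, 0.4, 1.5),
    _p("G_HAM_HFL", 4.0, 0.0, 10.0),
    _p("l_HAM_HFL_tar", 0.85, 0.4, 1.5),
    _p("G_GLU_sw", 0.4, 0.0, 5.0),
    _p("G_HAM_sw", 0.65, 0.0, 5.0),
    _p("G_TA_sw", 1.1, 0.0, 5.0),
    _p("l_TA_sw_tar", 0.71, 0.4, 1.5),
]

# Sub-phase stimulation: late-stance push-off boosts, late-swing retraction,
# and PD fixation of hip and knee while preparing for heel strike.
_SUBPHASE = [
    _p("G_SOL_ls", 0.4, 0.0, 5.0),
    _p("G_GAS_ls", 0.4, 0.0, 5.0),
    _p("du_HFL_ls", 0.15, 0.0, 1.0),
    _p("G_HAM_lsw", 0.4, 0.0, 5.0),
    _p("G_GLU_lsw", 0.4, 0.0, 5.0),
    _p("K_hip_sp", 2.0, 0.0, 10.0),
    _p("D_hip_sp", 0.3, 0.0, 2.0),
    _p("K_knee_sp", 2.0, 0.0, 10.0),
    _p("D_knee_sp", 0.3, 0.0, 2.0),
    _p("theta_k_sp_tar", 2.8, 1.5, 3.1),
]

# SIMBICON foot placement: theta_h_tar = theta_h0 + c_d*d + c_v*v_x applied
# during stance preparation.
_SIMBICON = [
    _p("theta_h0", 0.3, -1.0, 1.0),
    _p("c_d", 0.25, 0.0, 2.0),
    _p("c_v", 0.25, 0.0, 2.0),
]

# Pre-stimulation floors per muscle, separate for stance and swing.
_PRESTIM = [
    _p(f"u0_{m}_st", 0.02, 0.01, 0.2) for m in MUSCLES
] + [
    _p(f"u0_{m}_sw", 0.02, 0.01, 0.2) for m in MUSCLES
]

# Normalized phase-progress thresholds triggering the sub-phases.
_THRESHOLDS = [
    _p("late_stance_onset", 0.6, 0.0, 1.0),
    _p("late_swing_onset", 0.6, 0.0, 1.0),
    _p("stance_prep_onset", 0.8, 0.0, 1.0),
]

REGISTRY: tuple[ParamSpec, ...] = tuple(
    _STANCE + _SWING + _SUBPHASE + _SIMBICON + _PRESTIM + _THRESHOLDS
)
PARAM_NAMES: tuple[str, ...] = tuple(s.name for s in REGISTRY)
N_PARAMS: int = len(REGISTRY)
assert N_PARAMS == 56, f"registry must contain exactly 56 entries, got {N_PARAMS}"

_INDEX: dict[str, int] = {s.name: i for i, s in enumerate(REGISTRY)}

LOWER = np.array([s.lower for s in REGISTRY])
UPPER = np.array([s.upper for s in REGISTRY])
DEFAULTS = np.array([s.default for s in REGISTRY])

#: The two swing-phase reflex circuits identified as critical for efficiency.
CIRCUIT_GROUPS: dict[str, tuple[str, ...]] = {
    "circuit1": ("G_HFL", "l_HFL_tar"),
    "circuit2": ("G_HAM_HFL", "l_HAM_HFL_tar"),
}


@dataclass
class ParameterVector:
    """A full 56-entry reflex control parameter set in registry order."""

    values: np.ndarray = field(default_factory=lambda: DEFAULTS.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PARAMS,):
            raise ValueError(
                f"parameter vector must have {N_PARAMS} entries, "
                f"got shape {self.values.shape}"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ParameterVector":
        """Build from name->value pairs; unnamed entries take defaults."""
        values = DEFAULTS.copy()
        for name, value in mapping.items():
            values[index_of(name)] = value
        return cls(values)

    @classmethod
    def defaults(cls) -> "ParameterVector":
        return cls(DEFAULTS.copy())

    def __getitem__(self, name: str) -> float:
        return float(self.values[index_of(name)])

    def __setitem__(self, name: str, value: float) -> None:
        self.values[index_of(name)] = value

    def replace(self, **updates: float) -> "ParameterVector":
        out = ParameterVector(self.values.copy())
        for name, value in updates.items():
            out[name] = value
        return out

    def clipped(self) -> "ParameterVector":
        """Return a copy with every entry clipped to its registry bounds."""
        return ParameterVector(np.clip(self.values, LOWER, UPPER))

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(PARAM_NAMES, self.values)}


def index_of(name: str) -> int:
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(f"unknown control parameter {name!r}") from None


def validate_names(names: Iterable[str]) -> list[str]:
    """Check every name against the registry, returning them as a list."""
    out = list(names)
    for n in out:
        index_of(n)
    return out


def normalize(values: np.ndarray) -> np.ndarray:
    """Map raw parameter values to bound-normalized [0, 1] coordinates."""
    return (np.asarray(values, dtype=float) - LOWER) / (UPPER - LOWER)


def denormalize(unit: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`."""
    return LOWER + np.asarray(unit, dtype=float) * (UPPER - LOWER)
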