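"""Reflex-based stimulation laws with delayed sensory feedback.

The controller maps delayed sensory information to per-muscle stimulation
signals through three primitives — positive/negative force feedback (Golgi
tendon organ pathway), length feedback (muscle spindle stretch reflex) and
muscle-driven PD control toward target joint angles — wired differently in
the stance and swing phases.  Sub-phases (late stance, late swing, stance
preparation) add push-off, leg-retraction and heel-strike-preparation
stimulation; SIMBICON-style foot placement sets the swing-hip target angle
linearly in the hip-to-ankle offset d and the horizontal velocity v_x.

All stimulation outputs are clamped to [u_min, 1].
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .registry import MUSCLES, ParameterVector

__all__ = [
    "LegPhase",
    "SensorySample",
    "DelayBuffer",
    "sample_delayed",
    "force_feedback",
    "length_feedback",
    "pd_stimulation",
    "simbicon_hip_target",
    "compute_stimulations",
    "update_phase",
    "U_MIN",
]

#: Default stimulation floor.
U_MIN = 0.01


class LegPhase(Enum):
    STANCE = "stance"
    LATE_STANCE = "late_stance"
    SWING = "swing"
    LATE_SWING = "late_swing"
    STANCE_PREPARATION = "stance_preparation"


_STANCE_PHASES = {LegPhase.STANCE, LegPhase.LATE_STANCE}
_SWING_PHASES = {
    LegPhase.SWING,
    LegPhase.LATE_SWING,
    LegPhase.STANCE_PREPARATION,
}


@dataclass
class SensorySample:
    """Sensor snapshot for one leg at one instant."""

    time: float
    muscle_force: dict[str, float] = field(default_factory=dict)  # scaled F~
    muscle_length: dict[str, float] = field(default_factory=dict)  # scaled l~
    theta_t: float = 0.0  # torso angle [rad]
    theta_h: float = 0.0  # hip angle [rad]
    theta_k: float = 0.0  # knee angle [rad]
    theta_t_dot: float = 0.0
    theta_h_dot: float = 0.0
    theta_k_dot: float = 0.0
    contact: bool = True
    v_x: float = 0.0  # horizontal velocity [m/s]
    d: float = 0.0  # hip-to-ankle horizontal offset [m]

    def __post_init__(self) -> None:
        for name, f in self.muscle_force.items():
            if f < 0:
                raise ValueError(f"scaled force for {name} must be >= 0, got {f}")


class DelayBuffer:
    """Timestamped ring of sensory samples supporting delayed lookup.

    Lookup uses zero-order hold: the stored sample nearest below the query
    time.  Before any history exists at ``t - delay`` the earliest sample is
    held (never extrapolates into the future).
    """

    def __init__(self, capacity: int = 256) -> None:
        self.capacity = capacity
        self._times: list[float] = []
        self._samples: list[SensorySample] = []

    def push(self, sample: SensorySample) -> None:
        if self._times and sample.time < self._times[-1]:
            raise ValueError("sample times must be non-decreasing")
        self._times.append(sample.time)
        self._samples.append(sample)
        if len(self._times) > self.capacity:
            del self._times[0]
            del self._samples[0]

    def __len__(self) -> int:
        return len(self._samples)

    def latest(self) -> SensorySample:
        if not self._samples:
            raise RuntimeError("delay buffer is empty")
        return self._samples[-1]

    def at(self, t_query: float) -> SensorySample:
        if not self._samples:
            raise RuntimeError("delay buffer is empty")
        idx = bisect.bisect_right(self._times, t_query) - 1
        return self._samples[max(idx, 0)]


def sample_delayed(buffer: DelayBuffer, t: float, delay: float) -> SensorySample:
    """Sensory sample as seen through a pathway with time delay ``delay``."""
    if delay < 0:
        raise ValueError(f"delay must be non-negative, got {delay}")
    return buffer.at(t - delay)


def force_feedback(G: float, F_scaled_delayed: float) -> float:
    """u = G * F~(t - dt): monosynaptic Ib force feedback."""
    if G < 0:
        raise ValueError(f"gain must be non-negative, got {G}")
    return G * F_scaled_delayed


def length_feedback(G: float, l_delayed: float, l_tar: float) -> float:
    """u = max(0, G * (l - l_tar)): spindle stretch reflex above target."""
    if G < 0:
        raise ValueError(f"gain must be non-negative, got {G}")
    return max(0.0, G * (l_delayed - l_tar))


def pd_stimulation(
    K: float,
    D: float,
    theta: float,
    theta_dot: float,
    theta_tar: float,
    direction: str,
) -> float:
    """Muscle-driven PD stimulation toward a target joint angle.

    ``direction`` is '+' for a muscle torquing the joint positively and '-'
    for the antagonist; either way the output is clipped at zero since a
    muscle can only pull.
    """
    if K < 0 or D < 0:
        raise ValueError("PD gains must be non-negative")
    if direction == "+":
        return max(0.0, K * (theta_tar - theta) - D * theta_dot)
    if direction == "-":
        return max(0.0, K * (theta - theta_tar) + D * theta_dot)
    raise ValueError(f"direction must be '+' or '-', got {direction!r}")


def simbicon_hip_target(params: ParameterVector, d: float, v_x: float) -> float:
    """Foot-placement target hip angle: theta_h0 + c_d*d + c_v*v_x."""
    return params["theta_h0"] + params["c_d"] * d + params["c_v"] * v_x


def _mf(s: SensorySample, name: str) -> float:
    return s.muscle_force.get(name, 0.0)


def _ml(s: SensorySample, name: str) -> float:
    return s.muscle_length.get(name, 1.0)


def compute_stimulations(
    phase: LegPhase,
    buffer: DelayBuffer,
    params: ParameterVector,
    t: float,
    delays: dict[str, float] | None = None,
    u_min: float = U_MIN,
) -> dict[str, float]:
    """Per-muscle stimulation for one leg at time ``t``.

    Only the circuits of the active phase contribute; the other phase's
    circuits contribute exactly zero.  Every output is clamped to
    ``[u_min, 1]``.
    """
    from .muscle import DEFAULT_DELAYS

    delays = DEFAULT_DELAYS if delays is None else delays

    def delayed(name: str) -> SensorySample:
        return sample_delayed(buffer, t, delays.get(name, 0.01))

    u = {}
    if phase in _STANCE_PHASES:
        floor = {m: max(u_min, params[f"u0_{m}_st"]) for m in MUSCLES}
        s_sol = delayed("SOL")
        s_gas = delayed("GAS")
        s_vas = delayed("VAS")
        s_glu = delayed("GLU")
        s_ta = delayed("TA")
        s_hip = delayed("HFL")

        u["SOL"] = floor["SOL"] + force_feedback(params["G_SOL_st"], _mf(s_sol, "SOL"))
        u["GAS"] = floor["GAS"] + force_feedback(params["G_GAS_st"], _mf(s_gas, "GAS"))
        u["GLU"] = floor["GLU"] + force_feedback(params["G_GLU_st"], _mf(s_glu, "GLU"))
        # VAS force feedback with a knee-overextension guard
        u["VAS"] = (
            floor["VAS"]
            + force_feedback(params["G_VAS_st"], _mf(s_vas, "VAS"))
            - params["G_VAS_k"] * max(0.0, s_vas.theta_k - params["theta_k_off"])
        )
        # TA stretch reflex suppressed by SOL force (F- crossed pathway)
        u["TA"] = (
            floor["TA"]
            + length_feedback(
                params["G_TA_st"], _ml(s_ta, "TA"), params["l_TA_st_tar"]
            )
            - force_feedback(params["G_SOL_TA"], _mf(s_sol, "SOL"))
        )
        # torso balance PD at the hip muscles
        tt = params["theta_t_tar"]
        u["HFL"] = floor["HFL"] + pd_stimulation(
            params["K_HFL_st"], params["D_HFL_st"], s_hip.theta_t, s_hip.theta_t_dot, tt, "+"
        )
        u["GLU"] += pd_stimulation(
            params["K_GLU_st"], params["D_GLU_st"], s_hip.theta_t, s_hip.theta_t_dot, tt, "-"
        )
        u["HAM"] = floor["HAM"] + pd_stimulation(
            params["K_HAM_st"], params["D_HAM_st"], s_hip.theta_t, s_hip.theta_t_dot, tt, "-"
        )
        u["RF"] = floor["RF"]

        if phase is LegPhase.LATE_STANCE:
            u["SOL"] += force_feedback(params["G_SOL_ls"], _mf(s_sol, "SOL"))
            u["GAS"] += force_feedback(params["G_GAS_ls"], _mf(s_gas, "GAS"))
            u["HFL"] += params["du_HFL_ls"]
    else:
        floor = {m: max(u_min, params[f"u0_{m}_sw"]) for m in MUSCLES}
        s_hfl = delayed("HFL")
        s_ham = delayed("HAM")
        s_glu = delayed("GLU")
        s_ta = delayed("TA")

        # the two key swing circuits: HFL stretch reflex minus HAM-stretch
        # suppression
        u["HFL"] = (
            floor["HFL"]
            + length_feedback(params["G_HFL"], _ml(s_hfl, "HFL"), params["l_HFL_tar"])
            - length_feedback(
                params["G_HAM_HFL"], _ml(s_ham, "HAM"), params["l_HAM_HFL_tar"]
            )
        )
        u["GLU"] = floor["GLU"] + force_feedback(params["G_GLU_sw"], _mf(s_glu, "GLU"))
        u["HAM"] = floor["HAM"] + force_feedback(params["G_HAM_sw"], _mf(s_ham, "HAM"))
        u["TA"] = floor["TA"] + length_feedback(
            params["G_TA_sw"], _ml(s_ta, "TA"), params["l_TA_sw_tar"]
        )
        u["SOL"] = floor["SOL"]
        u["GAS"] = floor["GAS"]
        u["VAS"] = floor["VAS"]
        u["RF"] = floor["RF"]

        if phase is LegPhase.LATE_SWING:
            u["HAM"] += force_feedback(params["G_HAM_lsw"], _mf(s_ham, "HAM"))
            u["GLU"] += force_feedback(params["G_GLU_lsw"], _mf(s_glu, "GLU"))
        elif phase is LegPhase.STANCE_PREPARATION:
            s_hip = delayed("HFL")
            theta_h_tar = simbicon_hip_target(params, s_hip.d, s_hip.v_x)
            u["HFL"] += pd_stimulation(
                params["K_hip_sp"], params["D_hip_sp"],
                s_hip.theta_h, s_hip.theta_h_dot, theta_h_tar, "+",
            )
            u["GLU"] += pd_stimulation(
                params["K_hip_sp"], params["D_hip_sp"],
                s_hip.theta_h, s_hip.theta_h_dot, theta_h_tar, "-",
            )
            s_knee = delayed("VAS")
            u["VAS"] += pd_stimulation(
                params["K_knee_sp"], params["D_knee_sp"],
                s_knee.theta_k, s_knee.theta_k_dot, params["theta_k_sp_tar"], "-",
            )

    return {m: float(np.clip(u[m], u_min, 1.0)) for m in MUSCLES}


def update_phase(
    contact: bool,
    prev_phase: LegPhase | None,
    phase_progress: float,
    params: ParameterVector,
    torso_contact: bool = False,
) -> tuple[LegPhase, bool]:
    """Phase transition for one leg plus the fall flag.

    ``phase_progress`` is the normalized time within the current stance or
    swing period (0 at entry, approaching 1 near the expected transition);
    the registry thresholds split off the late sub-phases.  The fall flag is
    raised when any segment above the knee touches the ground
    (``torso_contact``).
    """
    if not 0.0 <= phase_progress:
        raise ValueError("phase_progress must be non-negative")
    progress = min(phase_progress, 1.0)
    if contact:
        phase = (
            LegPhase.LATE_STANCE
            if progress >= params["late_stance_onset"]
            else LegPhase.STANCE
        )
    else:
        if progress >= params["stance_prep_onset"]:
            phase = LegPhase.STANCE_PREPARATION
        elif progress >= params["late_swing_onset"]:
            phase = LegPhase.LATE_SWING
        else:
            phase = LegPhase.SWING
    return phase, bool(torso_contact)
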