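"""Energy-efficiency analysis: CoT curves, integrated CoT, substitutions.

Efficiency across velocity is summarized by fitting an unweighted quadratic
CoT(v) to (velocity, CoT) samples of steady gaits and integrating it over a
velocity range:

    iCoT = integral_{v_min}^{v_max} CoT(v) dv        (exact antiderivative)

Circuit-substitution experiments build hybrid modulators (base with selected
parameter functions replaced by a donor's), evaluate both over a velocity
grid, drop target velocities whose achieved speed misses the target by more
than 0.05 m/s, and compare iCoT over the common velocity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .cost import TrialTrace
from .modulator import CircuitGroup, Modulator, modulate, substitute_functions
from .pwls import SingularFitError

__all__ = [
    "CotCurve",
    "SubstitutionResult",
    "fit_cot_curve",
    "integrate_cot",
    "relative_icot",
    "evaluate_modulator",
    "substitution_experiment",
    "muscle_energy_breakdown",
]

#: velocity-tracking tolerance for including a target velocity [m/s]
VELOCITY_TOLERANCE = 0.05
#: steady-walking gate: minimum distance without a fall [m]
STEADY_DISTANCE = 30.0


@dataclass(frozen=True)
class CotCurve:
    """Quadratic CoT(v) = c2 v^2 + c1 v + c0 fitted over [v_min, v_max]."""

    c2: float
    c1: float
    c0: float
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.c2, self.c1, self.c0])):
            raise ValueError("CoT curve coefficients must be finite")
        if not self.v_min < self.v_max:
            raise ValueError("fit range must be non-empty")

    def __call__(self, v):
        return self.c2 * np.asarray(v) ** 2 + self.c1 * np.asarray(v) + self.c0


@dataclass
class SubstitutionResult:
    """Outcome of one circuit-substitution comparison."""

    name: str
    baseline_icot: float
    substituted_icot: float | None
    relative_change_pct: float | None
    abs_change_pct: float | None
    excluded_velocities: list[float] = field(default_factory=list)
    computable: bool = True


def fit_cot_curve(v_x: np.ndarray, cot: np.ndarray) -> CotCurve:
    """Unweighted least-squares quadratic through (v_x, CoT) samples."""
    v_x = np.asarray(v_x, dtype=float)
    cot = np.asarray(cot, dtype=float)
    if len(v_x) != len(cot):
        raise ValueError("v_x and cot must share length")
    if len(np.unique(v_x)) < 3:
        raise SingularFitError("need at least 3 distinct velocities for a quadratic")
    c0, c1, c2 = npoly.polyfit(v_x, cot, 2)
    return CotCurve(
        c2=float(c2), c1=float(c1), c0=float(c0),
        v_min=float(v_x.min()), v_max=float(v_x.max()),
    )


def integrate_cot(curve: CotCurve, v_min: float, v_max: float) -> float:
    """Exact antiderivative of the quadratic between the limits."""
    if v_min > v_max:
        raise ValueError("v_min must not exceed v_max")

    def F(v: float) -> float:
        return curve.c2 * v**3 / 3 + curve.c1 * v**2 / 2 + curve.c0 * v

    return F(v_max) - F(v_min)


def relative_icot(test: float, baseline: float) -> float:
    """Percent change of iCoT relative to a baseline: 100 (test - base)/|base|."""
    if baseline == 0:
        raise ValueError("baseline iCoT must be nonzero")
    return 100.0 * (test - baseline) / abs(baseline)


def evaluate_modulator(
    mod: Modulator,
    evaluator: Callable[..., TrialTrace],
    velocity_grid: Sequence[float],
    seeds: Sequence[int],
    mass: float = 80.0,
    gravity: float = 9.81,
) -> pd.DataFrame:
    """Evaluate a modulator at each grid velocity, averaging over seeds.

    Returns one row per target velocity with the mean achieved velocity and
    CoT over replicate seeds, the steady-walking flag (covers more than 30 m
    without falling in every replicate) and the velocity-tracking flag
    (|v_x - v_tar| within 0.05 m/s).
    """
    rows = []
    for v_tar in velocity_grid:
        Y = modulate(mod, v_tar)
        achieved, cots, steady = [], [], True
        for seed in seeds:
            trace = evaluator(Y, v_tar, seed)
            if trace.fell or trace.distance <= STEADY_DISTANCE:
                steady = False
                continue
            achieved.append(trace.mean_velocity)
            cots.append(
                trace.total_energy / (mass * gravity * trace.distance)
            )
        if not achieved:
            rows.append(
                {
                    "v_tar": v_tar, "v_x": np.nan, "cot": np.nan,
                    "steady": False, "tracked": False,
                }
            )
            continue
        v_mean = float(np.mean(achieved))
        rows.append(
            {
                "v_tar": v_tar,
                "v_x": v_mean,
                "cot": float(np.mean(cots)),
                "steady": steady,
                "tracked": abs(v_mean - v_tar) <= VELOCITY_TOLERANCE,
            }
        )
    return pd.DataFrame(rows)


def _icot_from_table(
    table: pd.DataFrame, v_range: tuple[float, float] | None = None
) -> tuple[float | None, CotCurve | None, list[float]]:
    good = table[table["steady"] & table["tracked"]]
    excluded = table.loc[~(table["steady"] & table["tracked"]), "v_tar"].tolist()
    if len(good) < 3 or good["v_x"].nunique() < 3:
        return None, None, excluded
    curve = fit_cot_curve(good["v_x"].to_numpy(), good["cot"].to_numpy())
    lo, hi = (curve.v_min, curve.v_max) if v_range is None else v_range
    return integrate_cot(curve, lo, hi), curve, excluded


def substitution_experiment(
    base: Modulator,
    donor: Modulator,
    groups: Sequence[CircuitGroup],
    evaluator: Callable[..., TrialTrace],
    velocity_grid: Sequence[float],
    seeds: Sequence[int] = (0, 1, 2),
    v_range: tuple[float, float] | None = None,
    mass: float = 80.0,
    gravity: float = 9.81,
) -> list[SubstitutionResult]:
    """Compare iCoT of hybrid modulators against the base modulator.

    For each circuit group the named parameter functions are replaced by the
    donor's, both modulators are evaluated over the grid, target velocities
    with achieved-velocity error above 0.05 m/s (or unsteady gaits) are
    excluded, quadratic CoT curves are fitted to the survivors, and iCoT is
    integrated over a common range (the intersection of the fitted ranges
    unless ``v_range`` fixes it).  Groups with fewer than three surviving
    velocities are flagged non-computable.
    """
    base_table = evaluate_modulator(
        base, evaluator, velocity_grid, seeds, mass, gravity
    )
    results: list[SubstitutionResult] = []
    for group in groups:
        hybrid = substitute_functions(base, donor, group.parameters)
        table = evaluate_modulator(
            hybrid, evaluator, velocity_grid, seeds, mass, gravity
        )
        base_good = base_table[base_table["steady"] & base_table["tracked"]]
        sub_good = table[table["steady"] & table["tracked"]]
        if v_range is None and len(base_good) >= 3 and len(sub_good) >= 3:
            lo = max(base_good["v_x"].min(), sub_good["v_x"].min())
            hi = min(base_good["v_x"].max(), sub_good["v_x"].max())
            common = (float(lo), float(hi))
        else:
            common = v_range
        base_icot, _, _ = _icot_from_table(base_table, common)
        sub_icot, _, excluded = _icot_from_table(table, common)
        if base_icot is None or sub_icot is None:
            results.append(
                SubstitutionResult(
                    name=group.name,
                    baseline_icot=base_icot if base_icot is not None else np.nan,
                    substituted_icot=sub_icot,
                    relative_change_pct=None,
                    abs_change_pct=None,
                    excluded_velocities=excluded,
                    computable=False,
                )
            )
            continue
        rel = relative_icot(sub_icot, base_icot)
        results.append(
            SubstitutionResult(
                name=group.name,
                baseline_icot=base_icot,
                substituted_icot=sub_icot,
                relative_change_pct=rel,
                abs_change_pct=abs(rel),
                excluded_velocities=excluded,
            )
        )
    return results


def muscle_energy_breakdown(
    trace: TrialTrace,
    distance: float = STEADY_DISTANCE,
    baseline: TrialTrace | None = None,
) -> pd.DataFrame:
    """Per-muscle metabolic energy over the first ``distance`` metres.

    If a baseline trace is supplied, a difference column is added (positive
    means more energy than the baseline for that muscle).
    """

    def window_energy(t: TrialTrace) -> np.ndarray:
        cum = t.cumulative_distance()
        if cum[-1] < distance:
            raise ValueError(
                f"trace covers only {cum[-1]:.2f} m, need {distance} m"
            )
        n = int(np.searchsorted(cum, distance)) + 1
        return t.muscle_energy[:n].sum(axis=0)

    energy = window_energy(trace)
    out = pd.DataFrame({"muscle": list(trace.muscle_names), "energy_J": energy})
    if baseline is not None:
        if baseline.muscle_names != trace.muscle_names:
            raise ValueError("traces must share the muscle set")
        out["delta_J"] = energy - window_energy(baseline)
    return out
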