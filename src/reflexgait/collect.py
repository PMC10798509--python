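"""Dataset collection: CMA-ES over an incremental two-thread velocity schedule.

Two sweeps ("threads") start from identical initial parameters: one raises
the target velocity from 1.3 m/s in +0.1 steps to 2.0 m/s, the other lowers
it from 1.2 m/s in -0.1 steps to 0.4 m/s.  At each target velocity the
reflex parameters are optimized for G generations of lambda candidates;
whenever the target changes, the step size is reset to sigma0 and both
evolution paths are emptied while the mean and covariance carry over.  A
candidate whose trial survives to the timestep cap contributes an admitted
record (v_x, Y, CoT); the merged dataset is sorted ascending by achieved
velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import registry
from .cma import CmaEs
from .cost import CostWeights, TrialTrace, cot, trial_cost
from .pwls import GaitDataset, GaitRecord
from .registry import ParameterVector

__all__ = [
    "CollectionSchedule",
    "thread_velocities",
    "schedule_trial_count",
    "velocity_sweep",
]

#: evaluator contract: (Y, v_tar, seed) -> TrialTrace, deterministic per seed
GaitEvaluator = Callable[[ParameterVector, float, int], TrialTrace]


@dataclass(frozen=True)
class CollectionSchedule:
    """Two-thread incremental target-velocity schedule plus CMA-ES sizes."""

    thread_a_start: float = 1.3
    thread_a_end: float = 2.0
    thread_b_start: float = 1.2
    thread_b_end: float = 0.4
    step: float = 0.1
    G: int = 300  # generations per target velocity
    lam: int = 20  # population size
    mu: int = 7  # parents
    sigma0: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.thread_a_end < self.thread_a_start:
            raise ValueError("thread A must be non-decreasing")
        if self.thread_b_end > self.thread_b_start:
            raise ValueError("thread B must be non-increasing")


def thread_velocities(start: float, end: float, step: float) -> list[float]:
    """Arithmetic velocity sequence materialized with integer step counts.

    Computing v_k as start + k*step with an integer k (then rounding to the
    schedule's decimal grid) avoids cumulative floating-point drift.
    """
    n_steps = int(round(abs(end - start) / step))
    sign = 1.0 if end >= start else -1.0
    return [round(start + sign * k * step, 10) for k in range(n_steps + 1)]


def schedule_velocities(schedule: CollectionSchedule) -> tuple[list[float], list[float]]:
    a = thread_velocities(schedule.thread_a_start, schedule.thread_a_end, schedule.step)
    b = thread_velocities(schedule.thread_b_start, schedule.thread_b_end, schedule.step)
    return a, b


def schedule_trial_count(schedule: CollectionSchedule) -> int:
    """Total number of evaluation trials the schedule prescribes."""
    a, b = schedule_velocities(schedule)
    return (len(a) + len(b)) * schedule.G * schedule.lam


def _run_thread(
    velocities: list[float],
    schedule: CollectionSchedule,
    evaluator: GaitEvaluator,
    weights: CostWeights,
    x0_unit: np.ndarray,
    rng: np.random.Generator,
    mass: float,
    gravity: float,
    thread_name: str,
    records: list[GaitRecord],
    log_rows: list[dict],
) -> None:
    es = CmaEs(
        x0=x0_unit,
        sigma0=schedule.sigma0,
        lam=schedule.lam,
        mu=schedule.mu,
        bounds=(np.zeros(registry.N_PARAMS), np.ones(registry.N_PARAMS)),
    )
    for v_tar in velocities:
        es.reset_for_new_velocity(schedule.sigma0)
        for gen in range(schedule.G):
            candidates = es.ask(rng)
            objectives = np.empty(schedule.lam)
            admitted_this_gen = 0
            for k, unit in enumerate(candidates):
                Y = ParameterVector(registry.denormalize(unit))
                trial_seed = int(rng.integers(0, 2**31 - 1))
                try:
                    trace = evaluator(Y, v_tar, trial_seed)
                    objectives[k] = trial_cost(trace, v_tar, weights, mass, gravity)
                except Exception:  # evaluator failure: score worst, continue
                    objectives[k] = np.inf
                    log_rows.append(
                        {
                            "thread": thread_name,
                            "v_tar": v_tar,
                            "generation": gen,
                            "objective": np.inf,
                            "admitted": False,
                        }
                    )
                    continue
                survived = (not trace.fell) and trace.T_prime >= weights.T
                if survived and trace.distance > 0:
                    records.append(
                        GaitRecord(
                            v_x=trace.mean_velocity,
                            Y=Y,
                            cot=cot(
                                trace.total_energy, mass, gravity, trace.distance
                            ),
                        )
                    )
                    admitted_this_gen += 1
                log_rows.append(
                    {
                        "thread": thread_name,
                        "v_tar": v_tar,
                        "generation": gen,
                        "objective": float(objectives[k]),
                        "admitted": bool(survived and trace.distance > 0),
                    }
                )
            es.tell(candidates, objectives)


def velocity_sweep(
    schedule: CollectionSchedule,
    evaluator: GaitEvaluator,
    weights: CostWeights | None = None,
    seed: int = 0,
    mass: float = 80.0,
    gravity: float = 9.81,
    initial: ParameterVector | None = None,
) -> tuple[GaitDataset, pd.DataFrame]:
    """Run both threads and merge their admitted records.

    Returns the velocity-sorted dataset and a per-evaluation log with one
    row per trial (thread, target velocity, generation, objective value,
    admitted flag).  Both threads start from the same initial parameters;
    the merged result is order-independent because the dataset sorts by
    achieved velocity.
    """
    weights = weights or CostWeights()
    initial = initial or ParameterVector.defaults()
    x0_unit = registry.normalize(initial.values)
    vels_a, vels_b = schedule_velocities(schedule)

    records: list[GaitRecord] = []
    log_rows: list[dict] = []
    root = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in root.spawn(2))
    _run_thread(
        vels_a, schedule, evaluator, weights, x0_unit, rng_a,
        mass, gravity, "A", records, log_rows,
    )
    _run_thread(
        vels_b, schedule, evaluator, weights, x0_unit, rng_b,
        mass, gravity, "B", records, log_rows,
    )
    log = pd.DataFrame(
        log_rows,
        columns=["thread", "v_tar", "generation", "objective", "admitted"],
    )
    if records:
        dataset = GaitDataset.from_records(records)
    else:
        dataset = GaitDataset(
            v_x=np.empty(0),
            cot=np.empty(0),
            Y=np.empty((0, registry.N_PARAMS)),
        )
    return dataset, log
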