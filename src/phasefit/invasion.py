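"""Deterministic invasion of a deposit-forming variant into a population.

A single mutant cell whose protein phase-separates appears among 10^6
wild-type cells.  Both strains grow exponentially; each environment
assigns them doubling times, and the mutant's doubling time is derived
from the measured selection coefficient S and the wild-type doubling
time tau_sol:

    1/tau_agg = 1/tau_sol + S/ln2

Cell counts are integrated in natural-log space with a forward Euler
scheme,

    ln N(t) = ln N(t - dt) + dt * ln2 / tau,

which for a constant tau is exact for any step size (the update is
linear in ln N).  Under a schedule of alternating environments the
doubling times are re-assigned at each switch (default every 12 h); the
long-run outcome is governed by the time-weighted mean selection
coefficient over the schedule (the history coefficient S_h).

Time is reported both in hours and in wild-type generations, using the
30 degC wild-type doubling time of 2.7 h as the reference generation
regardless of the simulated environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EnvironmentCondition

__all__ = [
    "TAU_REF_H",
    "tau_from_selection",
    "EnvironmentSchedule",
    "PopulationTrajectory",
    "simulate_population",
    "time_to_dominance",
    "history_selection_coefficient",
    "pairwise_history_grid",
]

LN2 = math.log(2.0)

#: reference generation time: wild type at 30 degC, hours
TAU_REF_H = 2.7


def tau_from_selection(S: float, tau_sol: float) -> float:
    """Doubling time of the variant implied by S and the wild-type tau.

    Inverts S = ln2 * (1/tau_agg - 1/tau_sol).  Raises when the implied
    growth rate is non-positive (the variant cannot be simulated as an
    exponential grower).
    """
    if tau_sol <= 0:
        raise ValueError("tau_sol must be > 0")
    omega_agg = 1.0 / tau_sol + S / LN2
    if omega_agg <= 0:
        raise ValueError(
            f"S={S} with tau_sol={tau_sol} implies a non-positive growth rate"
        )
    return 1.0 / omega_agg


@dataclass
class EnvironmentSchedule:
    """Ordered environments with dwell times, defining a growth history.

    ``segments`` is a list of ``(EnvironmentCondition, duration_h)``
    pairs; every referenced environment must have both S and tau_sol
    set.  Use :meth:`alternating` for the canonical two-environment
    periodic switch (default period 12 h).
    """

    segments: list

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for env, dur in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if env.S is None:
                raise ValueError(f"environment {env.label!r} has no S set")
            if env.tau_sol is None or env.tau_sol <= 0:
                raise ValueError(f"environment {env.label!r} has no valid tau_sol")

    @classmethod
    def constant(cls, env: EnvironmentCondition, duration_h: float) -> "EnvironmentSchedule":
        return cls([(env, duration_h)])

    @classmethod
    def alternating(cls, env1: EnvironmentCondition, env2: EnvironmentCondition,
                    period_h: float = 12.0, total_h: float = 1000.0) -> "EnvironmentSchedule":
        """Strict alternation env1/env2 every ``period_h`` for ``total_h`` hours."""
        if period_h <= 0 or total_h <= 0:
            raise ValueError("period and total duration must be > 0")
        segments = []
        t = 0.0
        envs = (env1, env2)
        i = 0
        while t < total_h - 1e-9:
            dur = min(period_h, total_h - t)
            segments.append((envs[i % 2], dur))
            t += dur
            i += 1
        return cls(segments)

    @property
    def total_h(self) -> float:
        return float(sum(dur for _, dur in self.segments))


@dataclass
class PopulationTrajectory:
    """Euler trajectory of both strains in natural-log cell counts."""

    times: np.ndarray
    ln_n_agg: np.ndarray
    ln_n_sol: np.ndarray
    tau_ref: float = TAU_REF_H

    @property
    def fraction(self) -> np.ndarray:
        """Mutant fraction N_agg/(N_agg+N_sol), computed in log space."""
        # fraction = 1 / (1 + exp(ln_sol - ln_agg)); stable for huge counts
        return 1.0 / (1.0 + np.exp(self.ln_n_sol - self.ln_n_agg))

    @property
    def generations(self) -> np.ndarray:
        """Elapsed time in wild-type reference generations (tau_ref)."""
        return self.times / self.tau_ref

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "generations": self.generations,
                "ln_n_agg": self.ln_n_agg,
                "ln_n_sol": self.ln_n_sol,
                "fraction": self.fraction,
            }
        )


def simulate_population(
    schedule: EnvironmentSchedule,
    init_agg: float = 1.0,
    init_sol: float = 1e6,
    dt_minutes: float = 60.0,
) -> PopulationTrajectory:
    """Integrate both strains through a schedule of environments.

    Forward Euler in natural-log space with step ``dt_minutes``
    (default 60 min).  Environment switch times must land on the step
    grid — a 12-h switch with a 60-min step does; misaligned schedules
    are rejected so no segment is silently truncated.
    """
    if dt_minutes <= 0:
        raise ValueError("dt must be > 0")
    if init_agg < 1 or init_sol < 1:
        raise ValueError("initial counts must be >= 1 cell")
    dt_h = dt_minutes / 60.0
    for env, dur in schedule.segments:
        steps = dur / dt_h
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"segment of {dur} h in {env.label!r} is not a whole number of "
                f"{dt_minutes}-min steps; align switch times to the step grid"
            )

    n_total = int(round(schedule.total_h / dt_h))
    times = np.empty(n_total + 1)
    ln_agg = np.empty(n_total + 1)
    ln_sol = np.empty(n_total + 1)
    times[0] = 0.0
    ln_agg[0] = math.log(init_agg)
    ln_sol[0] = math.log(init_sol)

    k = 0
    t = 0.0
    for env, dur in schedule.segments:
        tau_agg = tau_from_selection(env.S, env.tau_sol)
        inc_agg = dt_h * LN2 / tau_agg
        inc_sol = dt_h * LN2 / env.tau_sol
        for _ in range(int(round(dur / dt_h))):
            k += 1
            t += dt_h
            times[k] = t
            ln_agg[k] = ln_agg[k - 1] + inc_agg
            ln_sol[k] = ln_sol[k - 1] + inc_sol
    return PopulationTrajectory(times=times, ln_n_agg=ln_agg, ln_n_sol=ln_sol)


def time_to_dominance(traj: PopulationTrajectory, threshold: float = 0.5):
    """Wild-type generations until the mutant fraction first reaches ``threshold``.

    Read off the simulated grid (first step with fraction >= threshold,
    no interpolation).  Returns ``None`` when the threshold is never
    reached within the trajectory — a distinguished outcome, not an
    error.
    """
    frac = traj.fraction
    hits = np.nonzero(frac >= threshold)[0]
    if hits.size == 0:
        return None
    return float(traj.times[hits[0]] / traj.tau_ref)


def history_selection_coefficient(schedule: EnvironmentSchedule) -> float:
    """Time-weighted mean selection coefficient S_h over a schedule.

    Over any whole pass through the schedule the log abundance ratio
    changes by exactly S_h times the elapsed time, so the sign of S_h
    decides whether the variant ultimately invades.
    """
    total = schedule.total_h
    return float(sum(env.S * dur for env, dur in schedule.segments) / total)


def pairwise_history_grid(envs: "list[EnvironmentCondition]",
                          period_h: float = 12.0) -> pd.DataFrame:
    """S_h for equal-time alternation of every environment pair.

    Returns a symmetric labelled matrix; the diagonal is each
    environment's own S.  With equal dwell times the entry reduces to
    (S_i + S_j)/2, independent of the period.
    """
    if len(envs) < 2:
        raise ValueError("need >= 2 environments for a pairwise grid")
    labels = [e.label for e in envs]
    if len(set(labels)) != len(labels):
        raise ValueError("environment labels must be unique")
    n = len(envs)
    grid = np.empty((n, n))
    for i, ei in enumerate(envs):
        for j, ej in enumerate(envs):
            if i == j:
                grid[i, j] = ei.S
            else:
                sched = EnvironmentSchedule.alternating(
                    ei, ej, period_h=period_h, total_h=2 * period_h)
                grid[i, j] = history_selection_coefficient(sched)
    return pd.DataFrame(grid, index=labels, columns=labels)
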