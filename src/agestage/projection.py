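"""Deterministic age-stage population projection with bootstrap bands.

The projection propagates expected mass (fractional individuals) through
the empirical daily transition model: each day, occupants of an
(age, stage) cell split into next-day cells or death, and the eggs laid
by adult females enter the youngest cell the following day.  The total
across all cells is the population size N(t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .cohort_io import CohortTable
from .lifetable import (FecunditySchedule, TransitionModel,
                        compute_age_stage_survival, compute_fecundity,
                        fit_transition_model)

__all__ = [
    "ProjectionSeries",
    "ProjectionBand",
    "project_population",
    "projection_band",
    "count_generations",
]

DEFAULT_EGGS = 10.0
DEFAULT_DAYS = 120


@dataclass
class ProjectionSeries:
    """Daily census of a projected population.

    ``N[t]`` is the total over all age-stage cells; ``stage_totals[t, j]``
    the per-stage totals; ``births``/``deaths`` the per-day flows (births
    at index t are the eggs appearing at day t; both are 0 at t = 0).
    """

    N: np.ndarray              # (days + 1,)
    stage_totals: np.ndarray   # (days + 1, beta)
    births: np.ndarray         # (days + 1,)
    deaths: np.ndarray         # (days + 1,)
    retired: float             # mass dropped for lack of transition data
    stages: tuple[str, ...]


@dataclass
class ProjectionBand:
    """Pointwise mean and 95% percentile band over bootstrap projections."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    point: np.ndarray          # projection of the original cohort
    level: float = 0.95


def project_population(tm: TransitionModel, fs: FecunditySchedule,
                       initial_eggs: float = DEFAULT_EGGS,
                       days: int = DEFAULT_DAYS, *,
                       female_stage_index: int | None = None) -> ProjectionSeries:
    """Expected-value projection from an initial egg cohort.

    Newly laid eggs enter the (0, egg) cell the following day.  Mass in a
    cell with no transition data (unobserved in the source cohort) is
    retired with a warning.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    omega = tm.die.shape[0] - 1
    beta = tm.die.shape[1]
    if female_stage_index is None:
        female_stage_index = beta - 2  # FAW-style schema: ADULT_F then ADULT_M
        for j, s in enumerate(tm.stages):
            if s == "ADULT_F":
                female_stage_index = j
    mass = np.zeros((omega + 1, beta))
    mass[0, 0] = initial_eggs

    N = np.zeros(days + 1)
    stage_totals = np.zeros((days + 1, beta))
    births = np.zeros(days + 1)
    deaths = np.zeros(days + 1)
    retired_total = 0.0

    N[0] = mass.sum()
    stage_totals[0] = mass.sum(axis=0)
    for t in range(1, days + 1):
        new_eggs = float((mass[:, female_stage_index]
                          * fs.f[:, female_stage_index]).sum())
        # per-row transition; unobserved rows have all-zero advance + die,
        # so any mass there is silently lost unless we account for it
        nxt = np.zeros_like(mass)
        nxt[1:] = np.einsum("xj,xjy->xy", mass[:-1], tm.advance[:-1])
        dead = float((mass * tm.die).sum())
        lost = float(mass.sum()) - float(nxt.sum()) - dead
        if lost > 1e-9 * max(float(mass.sum()), 1.0):
            retired_total += lost
        nxt[0, 0] = new_eggs
        mass = nxt
        births[t] = new_eggs
        deaths[t] = dead
        N[t] = mass.sum()
        stage_totals[t] = mass.sum(axis=0)
    if retired_total > 1e-9:
        warnings.warn(
            f"{retired_total:.6g} individuals retired in cells without "
            "transition data", RuntimeWarning, stacklevel=2)
    return ProjectionSeries(N=N, stage_totals=stage_totals, births=births,
                            deaths=deaths, retired=retired_total,
                            stages=tuple(tm.stages))


def project_cohort(cohort: CohortTable, initial_eggs: float = DEFAULT_EGGS,
                   days: int = DEFAULT_DAYS) -> ProjectionSeries:
    """Fit the transition model and fecundity schedule, then project."""
    surv = compute_age_stage_survival(cohort)
    fs = compute_fecundity(cohort, surv)
    tm = fit_transition_model(cohort)
    jf = cohort.schema.index(cohort.schema.female_stage)
    return project_population(tm, fs, initial_eggs, days,
                              female_stage_index=jf)


def project_population_stochastic(tm: TransitionModel, fs: FecunditySchedule,
                                  initial_eggs: int, days: int,
                                  rng: np.random.Generator, *,
                                  female_stage_index: int) -> ProjectionSeries:
    """Individual-based variant: multinomial transitions, Poisson egg laying.

    Used to cross-validate the deterministic projection; not the default.
    """
    omega = tm.die.shape[0] - 1
    beta = tm.die.shape[1]
    mass = np.zeros((omega + 1, beta), dtype=np.int64)
    mass[0, 0] = int(initial_eggs)
    N = np.zeros(days + 1)
    stage_totals = np.zeros((days + 1, beta))
    births = np.zeros(days + 1)
    deaths = np.zeros(days + 1)
    N[0] = mass.sum()
    stage_totals[0] = mass.sum(axis=0)
    for t in range(1, days + 1):
        lam = float((mass[:, female_stage_index]
                     * fs.f[:, female_stage_index]).sum())
        new_eggs = int(rng.poisson(lam)) if lam > 0 else 0
        nxt = np.zeros_like(mass)
        dead = 0
        for x in range(omega):
            for j in range(beta):
                k = int(mass[x, j])
                if k == 0:
                    continue
                probs = np.append(tm.advance[x, j], tm.die[x, j])
                tot = probs.sum()
                if tot <= 0:
                    dead += k
                    continue
                outcome = rng.multinomial(k, probs / tot)
                nxt[x + 1] += outcome[:beta]
                dead += int(outcome[beta])
        dead += int(mass[omega].sum())
        nxt[0, 0] = new_eggs
        mass = nxt
        births[t] = new_eggs
        deaths[t] = dead
        N[t] = mass.sum()
        stage_totals[t] = mass.sum(axis=0)
    return ProjectionSeries(N=N, stage_totals=stage_totals, births=births,
                            deaths=deaths, retired=0.0, stages=tuple(tm.stages))


def projection_band(cohort: CohortTable, initial_eggs: float = DEFAULT_EGGS,
                    days: int = DEFAULT_DAYS, B: int = 200,
                    seed: int | None = None,
                    level: float = 0.95) -> ProjectionBand:
    """Percentile band of N(t) over bootstrap resamples of the cohort."""
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    point = project_cohort(cohort, initial_eggs, days).N
    curves = np.empty((B, days + 1))
    n = cohort.n
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        resampled = CohortTable(
            schema=cohort.schema,
            individuals=[cohort.individuals[i] for i in idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curves[b] = project_cohort(resampled, initial_eggs, days).N
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(curves, [100 * alpha, 100 * (1 - alpha)],
                                 axis=0)
    return ProjectionBand(mean=curves.mean(axis=0), lower=lower, upper=upper,
                          point=point, level=level)


def count_generations(series: ProjectionSeries,
                      prominence_frac: float = 0.05) -> int:
    """Number of egg-influx waves within the horizon.

    Generations are delimited by local minima of the daily egg influx;
    a wave is a peak with prominence above ``prominence_frac`` of the
    maximum influx (log scale would exaggerate late waves under growth).
    """
    b = series.births
    if b.max() <= 0:
        return 0
    # normalise out exponential growth so successive waves are comparable
    t = np.arange(len(b))
    pos = b > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(b[pos]), 1)[0]
        detrended = b / np.exp(slope * t)
    else:
        detrended = b
    peaks, _ = find_peaks(detrended, prominence=prominence_frac * detrended.max())
    return int(len(peaks))
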