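"""Age-stage, two-sex life table schedules and demographic parameters.

All ages are day counts from oviposition (age 0); one census per day.
Reproduction is credited at the end of the day, so discounted sums use
exponent ``x + 1`` — the convention under which a schedule concentrated
at age 0 with unit net maternity yields an intrinsic rate of exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .cohort_io import CohortTable

__all__ = [
    "AgeStageSurvival",
    "SurvivalCurve",
    "FecunditySchedule",
    "TransitionModel",
    "LifeExpectancyMatrix",
    "ReproductiveValueMatrix",
    "DemographicParams",
    "SummaryStats",
    "compute_age_stage_survival",
    "compute_lx",
    "compute_fecundity",
    "net_reproductive_rate",
    "two_sex_r0_identity",
    "solve_intrinsic_rate",
    "solve_intrinsic_rate_many",
    "derived_rates",
    "fit_transition_model",
    "life_expectancy",
    "reproductive_value",
    "summarize_cohort",
    "analyze_cohort",
]


# ---------------------------------------------------------------------------
# schedule containers

@dataclass
class AgeStageSurvival:
    """Probability ``s[x, j]`` that a newborn is alive in stage j at age x.

    ``counts[x, j]`` holds the raw number of individuals observed there;
    ``s = counts / n``.
    """

    s: np.ndarray          # (omega + 1, beta)
    counts: np.ndarray     # (omega + 1, beta) ints
    n: int
    stages: tuple[str, ...]

    @property
    def omega(self) -> int:
        return self.s.shape[0] - 1


@dataclass
class SurvivalCurve:
    l: np.ndarray          # (omega + 1,)


@dataclass
class FecunditySchedule:
    """Per-stage mean eggs ``f[x, j]``, pooled ``m_x``, and ``l_x * m_x``."""

    f: np.ndarray              # (omega + 1, beta)
    m: np.ndarray              # (omega + 1,)
    net_maternity: np.ndarray  # (omega + 1,)


@dataclass
class TransitionModel:
    """Empirical daily age-stage transition probabilities.

    ``advance[x, j, y]`` is the fraction of individuals observed in
    (x, j) that were in stage y at age x + 1 (y == j means staying put);
    ``die[x, j]`` the fraction dead the next day.  Rows with no
    occupants are all-zero and flagged in ``observed``.
    """

    advance: np.ndarray    # (omega + 1, beta, beta)
    die: np.ndarray        # (omega + 1, beta)
    observed: np.ndarray   # (omega + 1, beta) bool
    stages: tuple[str, ...]

    def stay(self, x: int, j: int) -> float:
        return float(self.advance[x, j, j])


@dataclass
class LifeExpectancyMatrix:
    e: np.ndarray          # (omega + 1, beta); NaN where unobserved


@dataclass
class ReproductiveValueMatrix:
    v: np.ndarray          # (omega + 1, beta); NaN where unobserved


@dataclass
class DemographicParams:
    """Population growth parameters.

    R0 — expected offspring per newborn; r — intrinsic rate of increase
    (d^-1); lam — finite rate of increase, e^r; T — mean generation time,
    ln(R0)/r.  r, lam and T are NaN when the cohort has no reproduction.
    """

    R0: float
    r: float
    lam: float
    T: float


@dataclass
class StageDuration:
    n: int
    mean: float
    se: float


@dataclass
class SummaryStats:
    stage_durations: dict[str, StageDuration]
    preadult_duration: StageDuration
    female_longevity: StageDuration
    male_longevity: StageDuration
    total_longevity: StageDuration
    apop: StageDuration
    tpop: StageDuration
    oviposition_days: StageDuration
    fecundity: StageDuration
    n: int = 0
    n_female: int = 0
    n_fertile_female: int = 0
    n_male: int = 0
    prop_female: float = math.nan        # N_f / N
    prop_fertile: float = math.nan       # N_fr / N_f
    prop_male: float = math.nan          # N_m / N
    supernumerary_prop: float = math.nan


# ---------------------------------------------------------------------------
# helpers

def _stage_index_matrix(cohort: CohortTable) -> np.ndarray:
    """(n, omega+1) matrix of stage indices; -1 where dead."""
    omega = cohort.omega
    beta_idx = np.full((cohort.n, omega + 1), -1, dtype=np.int64)
    schema = cohort.schema
    lut = {s: j for j, s in enumerate(schema.stages)}
    for i, ind in enumerate(cohort.individuals):
        for age, stage in ind.history:
            beta_idx[i, age] = lut[stage]
    return beta_idx


def _egg_matrix(cohort: CohortTable) -> np.ndarray:
    omega = cohort.omega
    eggs = np.zeros((cohort.n, omega + 1))
    for i, ind in enumerate(cohort.individuals):
        for age, e in ind.daily_eggs.items():
            eggs[i, age] = e
    return eggs


def _mean_se(values) -> StageDuration:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    k = v.size
    if k == 0:
        return StageDuration(0, math.nan, math.nan)
    mean = float(v.mean())
    se = float(v.std(ddof=1) / math.sqrt(k)) if k > 1 else 0.0
    return StageDuration(k, mean, se)


# ---------------------------------------------------------------------------
# schedules

def compute_age_stage_survival(cohort: CohortTable) -> AgeStageSurvival:
    """Count individuals per (age, stage) cell and normalise by cohort size."""
    if cohort.n == 0:
        raise ValueError("empty cohort")
    beta = cohort.schema.beta
    omega = cohort.omega
    idx = _stage_index_matrix(cohort)
    counts = np.zeros((omega + 1, beta), dtype=np.int64)
    for x in range(omega + 1):
        col = idx[:, x]
        alive = col >= 0
        np.add.at(counts[x], col[alive], 1)
    return AgeStageSurvival(
        s=counts / cohort.n, counts=counts, n=cohort.n,
        stages=tuple(cohort.schema.stages))


def compute_lx(survival: AgeStageSurvival) -> SurvivalCurve:
    """Age-specific survival: row sums of the age-stage matrix."""
    return SurvivalCurve(l=survival.s.sum(axis=1))


def compute_fecundity(cohort: CohortTable, survival: AgeStageSurvival) -> FecunditySchedule:
    """Per-stage fecundity f[x, j], pooled m_x and net maternity l_x m_x."""
    beta = cohort.schema.beta
    omega = survival.omega
    jf = cohort.schema.index(cohort.schema.female_stage)
    eggs = _egg_matrix(cohort)           # (n, omega+1)
    total_by_age = eggs.sum(axis=0)      # all eggs are ADULT_F days (validated)
    f = np.zeros((omega + 1, beta))
    nf = survival.counts[:, jf].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f[:, jf] = np.where(nf > 0, total_by_age / np.where(nf > 0, nf, 1), 0.0)
    l = survival.s.sum(axis=1)
    sf = (survival.s * f).sum(axis=1)    # = total eggs at age x / n
    m = np.where(l > 0, sf / np.where(l > 0, l, 1), 0.0)
    return FecunditySchedule(f=f, m=m, net_maternity=l * m)


def net_reproductive_rate(fs: FecunditySchedule) -> float:
    """R0 = sum of net maternity over all ages."""
    return float(fs.net_maternity.sum())


def two_sex_r0_identity(mean_fecundity: float, n_female: int, n: int) -> float:
    """R0 via the exact identity R0 = (N_f / N) * mean fecundity per female."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    return mean_fecundity * n_female / n


# ---------------------------------------------------------------------------
# growth rates

def _lotka_log_lhs(r: float, phi: np.ndarray, log_phi: np.ndarray,
                   ages1: np.ndarray) -> float:
    # log of sum_x exp(-r (x+1)) phi_x, overflow-safe
    return float(logsumexp(-r * ages1 + log_phi))


def solve_intrinsic_rate(sc: SurvivalCurve, fs: FecunditySchedule, *,
                         tol: float = 1e-12) -> float:
    """Solve sum_x exp(-r (x+1)) l_x m_x = 1 for the unique root r.

    The left-hand side is strictly decreasing in r, so the root is
    bracketed and unique.  Residual at the returned root is < 1e-10.
    """
    phi = np.asarray(fs.net_maternity, dtype=float)
    mask = phi > 0
    if not mask.any():
        raise ValueError("no reproduction: intrinsic rate undefined")
    ages1 = np.nonzero(mask)[0] + 1.0
    log_phi = np.log(phi[mask])

    def g(r: float) -> float:
        return _lotka_log_lhs(r, phi, log_phi, ages1)

    lo, hi = -1.0, 2.0
    for _ in range(80):
        if g(lo) > 0:
            break
        lo *= 2
    else:  # pragma: no cover - pathological schedule
        raise ValueError("could not bracket intrinsic rate from below")
    for _ in range(80):
        if g(hi) < 0:
            break
        hi *= 2
    else:  # pragma: no cover
        raise ValueError("could not bracket intrinsic rate from above")
    r = brentq(g, lo, hi, xtol=tol, rtol=8.9e-16, maxiter=200)
    residual = abs(math.exp(g(r)) - 1.0)
    if residual >= 1e-10:  # pragma: no cover - brentq at machine precision
        raise ArithmeticError(f"Euler-Lotka residual {residual:.3e} at r={r}")
    return float(r)


def solve_intrinsic_rate_many(maternity: np.ndarray, *, iters: int = 120) -> np.ndarray:
    """Vectorised bisection for many net-maternity schedules at once.

    ``maternity`` is (B, A); rows with zero total reproduction yield NaN.
    Used by the bootstrap, where one scalar solve per resample would
    dominate the runtime.
    """
    phi = np.asarray(maternity, dtype=float)
    B, A = phi.shape
    ages1 = np.arange(1, A + 1, dtype=float)
    with np.errstate(divide="ignore"):
        log_phi = np.where(phi > 0, np.log(np.where(phi > 0, phi, 1.0)), -np.inf)
    ok = (phi > 0).any(axis=1)

    def g(r: np.ndarray) -> np.ndarray:
        z = -r[:, None] * ages1[None, :] + log_phi
        return logsumexp(z, axis=1)

    lo = np.full(B, -1.0)
    hi = np.full(B, 2.0)
    for _ in range(60):
        bad = ok & (g(lo) <= 0)
        if not bad.any():
            break
        lo[bad] *= 2
    for _ in range(60):
        bad = ok & (g(hi) >= 0)
        if not bad.any():
            break
        hi[bad] *= 2
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        high = g(mid) > 0
        lo = np.where(high, mid, lo)
        hi = np.where(high, hi, mid)
    r = 0.5 * (lo + hi)
    return np.where(ok, r, np.nan)


def derived_rates(R0: float, r: float) -> tuple[float, float]:
    """Finite rate lam = e^r and mean generation time T = ln(R0)/r.

    T is NaN when R0 <= 0 or r == 0.
    """
    lam = math.exp(r)
    if R0 > 0 and r != 0 and not math.isnan(r):
        T = math.log(R0) / r
    else:
        T = math.nan
    return lam, T


# ---------------------------------------------------------------------------
# transition-based quantities

def fit_transition_model(cohort: CohortTable) -> TransitionModel:
    """Empirical daily transition fractions per occupied (age, stage) cell."""
    beta = cohort.schema.beta
    omega = cohort.omega
    idx = _stage_index_matrix(cohort)
    advance = np.zeros((omega + 1, beta, beta))
    die = np.zeros((omega + 1, beta))
    observed = np.zeros((omega + 1, beta), dtype=bool)
    counts = np.zeros((omega + 1, beta))
    for x in range(omega + 1):
        here = idx[:, x]
        nxt = idx[:, x + 1] if x + 1 <= omega else np.full(cohort.n, -1)
        for j in range(beta):
            sel = here == j
            m = int(sel.sum())
            if m == 0:
                continue
            observed[x, j] = True
            counts[x, j] = m
            to = nxt[sel]
            die[x, j] = float((to < 0).sum()) / m
            alive_to = to[to >= 0]
            if alive_to.size:
                np.add.at(advance[x, j], alive_to, 1.0 / m)
    return TransitionModel(advance=advance, die=die, observed=observed,
                           stages=tuple(cohort.schema.stages))


def _propagate(tm: TransitionModel, x0: int, j0: int):
    """Yield (age, mass-vector over stages) starting with unit mass at (x0, j0)."""
    omega = tm.die.shape[0] - 1
    beta = tm.die.shape[1]
    mass = np.zeros(beta)
    mass[j0] = 1.0
    x = x0
    while x <= omega and mass.sum() > 0:
        yield x, mass
        if x == omega:
            break
        mass = mass @ tm.advance[x]
        x += 1


def life_expectancy(tm: TransitionModel) -> LifeExpectancyMatrix:
    """Expected remaining days (including the current one) for every cell.

    Computed by one backward pass over ages: e[x] = 1 + advance[x] @ e[x+1].
    Equivalent to summing all surviving mass of a forward propagation.
    """
    omega = tm.die.shape[0] - 1
    beta = tm.die.shape[1]
    e = np.full((omega + 1, beta), np.nan)
    nxt = np.zeros(beta)
    for x in range(omega, -1, -1):
        cur = 1.0 + tm.advance[x] @ nxt
        e[x] = np.where(tm.observed[x], cur, np.nan)
        # unobserved cells receive no mass from observed ones, so their
        # placeholder values never contribute upstream
        nxt = cur
    return LifeExpectancyMatrix(e=e)


def reproductive_value(tm: TransitionModel, fs: FecunditySchedule,
                       survival: AgeStageSurvival, r: float) -> ReproductiveValueMatrix:
    """Expected discounted future offspring per occupant of each cell.

    v[x, j] = e^{r(x+1)} * sum_{i >= x} e^{-r(i+1)} sum_y s'_{iy} f_{iy},
    with s' the forward propagation that starts at unit mass in (x, j).
    Computed by a backward pass: w[x] = f[x] + e^{-r} advance[x] @ w[x+1],
    then v[x, j] = w[x, j].
    """
    omega = tm.die.shape[0] - 1
    beta = tm.die.shape[1]
    disc = math.exp(-r)
    v = np.full((omega + 1, beta), np.nan)
    nxt = np.zeros(beta)
    for x in range(omega, -1, -1):
        cur = fs.f[x] + disc * (tm.advance[x] @ nxt)
        v[x] = np.where(tm.observed[x], cur, np.nan)
        nxt = cur
    return ReproductiveValueMatrix(v=v)


# ---------------------------------------------------------------------------
# cohort summary

def summarize_cohort(cohort: CohortTable) -> SummaryStats:
    """Developmental, reproductive and sex-composition summary of a cohort.

    Stage-duration means cover only individuals completing the stage
    (advancing out of it alive); adult "durations" are adult longevities.
    APOP = first-egg age minus adult-emergence age; TPOP = first-egg age.
    """
    schema = cohort.schema
    jf_label = schema.female_stage
    adult_labels = set(schema.adult_stages)
    pupa_idx = schema.index("PUPA") if "PUPA" in schema.stages else None
    # larval stages sit strictly between egg and pupa; an individual with
    # more than the obligatory count is supernumerary
    if pupa_idx is not None:
        n_instars_obligatory = (pupa_idx - 1) - len(schema.optional_stages)
    else:
        n_instars_obligatory = 0

    durations: dict[str, list[float]] = {s: [] for s in schema.stages}
    preadult, female_lon, male_lon, total_lon = [], [], [], []
    apop, tpop, ovi_days, fecundity = [], [], [], []
    n_female = n_male = n_fertile = 0
    n_completed_larval = 0
    n_supernumerary = 0

    for ind in cohort.individuals:
        total_lon.append(ind.death_age)
        stages_seen: dict[str, int] = {}
        for _, stage in ind.history:
            stages_seen[stage] = stages_seen.get(stage, 0) + 1
        seq = [s for s, _ in _runs(ind.history)]
        last_stage = seq[-1]
        # completed a stage iff a later stage follows it in the sequence
        for k, stage in enumerate(seq):
            completed = k < len(seq) - 1
            if stage in adult_labels:
                durations[stage].append(stages_seen[stage])
            elif completed:
                durations[stage].append(stages_seen[stage])
        adult_age = _first_age_in(ind, adult_labels)
        if adult_age is not None:
            preadult.append(adult_age)
        if last_stage == jf_label:
            n_female += 1
            female_lon.append(stages_seen[jf_label])
            fecundity.append(ind.total_eggs())
            first_egg = ind.first_egg_age()
            if first_egg is not None:
                n_fertile += 1
                apop.append(first_egg - adult_age)
                tpop.append(first_egg)
                ovi_days.append(sum(1 for e in ind.daily_eggs.values() if e > 0))
        elif last_stage in adult_labels:
            n_male += 1
            male_lon.append(stages_seen[last_stage])
        if pupa_idx is not None and any(schema.index(s) >= pupa_idx for s in seq):
            n_completed_larval += 1
            n_larval = sum(1 for s in seq if 0 < schema.index(s) < pupa_idx)
            if n_larval > n_instars_obligatory:
                n_supernumerary += 1

    n = cohort.n
    return SummaryStats(
        stage_durations={s: _mean_se(d) for s, d in durations.items()},
        preadult_duration=_mean_se(preadult),
        female_longevity=_mean_se(female_lon),
        male_longevity=_mean_se(male_lon),
        total_longevity=_mean_se(total_lon),
        apop=_mean_se(apop),
        tpop=_mean_se(tpop),
        oviposition_days=_mean_se(ovi_days),
        fecundity=_mean_se(fecundity),
        n=n,
        n_female=n_female,
        n_fertile_female=n_fertile,
        n_male=n_male,
        prop_female=n_female / n,
        prop_fertile=(n_fertile / n_female) if n_female else math.nan,
        prop_male=n_male / n,
        supernumerary_prop=(n_supernumerary / n_completed_larval)
        if n_completed_larval else math.nan,
    )


def _runs(history: list[tuple[int, str]]):
    """Collapse a daily history into (stage, run-length) runs."""
    out = []
    for _, stage in history:
        if out and out[-1][0] == stage:
            out[-1][1] += 1
        else:
            out.append([stage, 1])
    return [(s, k) for s, k in out]


def _first_age_in(ind, labels: set[str]) -> int | None:
    for age, stage in ind.history:
        if stage in labels:
            return age
    return None


# ---------------------------------------------------------------------------
# one-call pipeline

@dataclass
class LifeTableResult:
    survival: AgeStageSurvival
    lx: SurvivalCurve
    fecundity: FecunditySchedule
    transitions: TransitionModel
    life_expectancy: LifeExpectancyMatrix
    reproductive_value: ReproductiveValueMatrix | None
    params: DemographicParams
    summary: SummaryStats


def analyze_cohort(cohort: CohortTable) -> LifeTableResult:
    """Run the full life-table pipeline on one cohort."""
    surv = compute_age_stage_survival(cohort)
    lx = compute_lx(surv)
    fs = compute_fecundity(cohort, surv)
    tm = fit_transition_model(cohort)
    R0 = net_reproductive_rate(fs)
    if R0 > 0:
        r = solve_intrinsic_rate(lx, fs)
        lam, T = derived_rates(R0, r)
        rv = reproductive_value(tm, fs, surv, r)
    else:
        r = lam = T = math.nan
        rv = None
    return LifeTableResult(
        survival=surv, lx=lx, fecundity=fs, transitions=tm,
        life_expectancy=life_expectancy(tm), reproductive_value=rv,
        params=DemographicParams(R0=R0, r=r, lam=lam, T=T),
        summary=summarize_cohort(cohort))
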