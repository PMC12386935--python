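"""Synthetic daily-record cohorts with known ground truth.

Generates individual life histories with the structure of a laboratory
rearing study: discretized-gamma stage durations, geometric within-stage
daily mortality, optional supernumerary instars, sex assigned at adult
emergence, and a unimodal daily egg-allocation curve.  Because every
surviving female lays her full sampled egg total, the net reproductive
rate of the configured process has the exact product form

    R0 = sex_ratio * pre-adult survival * mean total fecundity

which :func:`ground_truth` evaluates analytically, together with the
true intrinsic rate obtained from the expected (not sampled) schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

from .cohort_io import (CohortTable, IndividualRecord, StageSchema, FAW_SCHEMA,
                        FEMALE, MALE, UNKNOWN)
from .lifetable import SurvivalCurve, FecunditySchedule, solve_intrinsic_rate

__all__ = [
    "DurationDist",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "ground_truth",
    "preset",
    "PRESETS",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class DurationDist:
    """Discretized gamma duration: sample, round to nearest day, floor at 1.

    ``cv`` is the coefficient of variation; ``cv = 0`` gives the
    deterministic duration ``max(1, round(mean))``.
    """

    mean: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("duration mean must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    def sample(self, rng: np.random.Generator) -> int:
        if self.cv == 0:
            return max(1, round(self.mean))
        shape = 1.0 / self.cv**2
        scale = self.mean * self.cv**2
        return max(1, round(float(rng.gamma(shape, scale))))

    def pmf(self, tail: float = 1e-10) -> dict[int, float]:
        """Exact pmf of the discretized duration (truncated far tail)."""
        if self.cv == 0:
            return {max(1, round(self.mean)): 1.0}
        shape = 1.0 / self.cv**2
        scale = self.mean * self.cv**2
        dist = stats.gamma(shape, scale=scale)
        hi = int(math.ceil(dist.ppf(1 - tail))) + 2
        out: dict[int, float] = {}
        prev = 0.0
        for d in range(1, hi + 1):
            cdf = float(dist.cdf(d + 0.5))
            out[d] = cdf - prev
            prev = cdf
        # fold residual tail into the last bin so the pmf sums to 1
        out[hi] = out.get(hi, 0.0) + (1.0 - prev)
        return out

    @property
    def expected(self) -> float:
        return sum(d * p for d, p in self.pmf().items())


@dataclass
class SyntheticConfig:
    """Full parameterisation of the cohort generator."""

    n: int = 80
    sex_ratio: float = 0.4
    seed: int | None = None
    schema: StageSchema = FAW_SCHEMA
    # pre-adult stages in developmental order, excluding optional instars
    durations: dict[str, DurationDist] = field(default_factory=dict)
    daily_survival: dict[str, float] = field(default_factory=dict)
    supernumerary_prob: float = 0.0        # P(7th instar)
    second_supernumerary_prob: float = 0.0  # P(8th | 7th)
    apop: DurationDist = field(default_factory=lambda: DurationDist(3.5, 0.3))
    female_longevity: DurationDist = field(default_factory=lambda: DurationDist(12.0, 0.4))
    male_longevity: DurationDist = field(default_factory=lambda: DurationDist(13.0, 0.4))
    fecundity_mean: float = 700.0
    fecundity_cv: float = 0.3
    infertile_prob: float = 0.0
    # unimodal daily allocation: lognormal-shaped, mode at `peak_lag` days
    # after first oviposition (1-based), log-scale width `peak_width`
    peak_lag: float = 3.0
    peak_width: float = 0.6

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p, name in [(self.sex_ratio, "sex_ratio"),
                        (self.supernumerary_prob, "supernumerary_prob"),
                        (self.second_supernumerary_prob, "second_supernumerary_prob"),
                        (self.infertile_prob, "infertile_prob")]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for s, q in self.daily_survival.items():
            if not 0 < q <= 1:
                raise ValueError(f"daily survival for {s} must be in (0, 1]")

    # -- stage plumbing ----------------------------------------------------
    @property
    def obligatory_stages(self) -> list[str]:
        pupa = self.schema.index("PUPA")
        return [s for s in self.schema.stages[:pupa + 1]
                if s not in self.schema.optional_stages]

    @property
    def optional_sequence(self) -> list[str]:
        return list(self.schema.optional_stages)

    def stage_sequence(self, extra_instars: int) -> list[str]:
        """Pre-adult stage sequence with `extra_instars` supernumerary stages."""
        obligatory = self.obligatory_stages
        seq = obligatory[:-1]  # everything before PUPA
        seq += self.optional_sequence[:extra_instars]
        seq.append(obligatory[-1])  # PUPA
        return seq

    def survival_of(self, stage: str) -> float:
        return self.daily_survival.get(stage, 1.0)


@dataclass
class GroundTruth:
    """Analytic truth implied by a :class:`SyntheticConfig`."""

    R0: float
    r: float                      # NaN when R0 == 0
    preadult_survival: float
    stage_duration_means: dict[str, float]
    maternity: np.ndarray         # expected l_x m_x of the configured process


# ---------------------------------------------------------------------------
# generation

def _alloc_eggs(total: int, span: int, peak_lag: float, width: float) -> list[int]:
    """Spread `total` eggs over `span` days along a lognormal-shaped curve.

    Largest-remainder rounding guarantees the day counts sum to `total`.
    """
    if span <= 0 or total <= 0:
        return [0] * max(span, 0)
    if span == 1:
        return [total]
    k = np.arange(1, span + 1, dtype=float)
    mu = math.log(max(peak_lag, 1e-9)) + width**2  # mode at peak_lag
    w = stats.lognorm.pdf(k, s=width, scale=math.exp(mu))
    if w.sum() <= 0:
        w = np.ones(span)
    w = w / w.sum()
    raw = total * w
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base.tolist()


def _expected_alloc(span: int, peak_lag: float, width: float) -> np.ndarray:
    """Normalised allocation weights for a laying span (real-valued)."""
    if span <= 0:
        return np.zeros(0)
    if span == 1:
        return np.ones(1)
    k = np.arange(1, span + 1, dtype=float)
    mu = math.log(max(peak_lag, 1e-9)) + width**2
    w = stats.lognorm.pdf(k, s=width, scale=math.exp(mu))
    if w.sum() <= 0:
        w = np.ones(span)
    return w / w.sum()


def generate_cohort(config: SyntheticConfig,
                    seed: int | None = None) -> CohortTable:
    """Draw a cohort of ``config.n`` independent individuals.

    ``seed`` overrides ``config.seed``; one of the two must be given for
    reproducibility but either may be None for a nondeterministic draw.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    schema = config.schema
    individuals: list[IndividualRecord] = []
    width = max(1, len(str(config.n)))
    for i in range(config.n):
        ind = _generate_individual(config, rng, f"i{i + 1:0{width}d}")
        individuals.append(ind)
    return CohortTable(schema=schema, individuals=individuals)


def _generate_individual(config: SyntheticConfig, rng: np.random.Generator,
                         ind_id: str) -> IndividualRecord:
    schema = config.schema
    extra = 0
    if config.optional_sequence and rng.random() < config.supernumerary_prob:
        extra = 1
        if (len(config.optional_sequence) > 1
                and rng.random() < config.second_supernumerary_prob):
            extra = 2
    history: list[tuple[int, str]] = []
    age = 0
    died = False
    for stage in config.stage_sequence(extra):
        d = config.durations[stage].sample(rng)
        q = config.survival_of(stage)
        if q >= 1.0:
            alive_days = d
            died = False
        else:
            g = int(rng.geometric(1.0 - q))  # first failed daily trial
            alive_days = min(g, d)
            died = g <= d
        for _ in range(alive_days):
            history.append((age, stage))
            age += 1
        if died:
            return IndividualRecord(id=ind_id, sex=UNKNOWN, history=history)
    # adult emergence
    female = rng.random() < config.sex_ratio
    if female:
        apop = config.apop.sample(rng)
        longevity = max(config.female_longevity.sample(rng), apop + 1)
        if config.infertile_prob and rng.random() < config.infertile_prob:
            total = 0
        else:
            total = max(0, round(float(
                rng.gamma(1.0 / config.fecundity_cv**2,
                          config.fecundity_mean * config.fecundity_cv**2)
                if config.fecundity_cv > 0 else config.fecundity_mean)))
        span = longevity - apop
        alloc = _alloc_eggs(total, span, config.peak_lag, config.peak_width)
        eggs: dict[int, int] = {}
        emergence = age
        for day in range(longevity):
            history.append((age, schema.female_stage))
            lag = day - apop
            if 0 <= lag < len(alloc) and alloc[lag] > 0:
                eggs[age] = alloc[lag]
            age += 1
        return IndividualRecord(id=ind_id, sex=FEMALE, history=history,
                                daily_eggs=eggs)
    longevity = config.male_longevity.sample(rng)
    male_stage = next(s for s in schema.adult_stages if s != schema.female_stage)
    for _ in range(longevity):
        history.append((age, male_stage))
        age += 1
    return IndividualRecord(id=ind_id, sex=MALE, history=history)


# ---------------------------------------------------------------------------
# analytic ground truth

def _stage_factor(dd: DurationDist, q: float) -> float:
    """P(surviving a whole stage) = sum_d pmf(d) q^d."""
    if q >= 1.0:
        return 1.0
    return sum(p * q**d for d, p in dd.pmf().items())


def _convolve_stage(mass: np.ndarray, dd: DurationDist, q: float) -> np.ndarray:
    """Propagate an emergence-age mass vector through one stage."""
    pmf = dd.pmf()
    hi = max(pmf)
    out = np.zeros(len(mass) + hi)
    for d, p in pmf.items():
        w = p * (q**d if q < 1.0 else 1.0)
        if w > 0:
            out[d:d + len(mass)] += w * mass
    return out


def preadult_emergence_distribution(config: SyntheticConfig) -> np.ndarray:
    """Mass over adult-emergence ages; total mass = pre-adult survival."""
    branches: list[tuple[float, int]] = [(1.0 - config.supernumerary_prob, 0)]
    if config.optional_sequence:
        p7 = config.supernumerary_prob
        p8 = config.second_supernumerary_prob if len(config.optional_sequence) > 1 else 0.0
        branches = [(1.0 - p7, 0), (p7 * (1.0 - p8), 1), (p7 * p8, 2)]
        branches = [(w, e) for w, e in branches if w > 0]
    total = None
    for weight, extra in branches:
        mass = np.array([1.0])
        for stage in config.stage_sequence(extra):
            mass = _convolve_stage(mass, config.durations[stage],
                                   config.survival_of(stage))
        mass = weight * mass
        if total is None:
            total = mass
        elif len(total) >= len(mass):
            total[:len(mass)] += mass
        else:
            mass[:len(total)] += total
            total = mass
    return total if total is not None else np.array([1.0])


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Closed-form R0 and the intrinsic rate of the expected schedules."""
    emergence = preadult_emergence_distribution(config)
    preadult_survival = float(emergence.sum())
    fertile = 1.0 - config.infertile_prob
    R0 = config.sex_ratio * preadult_survival * fertile * config.fecundity_mean

    duration_means = {s: dd.expected for s, dd in config.durations.items()}

    if R0 <= 0:
        return GroundTruth(R0=R0, r=math.nan,
                           preadult_survival=preadult_survival,
                           stage_duration_means=duration_means,
                           maternity=np.zeros(1))

    apop_pmf = config.apop.pmf()
    lon_pmf = config.female_longevity.pmf()
    horizon = (len(emergence) + max(apop_pmf) + max(lon_pmf) + 2)
    phi = np.zeros(horizon)
    female_factor = config.sex_ratio * fertile
    for a, wa in enumerate(emergence):
        if wa <= 0:
            continue
        for p, wp in apop_pmf.items():
            for L, wl in lon_pmf.items():
                w = wa * wp * wl * female_factor
                if w <= 0:
                    continue
                span = max(L, p + 1) - p    # generator clips longevity
                alloc = _expected_alloc(span, config.peak_lag, config.peak_width)
                start = a + p
                phi[start:start + span] += w * config.fecundity_mean * alloc
    sc = SurvivalCurve(l=np.ones_like(phi))
    fs = FecunditySchedule(f=np.zeros((len(phi), 1)), m=phi, net_maternity=phi)
    r = solve_intrinsic_rate(sc, fs)
    return GroundTruth(R0=R0, r=r, preadult_survival=preadult_survival,
                       stage_duration_means=duration_means, maternity=phi)


# ---------------------------------------------------------------------------
# presets and config files

def _uniform_survival(stages: list[str], target: float,
                      expected_days: float) -> dict[str, float]:
    q = target ** (1.0 / expected_days)
    return {s: q for s in stages}


def _faw_like() -> SyntheticConfig:
    durations = {
        "EGG": DurationDist(3.0, 0.0),
        "L1": DurationDist(2.0, 0.25),
        "L2": DurationDist(2.0, 0.25),
        "L3": DurationDist(2.1, 0.25),
        "L4": DurationDist(2.0, 0.3),
        "L5": DurationDist(2.5, 0.3),
        "L6": DurationDist(4.5, 0.25),
        "L7": DurationDist(5.0, 0.25),
        "L8": DurationDist(5.0, 0.3),
        "PUPA": DurationDist(8.6, 0.1),
    }
    expected_days = sum(durations[s].expected
                        for s in ["EGG", "L1", "L2", "L3", "L4", "L5", "L6", "PUPA"])
    expected_days += 0.3 * durations["L7"].expected
    survival = _uniform_survival(list(durations), 0.7, expected_days)
    return SyntheticConfig(
        n=80, sex_ratio=0.4, durations=durations, daily_survival=survival,
        supernumerary_prob=0.3, second_supernumerary_prob=0.1,
        apop=DurationDist(3.5, 0.3),
        female_longevity=DurationDist(12.0, 0.4),
        male_longevity=DurationDist(13.0, 0.4),
        fecundity_mean=700.0, fecundity_cv=0.3,
        peak_lag=3.0, peak_width=0.6)


def _corn_like() -> SyntheticConfig:
    durations = {
        "EGG": DurationDist(3.0, 0.0),
        "L1": DurationDist(2.0, 0.1),
        "L2": DurationDist(2.0, 0.1),
        "L3": DurationDist(2.1, 0.15),
        "L4": DurationDist(1.5, 0.3),
        "L5": DurationDist(3.0, 0.3),
        "L6": DurationDist(4.6, 0.2),
        "L7": DurationDist(5.0, 0.25),
        "L8": DurationDist(5.0, 0.3),
        "PUPA": DurationDist(8.6, 0.1),
    }
    expected_days = sum(durations[s].expected
                        for s in ["EGG", "L1", "L2", "L3", "L4", "L5", "L6", "PUPA"])
    survival = _uniform_survival(list(durations), 0.7375, expected_days)
    return SyntheticConfig(
        n=80, sex_ratio=0.46, durations=durations, daily_survival=survival,
        supernumerary_prob=0.0,
        apop=DurationDist(3.4, 0.25),
        female_longevity=DurationDist(12.6, 0.3),
        male_longevity=DurationDist(14.4, 0.35),
        fecundity_mean=950.0, fecundity_cv=0.25,
        peak_lag=3.0, peak_width=0.55)


def _jobs_tears_like() -> SyntheticConfig:
    durations = {
        "EGG": DurationDist(2.0, 0.0),
        "L1": DurationDist(2.8, 0.2),
        "L2": DurationDist(2.2, 0.15),
        "L3": DurationDist(2.1, 0.15),
        "L4": DurationDist(2.2, 0.15),
        "L5": DurationDist(3.0, 0.2),
        "L6": DurationDist(5.1, 0.25),
        "L7": DurationDist(5.9, 0.3),
        "L8": DurationDist(6.0, 0.3),
        "PUPA": DurationDist(9.7, 0.1),
    }
    expected_days = sum(durations[s].expected
                        for s in ["EGG", "L1", "L2", "L3", "L4", "L5", "L6", "PUPA"])
    expected_days += 0.2 * durations["L7"].expected
    survival = _uniform_survival(list(durations), 0.63, expected_days)
    return SyntheticConfig(
        n=100, sex_ratio=0.48, durations=durations, daily_survival=survival,
        supernumerary_prob=0.2, second_supernumerary_prob=0.05,
        apop=DurationDist(5.0, 0.3),
        female_longevity=DurationDist(13.0, 0.35),
        male_longevity=DurationDist(10.4, 0.35),
        fecundity_mean=450.0, fecundity_cv=0.3,
        peak_lag=3.0, peak_width=0.6)


def _well_mixed() -> SyntheticConfig:
    """Heavily spread schedules: the projection's transient generation
    cycles damp out quickly, so asymptotic growth is reached within a
    120-day horizon.  Used for growth-rate convergence checks."""
    durs = {
        "EGG": DurationDist(1.5, 1.0),
        "L1": DurationDist(1.5, 1.0), "L2": DurationDist(1.5, 1.0),
        "L3": DurationDist(1.5, 1.0), "L4": DurationDist(1.5, 1.0),
        "L5": DurationDist(1.5, 1.0), "L6": DurationDist(2.0, 1.0),
        "L7": DurationDist(2.0, 0.8), "L8": DurationDist(2.0, 0.8),
        "PUPA": DurationDist(4.0, 0.6),
    }
    return SyntheticConfig(
        n=1000, sex_ratio=0.5, durations=durs,
        daily_survival={s: 0.995 for s in durs},
        supernumerary_prob=0.3, second_supernumerary_prob=0.1,
        apop=DurationDist(2.0, 1.0),
        female_longevity=DurationDist(30.0, 0.6),
        male_longevity=DurationDist(12.0, 0.5),
        fecundity_mean=200.0, fecundity_cv=0.4,
        peak_lag=10.0, peak_width=2.0)


PRESETS = {
    "faw-like": _faw_like,
    "corn-like": _corn_like,
    "jobs-tears-like": _jobs_tears_like,
    "well-mixed": _well_mixed,
}


def preset(name: str) -> SyntheticConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(PRESETS)}") from None


# -- config (de)serialisation ----------------------------------------------

def save_config(config: SyntheticConfig, path) -> None:
    doc = {
        "n": config.n,
        "sex_ratio": config.sex_ratio,
        "seed": config.seed,
        "durations": {s: {"mean": d.mean, "cv": d.cv}
                      for s, d in config.durations.items()},
        "daily_survival": dict(config.daily_survival),
        "supernumerary_prob": config.supernumerary_prob,
        "second_supernumerary_prob": config.second_supernumerary_prob,
        "apop": {"mean": config.apop.mean, "cv": config.apop.cv},
        "female_longevity": {"mean": config.female_longevity.mean,
                             "cv": config.female_longevity.cv},
        "male_longevity": {"mean": config.male_longevity.mean,
                           "cv": config.male_longevity.cv},
        "fecundity_mean": config.fecundity_mean,
        "fecundity_cv": config.fecundity_cv,
        "infertile_prob": config.infertile_prob,
        "peak_lag": config.peak_lag,
        "peak_width": config.peak_width,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    def dd(d):
        return DurationDist(mean=float(d["mean"]), cv=float(d.get("cv", 0.0)))
    return SyntheticConfig(
        n=int(doc["n"]),
        sex_ratio=float(doc["sex_ratio"]),
        seed=doc.get("seed"),
        durations={s: dd(d) for s, d in doc["durations"].items()},
        daily_survival={s: float(q) for s, q in doc.get("daily_survival", {}).items()},
        supernumerary_prob=float(doc.get("supernumerary_prob", 0.0)),
        second_supernumerary_prob=float(doc.get("second_supernumerary_prob", 0.0)),
        apop=dd(doc["apop"]),
        female_longevity=dd(doc["female_longevity"]),
        male_longevity=dd(doc["male_longevity"]),
        fecundity_mean=float(doc["fecundity_mean"]),
        fecundity_cv=float(doc["fecundity_cv"]),
        infertile_prob=float(doc.get("infertile_prob", 0.0)),
        peak_lag=float(doc.get("peak_lag", 3.0)),
        peak_width=float(doc.get("peak_width", 0.6)),
    )
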