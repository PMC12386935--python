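import math

import numpy as np
import pytest

from agestage.cohort_io import FEMALE, MALE, UNKNOWN
from agestage.lifetable import (FecunditySchedule,
                                SurvivalCurve, analyze_cohort,
                                compute_age_stage_survival, compute_fecundity,
                                compute_lx, derived_rates,
                                fit_transition_model, life_expectancy,
                                net_reproductive_rate, reproductive_value,
                                solve_intrinsic_rate, solve_intrinsic_rate_many,
                                summarize_cohort, two_sex_r0_identity)
from conftest import make_cohort


def schedule_from_maternity(phi):
    phi = np.asarray(phi, dtype=float)
    return (SurvivalCurve(l=np.ones_like(phi)),
            FecunditySchedule(f=np.zeros((len(phi), 1)), m=phi,
                              net_maternity=phi))


def grid_search_rate(phi, lo=-1.0, hi=2.0, rounds=8, points=2001):
    """Independent brute-force oracle: iterated grid refinement on the
    discounted-sum equation."""
    phi = np.asarray(phi, dtype=float)
    ages1 = np.arange(1, len(phi) + 1)
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        vals = np.array([(np.exp(-r * ages1) * phi).sum() - 1.0 for r in grid])
        sign = np.sign(vals)
        idx = np.nonzero(np.diff(sign) < 0)[0]
        assert idx.size >= 1
        lo, hi = grid[idx[0]], grid[idx[0] + 1]
    return 0.5 * (lo + hi)


class TestAgeStageSurvival:
    def test_two_individual_counts(self, two_egg_cohort):
        surv = compute_age_stage_survival(two_egg_cohort)
        egg = surv.stages.index("EGG")
        l1 = surv.stages.index("L1")
        assert surv.s[0, egg] == 1.0
        assert surv.s[3, l1] == 0.5
        assert surv.s[3, egg] == 0.0

    def test_everyone_starts_as_egg(self, faw_cohort):
        surv = compute_age_stage_survival(faw_cohort)
        assert surv.s[0, 0] == 1.0

    def test_single_individual_zero_one(self):
        cohort = make_cohort([("a", UNKNOWN, ["EGG"] * 5, {})])
        surv = compute_age_stage_survival(cohort)
        assert set(np.unique(surv.s)) <= {0.0, 1.0}

    def test_row_sums_non_increasing(self, faw_cohort):
        surv = compute_age_stage_survival(faw_cohort)
        l = surv.s.sum(axis=1)
        assert np.all(np.diff(l) <= 1e-12)

    def test_counts_match_probabilities(self, corn_cohort):
        surv = compute_age_stage_survival(corn_cohort)
        np.testing.assert_allclose(surv.s, surv.counts / corn_cohort.n)


class TestSurvivalCurve:
    def test_l3_is_half(self, two_egg_cohort):
        lx = compute_lx(compute_age_stage_survival(two_egg_cohort))
        assert lx.l[3] == 0.5

    def test_l0_is_one(self, faw_cohort):
        lx = compute_lx(compute_age_stage_survival(faw_cohort))
        assert lx.l[0] == 1.0

    def test_defined_through_last_alive_day(self, two_egg_cohort):
        lx = compute_lx(compute_age_stage_survival(two_egg_cohort))
        omega = two_egg_cohort.omega
        assert lx.l[omega - 1] > 0
        assert len(lx.l) == omega + 1


class TestFecundity:
    def test_toy_pair(self, toy_pair_cohort):
        surv = compute_age_stage_survival(toy_pair_cohort)
        fs = compute_fecundity(toy_pair_cohort, surv)
        jf = surv.stages.index("ADULT_F")
        assert fs.f[1, jf] == 10.0
        # m_1 = s_1F * 10 / l_1 = 0.5 * 10 / 1
        assert fs.m[1] == pytest.approx(5.0)
        assert fs.net_maternity.sum() == pytest.approx(5.0)

    def test_no_eggs_zero_schedule(self, two_egg_cohort):
        surv = compute_age_stage_survival(two_egg_cohort)
        fs = compute_fecundity(two_egg_cohort, surv)
        assert np.all(fs.m == 0)

    def test_net_maternity_equals_egg_total_over_n(self, faw_cohort):
        surv = compute_age_stage_survival(faw_cohort)
        fs = compute_fecundity(faw_cohort, surv)
        total = sum(i.total_eggs() for i in faw_cohort.individuals)
        assert fs.net_maternity.sum() == pytest.approx(total / faw_cohort.n)


class TestNetReproductiveRate:
    def test_toy_r0_is_five(self, toy_pair_cohort):
        surv = compute_age_stage_survival(toy_pair_cohort)
        fs = compute_fecundity(toy_pair_cohort, surv)
        assert net_reproductive_rate(fs) == pytest.approx(5.0)

    def test_no_females_zero(self, two_egg_cohort):
        surv = compute_age_stage_survival(two_egg_cohort)
        fs = compute_fecundity(two_egg_cohort, surv)
        assert net_reproductive_rate(fs) == 0.0

    def test_identity_printed_values(self):
        assert round(two_sex_r0_identity(1054.6, 27, 80), 1) == 355.9

    def test_identity_on_cohort(self, faw_cohort):
        res = analyze_cohort(faw_cohort)
        s = res.summary
        assert res.params.R0 == pytest.approx(
            two_sex_r0_identity(s.fecundity.mean, s.n_female, s.n),
            rel=1e-12)


class TestIntrinsicRate:
    def test_unit_maternity_at_age_zero(self):
        sc, fs = schedule_from_maternity([1.0])
        assert solve_intrinsic_rate(sc, fs) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_age_one(self):
        sc, fs = schedule_from_maternity([0.0, 2.0])
        assert solve_intrinsic_rate(sc, fs) == pytest.approx(
            math.log(2) / 2, abs=1e-10)

    def test_residual_below_1e10(self, faw_cohort):
        res = analyze_cohort(faw_cohort)
        phi = res.fecundity.net_maternity
        ages1 = np.arange(1, len(phi) + 1)
        residual = abs((np.exp(-res.params.r * ages1) * phi).sum() - 1.0)
        assert residual < 1e-10

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            length = rng.integers(3, 40)
            phi = rng.random(length) * rng.integers(0, 2, length)
            phi[rng.integers(length)] += 0.5  # ensure reproduction
            sc, fs = schedule_from_maternity(phi)
            r = solve_intrinsic_rate(sc, fs)
            assert r == pytest.approx(grid_search_rate(phi), abs=1e-6)

    def test_no_reproduction_raises(self):
        sc, fs = schedule_from_maternity([0.0, 0.0])
        with pytest.raises(ValueError, match="no reproduction"):
            solve_intrinsic_rate(sc, fs)

    def test_vectorised_matches_scalar(self, faw_cohort, corn_cohort):
        rows = []
        expected = []
        for cohort in (faw_cohort, corn_cohort):
            res = analyze_cohort(cohort)
            rows.append(res.fecundity.net_maternity)
            expected.append(res.params.r)
        width = max(len(r) for r in rows)
        mat = np.zeros((len(rows), width))
        for i, r in enumerate(rows):
            mat[i, :len(r)] = r
        out = solve_intrinsic_rate_many(mat)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_vectorised_nan_for_sterile_rows(self):
        mat = np.array([[0.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        out = solve_intrinsic_rate_many(mat)
        assert math.isnan(out[0])
        assert out[1] == pytest.approx(math.log(2) / 2, abs=1e-9)


class TestDerivedRates:
    @pytest.mark.parametrize("r, lam3dp", [(0.137, 1.147), (0.138, 1.148),
                                           (0.172, 1.188)])
    def test_printed_lambda(self, r, lam3dp):
        lam, _ = derived_rates(100.0, r)
        assert round(lam, 3) == lam3dp

    def test_r_zero(self):
        lam, T = derived_rates(5.0, 0.0)
        assert lam == 1.0
        assert math.isnan(T)

    def test_closed_form_T(self):
        lam, T = derived_rates(5.0, math.log(2) / 2)
        assert T == pytest.approx(math.log(5) / (math.log(2) / 2))
        assert lam == pytest.approx(math.exp(math.log(2) / 2))


class TestTransitionModel:
    def test_half_advance_half_die(self):
        cohort = make_cohort([
            ("a", UNKNOWN, ["EGG", "L1"], {}),
            ("b", UNKNOWN, ["EGG"], {}),
        ])
        tm = fit_transition_model(cohort)
        egg = tm.stages.index("EGG")
        l1 = tm.stages.index("L1")
        assert tm.stay(0, egg) == 0.0
        assert tm.advance[0, egg, l1] == 0.5
        assert tm.die[0, egg] == 0.5

    def test_deterministic_cohort_degenerate_rows(self, clone_cohort):
        tm = fit_transition_model(clone_cohort)
        vals = np.concatenate([tm.advance[tm.observed].ravel(),
                               tm.die[tm.observed].ravel()])
        assert set(np.round(np.unique(vals), 12)) <= {0.0, 1.0}

    def test_skip_optional_stage_allowed(self):
        stages = ["EGG", "L1", "L2", "L3", "L4", "L5", "L6", "PUPA"]
        cohort = make_cohort([("s", UNKNOWN, stages, {})])
        tm = fit_transition_model(cohort)
        l6 = tm.stages.index("L6")
        pupa = tm.stages.index("PUPA")
        assert tm.advance[6, l6, pupa] == 1.0

    def test_rows_sum_to_one(self, faw_cohort):
        tm = fit_transition_model(faw_cohort)
        total = tm.advance.sum(axis=2) + tm.die
        np.testing.assert_allclose(total[tm.observed], 1.0, atol=1e-12)


def propagate_oracle(tm, x0, j0):
    """Independent forward propagation: list of (age, mass vector)."""
    omega, beta = tm.die.shape
    omega -= 1
    mass = np.zeros(beta)
    mass[j0] = 1.0
    out = []
    x = x0
    while x <= omega and mass.sum() > 1e-15:
        out.append((x, mass.copy()))
        if x == omega:
            break
        nxt = np.zeros(beta)
        for j in range(beta):
            for y in range(beta):
                nxt[y] += mass[j] * tm.advance[x, j, y]
        mass = nxt
        x += 1
    return out


class TestLifeExpectancy:
    def test_certain_death_tomorrow(self):
        cohort = make_cohort([("a", UNKNOWN, ["EGG"], {})])
        e = life_expectancy(fit_transition_model(cohort)).e
        assert e[0, 0] == 1.0

    def test_deterministic_three_day_life(self):
        cohort = make_cohort([("a", UNKNOWN, ["EGG", "EGG", "EGG"], {})])
        e = life_expectancy(fit_transition_model(cohort)).e
        assert e[0, 0] == pytest.approx(3.0)

    def test_e00_equals_mean_longevity(self, faw_cohort):
        res = analyze_cohort(faw_cohort)
        mean_death = np.mean([i.death_age for i in faw_cohort.individuals])
        assert res.life_expectancy.e[0, 0] == pytest.approx(mean_death,
                                                            abs=1e-9)

    def test_matches_forward_propagation_oracle(self, toy_pair_cohort):
        tm = fit_transition_model(toy_pair_cohort)
        e = life_expectancy(tm).e
        for x in range(tm.die.shape[0]):
            for j in range(tm.die.shape[1]):
                if not tm.observed[x, j]:
                    continue
                expected = sum(m.sum() for _, m in propagate_oracle(tm, x, j))
                assert e[x, j] == pytest.approx(expected, abs=1e-12)

    def test_at_least_one_everywhere(self, corn_cohort):
        res = analyze_cohort(corn_cohort)
        e = res.life_expectancy.e
        assert np.all(e[~np.isnan(e)] >= 1.0 - 1e-12)


class TestReproductiveValue:
    def test_v00_equals_lambda(self, faw_cohort):
        res = analyze_cohort(faw_cohort)
        assert res.reproductive_value.v[0, 0] == pytest.approx(
            res.params.lam, abs=1e-9)

    def test_male_cells_zero(self, faw_cohort):
        res = analyze_cohort(faw_cohort)
        jm = res.survival.stages.index("ADULT_M")
        col = res.reproductive_value.v[:, jm]
        assert np.all(np.abs(col[~np.isnan(col)]) < 1e-12)

    def test_matches_double_sum_oracle(self, toy_pair_cohort):
        res = analyze_cohort(toy_pair_cohort)
        tm = res.transitions
        fs = res.fecundity
        r = res.params.r
        v = res.reproductive_value.v
        for x in range(tm.die.shape[0]):
            for j in range(tm.die.shape[1]):
                if not tm.observed[x, j]:
                    continue
                total = 0.0
                for i, mass in propagate_oracle(tm, x, j):
                    total += math.exp(-r * (i + 1)) * float(mass @ fs.f[i])
                expected = math.exp(r * (x + 1)) * total
                assert v[x, j] == pytest.approx(expected, abs=1e-10)


class TestSummaries:
    def test_apop_tpop_example(self):
        stages = ["EGG"] * 23 + ["ADULT_F"] * 10
        cohort = make_cohort([
            ("f", FEMALE, stages, {26: 5, 27: 3, 30: 2}),
        ])
        s = summarize_cohort(cohort)
        assert s.apop.mean == 3.0
        assert s.tpop.mean == 26.0
        assert s.oviposition_days.mean == 3.0
        assert s.fecundity.mean == 10.0

    def test_proportions(self, three_individual_cohort):
        s = summarize_cohort(three_individual_cohort)
        assert s.prop_female == pytest.approx(1 / 3)
        assert s.prop_male == pytest.approx(1 / 3)
        assert s.prop_fertile == 1.0

    def test_printed_proportions(self):
        assert round(100 * 27 / 80, 1) == 33.8
        assert round(100 * 26 / 27, 1) == 96.3

    def test_stage_duration_completers_only(self, two_egg_cohort):
        s = summarize_cohort(two_egg_cohort)
        # only B completed the egg stage (3 days); A died in it
        assert s.stage_durations["EGG"].n == 1
        assert s.stage_durations["EGG"].mean == 3.0

    def test_supernumerary_proportion(self):
        base = ["EGG", "L1", "L2", "L3", "L4", "L5", "L6"]
        normal = base + ["PUPA"] * 2 + ["ADULT_M"] * 2
        extra = base + ["L7"] * 2 + ["PUPA"] * 2 + ["ADULT_M"] * 2
        died = base[:4]
        cohort = make_cohort([
            ("n", MALE, normal, {}),
            ("s", MALE, extra, {}),
            ("d", UNKNOWN, died, {}),
        ])
        s = summarize_cohort(cohort)
        assert s.supernumerary_prop == pytest.approx(0.5)

    def test_per_individual_tpop_identity(self, faw_cohort):
        """TPOP = adult emergence age + APOP for each ovipositing female."""
        for ind in faw_cohort.individuals:
            first = ind.first_egg_age()
            if first is None:
                continue
            emergence = next(a for a, st in ind.history if st == "ADULT_F")
            assert first == emergence + (first - emergence)
            assert first >= emergence


class TestMonotonicity:
    def test_extra_daily_fecundity_never_decreases_R0_or_r(self, faw_cohort):
        import copy
        res = analyze_cohort(faw_cohort)
        boosted = copy.deepcopy(faw_cohort)
        for ind in boosted.individuals:
            if ind.sex == FEMALE:
                for age, stage in ind.history:
                    if stage == "ADULT_F":
                        ind.daily_eggs[age] = ind.daily_eggs.get(age, 0) + 5
        res2 = analyze_cohort(boosted)
        assert res2.params.R0 >= res.params.R0
        assert res2.params.r >= res.params.r
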