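"""Life-cycle processes: mortality composition, migration timing, spawning, cull."""

import dataclasses

import numpy as np
import pytest

from troutmig import experiments as E
from troutmig import lifecycle as L
from troutmig.demography import ANADROMOUS, FRESHWATER, MARINE, RESIDENT
from troutmig.genetics import FEMALE, MALE


def small_state(**config_overrides) -> L.SimulationState:
    cfg = E.ScenarioConfig(seed=11, **config_overrides)
    return E.build_state(cfg)


class TestMortalityComposition:
    def test_reference_rates(self):
        p = L.MortalityParams()
        assert L.weekly_mortality_prob(MALE, FRESHWATER, False, p) == 0.01543
        assert L.weekly_mortality_prob(MALE, MARINE, False, p) == pytest.approx(
            0.01543 * 1.262
        )

    def test_female_multipliers_scale_female_freshwater_rate(self):
        p = L.MortalityParams(mortalityF=1.5, anad_death_multiplierF=2.0)
        assert L.weekly_mortality_prob(FEMALE, FRESHWATER, False, p) == pytest.approx(
            0.01543 * 1.5
        )
        # female marine rate is the female multiplier applied to the female
        # freshwater baseline (the ratio swept in the third experiment)
        assert L.weekly_mortality_prob(FEMALE, MARINE, False, p) == pytest.approx(
            0.01543 * 1.5 * 2.0
        )

    def test_sexes_identical_when_all_scalars_one(self):
        p = L.MortalityParams(
            mortalityF=1.0, anad_death_multiplierM=1.0, anad_death_multiplierF=1.0
        )
        for habitat in (FRESHWATER, MARINE):
            assert L.weekly_mortality_prob(FEMALE, habitat, False, p) == (
                L.weekly_mortality_prob(MALE, habitat, False, p)
            )

    def test_parasite_load_only_at_sea(self):
        p = L.MortalityParams(parasite_load=1.6)
        assert L.weekly_mortality_prob(MALE, MARINE, True, p) == pytest.approx(
            0.01543 * 1.262 * 1.6
        )
        assert L.weekly_mortality_prob(MALE, FRESHWATER, True, p) == 0.01543
        # load 1 means no extra mortality
        p1 = L.MortalityParams(parasite_load=1.0)
        assert L.weekly_mortality_prob(MALE, MARINE, True, p1) == (
            L.weekly_mortality_prob(MALE, MARINE, False, p1)
        )

    def test_composed_probability_is_clamped(self):
        p = L.MortalityParams(mortalityM=0.9, anad_death_multiplierM=5.0)
        assert L.weekly_mortality_prob(MALE, MARINE, False, p) == 1.0

    def test_validation_names_offender(self):
        with pytest.raises(ValueError, match="mortalityM"):
            L.MortalityParams(mortalityM=-0.1)
        with pytest.raises(ValueError, match="parasite_load"):
            L.MortalityParams(parasite_load=-1)


class TestStageSurvival:
    def test_zero_rate(self):
        assert L.stage_survival(0.0, 500) == 1.0

    def test_calibration_identities(self):
        # ~1.5% egg-to-migration survival over 122 freshwater weeks incl. 10% egg survival
        assert 0.10 * L.stage_survival(0.01543, 122) == pytest.approx(0.015, abs=5e-4)
        # ~20% marine survival over the 82-week first sojourn
        assert L.stage_survival(0.01543 * 1.262, 82) == pytest.approx(0.20, abs=5e-3)


class TestWeeklyMortalityApplication:
    def test_no_deaths_when_rate_zero(self):
        state = small_state(mortalityM=0.0)
        n0 = state.pop.n_alive
        assert L.apply_weekly_mortality(state) == 0
        assert state.pop.n_alive == n0

    def test_binomial_death_count(self):
        state = small_state(initial_population=10_000, mortalityM=0.01543)
        state.pop.age_weeks[:] = 10  # keep everyone far from the lifespan cap
        deaths = L.apply_weekly_mortality(state)
        assert deaths == pytest.approx(154, abs=4 * np.sqrt(154))

    def test_lifespan_cap_removal_is_certain(self):
        state = small_state(mortalityM=0.0)
        state.pop.age_weeks[:5] = 416
        state.pop.age_weeks[5:] = 100
        L.apply_weekly_mortality(state)
        assert state.pop.n_alive == len(state.pop) - 5

    def test_survivors_age_by_one_week(self):
        state = small_state(mortalityM=0.0)
        ages = state.pop.age_weeks.copy()
        L.apply_weekly_mortality(state)
        alive = state.pop.alive_indices
        assert (state.pop.age_weeks[alive] == ages[alive] + 1).all()


class TestTacticAndCondition:
    def test_strict_threshold_comparison(self):
        assert L.decide_tactic(12.0, 10.0) == RESIDENT
        assert L.decide_tactic(10.0, 12.0) == ANADROMOUS
        assert L.decide_tactic(10.0, 10.0) == ANADROMOUS  # tie goes to anadromy

    def test_zero_variance_condition_equals_mean(self, rng):
        means = np.array([3.0, 7.0])
        c = L.draw_condition(np.array([MALE, FEMALE]), means, 0.0, rng)
        assert c.tolist() == [3.0, 7.0]

    @pytest.mark.parametrize("n_loci", [0, 10, 20])
    def test_initial_tactics_equally_likely_per_sex(self, n_loci):
        """Frozen sex-specific condition means give each sex ~50:50 odds at start."""
        state = small_state(initial_population=10_000, n_loci=n_loci)
        pop = state.pop
        for sex in (MALE, FEMALE):
            mask = pop.sex == sex
            p_res = (pop.tactic[mask] == RESIDENT).mean()
            assert p_res == pytest.approx(0.5, abs=0.03)


class TestMigrationAndReturn:
    def test_first_timer_sojourn_is_82_weeks_and_430mm(self):
        """Agent trace: out week 14, back week 44 next year, +200 mm exactly."""
        state = small_state(mortalityM=0.0, initial_population=4)
        pop = state.pop
        pop.sex[:] = [MALE, MALE, FEMALE, FEMALE]
        pop.tactic[:] = ANADROMOUS
        pop.age_weeks[:] = 104
        pop.habitat[:] = FRESHWATER
        pop.quality[:] = 230.0
        pop.times_at_sea[:] = 0
        weeks_at_sea_seen = 0
        for week in range(1, 2 * 52 + 1):
            L.step_week(state)
            week_of_year = (week - 1) % 52 + 1
            if week_of_year == 14 and week <= 52:
                assert (pop.habitat[pop.alive_indices] == MARINE).all()
        # returned at week 44 of year 2 after exactly 82 accrual weeks
        alive = pop.alive_indices
        orig = alive[pop.id[alive] < 4]  # exclude any fry spawned meanwhile
        assert len(orig) == 4
        assert (pop.habitat[orig] == FRESHWATER).all()
        assert (pop.weeks_at_sea[orig] == 82).all()
        np.testing.assert_allclose(pop.quality[orig], 430.0, rtol=1e-12)

    def test_repeat_spawner_sojourn_is_30_weeks(self):
        state = small_state(mortalityM=0.0, initial_population=2)
        pop = state.pop
        pop.tactic[:] = ANADROMOUS
        pop.age_weeks[:] = 104
        pop.times_at_sea[:] = 1  # already completed a first migration
        pop.weeks_at_sea[:] = 82
        pop.quality[:] = 430.0
        for _ in range(52):
            L.step_week(state)
        alive = pop.alive_indices
        assert (pop.habitat[alive] == FRESHWATER).all()
        assert (pop.weeks_at_sea[alive] == 30).all()
        np.testing.assert_allclose(
            pop.quality[alive], 430.0 + 200.0 * 30 / 82, rtol=1e-12
        )

    def test_infestation_matches_patch_proportion(self):
        state = small_state(
            mortalityM=0.0, prop_parasites=0.4, initial_population=1000
        )
        pop = state.pop
        pop.tactic[:] = ANADROMOUS
        pop.age_weeks[:] = 104
        state.week = 14
        migrants = L.migrate_to_sea(state)
        frac = pop.parasitised[migrants].mean()
        assert frac == pytest.approx(0.4, abs=4 * np.sqrt(0.24 / 1000))
        # lice are shed on return
        n_infested = int(pop.parasitised[migrants].sum())
        pop.weeks_at_sea[migrants] = 82
        pop.times_at_sea[migrants] = 1
        n_ret, n_par = L.return_to_freshwater(state)
        assert n_ret == len(migrants)
        assert n_par == n_infested  # counted before shedding
        assert pop.parasitised[migrants].sum() == 0  # flags cleared

    def test_no_parasites_no_infestation(self):
        state = small_state(mortalityM=0.0, prop_parasites=0.0, initial_population=200)
        state.pop.tactic[:] = ANADROMOUS
        state.pop.age_weeks[:] = 104
        state.week = 14
        migrants = L.migrate_to_sea(state)
        assert state.pop.parasitised[migrants].sum() == 0

    def test_infested_growth_reduction(self):
        state = small_state(mortalityM=0.0, paras_quality=0.8, initial_population=2)
        pop = state.pop
        pop.habitat[:] = MARINE
        pop.parasitised[:] = [True, False]
        pop.quality[:] = 230.0
        L.accrue_sea_quality(state, weeks=82)
        assert pop.quality[0] == pytest.approx(230.0 + 200.0 * 0.2)
        assert pop.quality[1] == pytest.approx(430.0)


class TestReproduction:
    def test_no_mature_males_means_no_eggs(self):
        state = small_state(initial_population=10)
        pop = state.pop
        pop.sex[:] = FEMALE
        pop.age_weeks[:] = 104
        assert L.reproduce(state) == (0, 0)

    def test_fecundity_allometry_ratio(self):
        """A 430 mm female produces (430/230)^beta times a 230 mm female's eggs."""
        q = E.ScenarioConfig().quality_params()
        f230 = round(q.fecundity_alpha * 230.0**q.fecundity_beta)
        f430 = round(q.fecundity_alpha * 430.0**q.fecundity_beta)
        assert f430 / f230 == pytest.approx((430 / 230) ** q.fecundity_beta, rel=0.01)
        assert f230 == 100  # calibration: resident female ~100 eggs

    def test_egg_to_fry_survival_is_binomial(self):
        state = small_state(initial_population=400, mortalityM=0.0)
        pop = state.pop
        pop.sex[: 200] = FEMALE
        pop.sex[200:] = MALE
        pop.tactic[:] = RESIDENT
        pop.age_weeks[:] = 104
        n_before = pop.n_alive
        eggs, spawners = L.reproduce(state)
        assert spawners == 200
        fry = pop.n_alive - n_before
        assert fry == pytest.approx(
            eggs * 0.10, abs=4 * np.sqrt(eggs * 0.1 * 0.9)
        )

    def test_spawning_stats_tally(self):
        state = small_state(initial_population=30, mortalityM=0.0)
        pop = state.pop
        pop.sex[0] = FEMALE
        pop.sex[1:] = MALE
        pop.tactic[:] = RESIDENT
        pop.age_weeks[:] = 104
        pop.x[:] = 0
        pop.y[:] = 0
        L.reproduce(state)
        stats = state.last_spawning_stats
        assert stats["mature_males_resident"] == 29
        # all fry share at most 5 distinct fathers
        newborn = pop.alive_indices[pop.age_weeks[pop.alive_indices] == 0]
        assert len(newborn) > 0


class TestCull:
    def test_no_cull_below_capacity(self):
        state = small_state(initial_population=2900)
        assert L.density_dependent_cull(state) == 0

    def test_exact_cull_arithmetic(self):
        state = small_state(initial_population=3200)
        state.pop.age_weeks[:] = 50
        state.pop.age_weeks[:500] = 0  # 500 newborns
        assert L.density_dependent_cull(state) == 200
        assert state.pop.n_alive == 3000

    def test_cull_never_removes_older_fish(self):
        state = small_state(initial_population=3200)
        state.pop.age_weeks[:] = 50
        state.pop.age_weeks[:150] = 0  # fewer newborns than the excess
        assert L.density_dependent_cull(state) == 150
        assert state.pop.n_alive == 3050  # may exceed K when elders exceed K
        alive = state.pop.alive_indices
        assert (state.pop.age_weeks[alive] > 0).all()


class TestScheduler:
    def test_52_steps_advance_one_year_with_one_record(self):
        state = small_state(initial_population=100, duration_years=1)
        records = [L.step_week(state) for _ in range(52)]
        assert state.year == 2 and state.week == 1
        assert sum(r is not None for r in records) == 1
        assert records[-1].year == 1

    def test_empty_population_runs_without_crash(self):
        state = small_state(initial_population=100)
        state.pop.kill(state.pop.alive_indices)
        for _ in range(52):
            rec = L.step_week(state)
        assert rec.eggs_total == 0 and rec.spawning_females == 0
        assert np.isnan(rec.productivity)

    def test_fish_dying_before_spawning_week_never_spawns(self):
        # a lone pair that dies with certainty can produce no eggs that year
        state = small_state(initial_population=2, mortalityM=1.0)
        state.pop.sex[:] = [MALE, FEMALE]
        state.pop.age_weeks[:] = 104
        for _ in range(52):
            rec = L.step_week(state)
        assert rec.eggs_total == 0

    def test_block_and_weekly_drivers_agree_statistically(self):
        """Aggregated-block driver matches the weekly reference distributionally."""
        cfg = E.ScenarioConfig(duration_years=40, seed=5, initial_population=1500)
        fast = E.records_to_frame(E.run_scenario(cfg))
        slow = E.records_to_frame(E.run_scenario(cfg, weekly=True))
        last_fast = fast[fast.year > 20]
        last_slow = slow[slow.year > 20]
        assert last_fast.pop_size_freshwater.mean() == pytest.approx(
            last_slow.pop_size_freshwater.mean(), rel=0.05
        )
        assert abs(
            last_fast.prop_anad_total.mean() - last_slow.prop_anad_total.mean()
        ) < 0.1
        assert last_fast.eggs_total.median() == pytest.approx(
            last_slow.eggs_total.median(), rel=0.15
        )


class TestMarineInvariant:
    def test_no_resident_ever_at_sea(self):
        cfg = E.ScenarioConfig(duration_years=6, seed=7)
        state = E.build_state(cfg)
        for _ in range(6):
            L.advance_year(state)
            idx = state.pop.alive_indices
            at_sea = idx[state.pop.habitat[idx] == MARINE]
            assert (state.pop.tactic[at_sea] == ANADROMOUS).all()
            assert (state.pop.age_weeks[at_sea] >= 104).all()
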