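"""Weekly life-cycle processes: mortality, migration, growth, mating, recruitment.

The year has 52 weekly time steps.  Mortality and aging happen every
week; everything else is pinned to one week of the year:

* week 14 — all anadromous trout aged 2+ years migrate to a random
  marine patch (and may pick up sea lice there);
* week 44 — anadromous fish whose sojourn is complete return to fresh
  water (82 weeks for first-timers, i.e. two summers and one winter;
  30 weeks for repeat spawners) and shed any lice;
* week 48 — sneaker decision, spawning, and the density-dependent cull
  of surplus newborns down to the freshwater carrying capacity;
* week 52 — the yearly record is emitted.

Fish at sea gain quality (body length, mm) pro rata: 200 mm over the
82-week first sojourn, i.e. 200/82 mm per week at sea, reduced by the
factor ``1 - paras_quality`` while infested.  A first-time anadromous
spawner therefore returns at 230 + 200 = 430 mm exactly.

Two drivers are provided.  :func:`step_week` advances a single week and
is the reference semantics.  :func:`advance_year` produces the same
process distribution but aggregates the uneventful stretches of weeks
into single vectorised survival/growth updates (a fish's survival over k
identical weeks is one Bernoulli draw with probability ``(1-p)^k``),
which is what makes 750-year runs cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genetics
from .demography import (
    ANADROMOUS,
    FRESHWATER,
    MARINE,
    RESIDENT,
    HabitatGrid,
    Population,
)
from .genetics import FEMALE, MALE, GeneticArchitecture


@dataclass(frozen=True)
class MortalityParams:
    """Weekly mortality rates and the scalars composing them.

    ``mortalityM`` is the male freshwater weekly mortality (the reference
    rate).  ``mortalityF`` scales female freshwater mortality relative to
    males.  Each sex's marine multiplier scales that sex's marine
    mortality relative to its own freshwater rate (this is the ratio
    plotted on the female-mortality axis of the third experiment).
    ``parasite_load`` further multiplies the marine mortality of infested
    fish.  ``surv_rate`` is egg-to-fry survival.
    """

    mortalityM: float = 0.01543
    mortalityF: float = 1.0
    anad_death_multiplierM: float = 1.262
    anad_death_multiplierF: float = 1.0
    parasite_load: float = 1.0
    surv_rate: float = 0.10
    max_lifespan_weeks: int = 416  # 8 years

    def __post_init__(self) -> None:
        for name in ("mortalityM", "surv_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in (
            "mortalityF",
            "anad_death_multiplierM",
            "anad_death_multiplierF",
            "parasite_load",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class QualityParams:
    """Body-size ('quality') dynamics and fecundity allometry.

    Residents hold a fixed 230 mm; sea growth is 200 mm per 82-week first
    sojourn accrued weekly.  Fecundity is ``round(alpha * quality^beta)``
    eggs; the default alpha gives a 230 mm resident female ~100 eggs.
    ``sneaker_boost`` is the temporary quality bump a sneaking resident
    male gets, large enough by default (+250 mm) to outrank unparasitised
    anadromous rivals in a female's quality ranking.
    """

    resident_quality: float = 230.0
    anad_quality_gain: float = 200.0
    paras_quality: float = 0.0
    sneaker_boost: float = 250.0
    fecundity_alpha: float = 100.0 / 230.0**3.5
    fecundity_beta: float = 3.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.paras_quality <= 1.0:
            raise ValueError(
                f"paras_quality must be in [0, 1], got {self.paras_quality}"
            )
        for name in ("resident_quality", "anad_quality_gain", "sneaker_boost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ScheduleConstants:
    migration_week: int = 14
    return_week: int = 44
    spawning_week: int = 48
    weeks_per_year: int = 52
    resident_maturity_weeks: int = 104  # mature in third year of life
    anadromous_maturity_weeks: int = 156  # first spawn in fourth year

    def __post_init__(self) -> None:
        if not self.migration_week < self.return_week < self.spawning_week <= self.weeks_per_year:
            raise ValueError("schedule must satisfy migration < return < spawning <= 52")

    @property
    def first_sojourn_weeks(self) -> int:
        """Weeks at sea for a first-time migrant (two summers, one winter)."""
        return self.weeks_per_year - self.migration_week + self.return_week  # 82

    @property
    def repeat_sojourn_weeks(self) -> int:
        """Weeks at sea for a repeat spawner (one summer)."""
        return self.return_week - self.migration_week  # 30


# -- elementary rates ---------------------------------------------------


def weekly_mortality_prob(
    sex, habitat, parasitised: bool, p: MortalityParams
) -> float:
    """Weekly death probability for one sex/habitat/infestation combination."""
    sex = genetics._SEX_CODES[sex]
    m = p.mortalityM
    if sex == FEMALE:
        m *= p.mortalityF
    if habitat == MARINE:
        m *= p.anad_death_multiplierM if sex == MALE else p.anad_death_multiplierF
        if parasitised:
            m *= p.parasite_load
    return min(m, 1.0)


def stage_survival(weekly_m: float, weeks: int) -> float:
    """Probability of surviving ``weeks`` consecutive weeks at rate ``weekly_m``."""
    if not 0.0 <= weekly_m <= 1.0 or weeks < 0:
        raise ValueError("need 0 <= weekly_m <= 1 and weeks >= 0")
    return (1.0 - weekly_m) ** weeks


def _rate_table(p: MortalityParams) -> np.ndarray:
    """Lookup indexed by ``2*sex + habitat`` (unparasitised rates)."""
    return np.array(
        [
            weekly_mortality_prob(MALE, FRESHWATER, False, p),
            weekly_mortality_prob(MALE, MARINE, False, p),
            weekly_mortality_prob(FEMALE, FRESHWATER, False, p),
            weekly_mortality_prob(FEMALE, MARINE, False, p),
        ]
    )


# -- simulation state ---------------------------------------------------


@dataclass
class YearlyRecord:
    year: int
    prop_anad_total: float
    prop_anad_female: float
    prop_anad_male: float
    eggs_total: int
    spawning_females: int
    productivity: float  # nan when spawning_females == 0
    pop_size_freshwater: int
    pop_size_marine: int
    n_sneakers: int
    n_parasitised_returners: int

    FIELDS = (
        "year",
        "prop_anad_total",
        "prop_anad_female",
        "prop_anad_male",
        "eggs_total",
        "spawning_females",
        "productivity",
        "pop_size_freshwater",
        "pop_size_marine",
        "n_sneakers",
        "n_parasitised_returners",
    )

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}


@dataclass
class SimulationState:
    pop: Population
    grid: HabitatGrid
    mort: MortalityParams
    qual: QualityParams
    sched: ScheduleConstants
    arch: GeneticArchitecture
    cond_means: np.ndarray  # frozen sex-specific condition means, index = sex code
    condition_variance: float
    search_radius: float
    sneaker_on: bool
    sneaker_threshold_ratio: float
    carrying_capacity: int
    rng: np.random.Generator
    week: int = 1
    year: int = 1
    # per-year counters, reset after each yearly record
    eggs_year: int = 0
    spawning_females_year: int = 0
    sneakers_year: int = 0
    parasitised_returners_year: int = 0
    #: per-tactic mating-market tallies from the most recent spawning event
    last_spawning_stats: dict | None = None
    _rates: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.search_radius <= 0:
            raise ValueError(f"search-radius must be > 0, got {self.search_radius}")
        self._rates = _rate_table(self.mort)


def draw_condition(
    sexes: np.ndarray,
    cond_means: np.ndarray,
    condition_variance: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Condition cue at birth: N(frozen sex-specific mean, constant variance).

    The means are the mean liability thresholds of each sex in the
    founding generation, frozen for the whole run, which makes residency
    and anadromy equally likely for both sexes at initialisation.
    """
    if condition_variance < 0:
        raise ValueError("condition variance must be >= 0")
    sexes = np.asarray(sexes)
    return rng.normal(
        np.asarray(cond_means)[sexes], np.sqrt(condition_variance), size=sexes.shape
    )


def decide_tactic(condition, threshold):
    """Resident iff condition strictly exceeds threshold; ties go anadromous."""
    return np.where(np.asarray(condition) > np.asarray(threshold), RESIDENT, ANADROMOUS)


def init_state(
    *,
    mort: MortalityParams,
    qual: QualityParams,
    sched: ScheduleConstants,
    arch: GeneticArchitecture,
    rng: np.random.Generator,
    prop_parasites: float = 0.0,
    allele_frequency: float = 0.5,
    condition_variance: float | None = None,
    search_radius: float = 14.0,
    sneaker_on: bool = True,
    sneaker_threshold_ratio: float = 1.0,
    carrying_capacity: int = 3000,
    initial_population: int = 3000,
) -> SimulationState:
    """Build the founding population and frozen initial-condition means.

    3000 fish, an exact 50:50 sex ratio, ages uniform on 0-4 years, every
    locus at ``allele_frequency``, all starting in fresh water at 230 mm.
    When ``condition_variance`` is None it defaults to the initial
    phenotypic variance of the threshold (V_A + sigma_E^2).
    """
    grid = HabitatGrid.create(prop_parasites, rng)
    n = int(initial_population)
    sexes = np.empty(n, dtype=np.int8)
    sexes[: n // 2] = MALE
    sexes[n // 2 :] = FEMALE
    genomes = genetics.init_genome(allele_frequency, rng, n)
    G = genetics.genetic_values(genomes, sexes, arch)
    thresholds = genetics.threshold_phenotype(G, arch, rng)
    cond_means = np.array(
        [
            float(thresholds[sexes == MALE].mean()),
            float(thresholds[sexes == FEMALE].mean()),
        ]
    )
    if condition_variance is None:
        condition_variance = (
            genetics.expected_additive_variance(allele_frequency) + arch.sigma_e_sq
        )
    conditions = draw_condition(sexes, cond_means, condition_variance, rng)
    tactics = decide_tactic(conditions, thresholds)
    x, y = grid.random_freshwater_patch(rng, n)
    fields = {
        "id": np.arange(n, dtype=np.int64),
        "sex": sexes,
        "age_weeks": rng.integers(0, 4 * sched.weeks_per_year, size=n),
        "habitat": np.full(n, FRESHWATER, dtype=np.int8),
        "tactic": tactics.astype(np.int8),
        "threshold": thresholds,
        "condition": conditions,
        "quality": np.full(n, qual.resident_quality),
        "base_quality": np.full(n, qual.resident_quality),
        "parasitised": np.zeros(n, dtype=bool),
        "sneaking": np.zeros(n, dtype=bool),
        "x": x,
        "y": y,
        "weeks_at_sea": np.zeros(n, dtype=np.int32),
        "times_at_sea": np.zeros(n, dtype=np.int32),
    }
    pop = Population(fields, genomes)
    return SimulationState(
        pop=pop,
        grid=grid,
        mort=mort,
        qual=qual,
        sched=sched,
        arch=arch,
        cond_means=cond_means,
        condition_variance=float(condition_variance),
        search_radius=float(search_radius),
        sneaker_on=bool(sneaker_on),
        sneaker_threshold_ratio=float(sneaker_threshold_ratio),
        carrying_capacity=int(carrying_capacity),
        rng=rng,
    )


# -- weekly processes ---------------------------------------------------


def apply_weekly_mortality(state: SimulationState, weeks: int = 1) -> int:
    """Background mortality + lifespan cap + aging over ``weeks`` identical weeks.

    Survival over k weeks at constant weekly rate p is one Bernoulli draw
    with probability (1-p)^k — distributionally identical to k weekly
    draws because nothing observable happens between them.  Fish at or
    beyond the 8-year lifespan cap (or reaching it within the block) are
    removed regardless of the draw.  Survivors age by ``weeks``.
    """
    pop = state.pop
    idx = pop.alive_indices
    if len(idx) == 0:
        return 0
    p = state._rates[2 * pop.sex[idx].astype(np.intp) + pop.habitat[idx]]
    infested = pop.parasitised[idx] & (pop.habitat[idx] == MARINE)
    if infested.any() and state.mort.parasite_load != 1.0:
        p = np.where(infested, np.minimum(p * state.mort.parasite_load, 1.0), p)
    death_p = 1.0 - (1.0 - p) ** weeks
    over_cap = pop.age_weeks[idx] >= state.mort.max_lifespan_weeks - (weeks - 1)
    dead = over_cap | (state.rng.random(len(idx)) < death_p)
    pop.kill(idx[dead])
    pop.age_weeks[idx[~dead]] += weeks
    return int(dead.sum())


def migrate_to_sea(state: SimulationState) -> np.ndarray:
    """Week 14: anadromous fish aged 2+ move to a random marine patch.

    Landing on a lice-flagged patch infests the fish for the whole
    sojourn.  Returns the migrants' indices.
    """
    pop = state.pop
    idx = pop.alive_indices
    mig = idx[
        (pop.tactic[idx] == ANADROMOUS)
        & (pop.habitat[idx] == FRESHWATER)
        & (pop.age_weeks[idx] >= state.sched.resident_maturity_weeks)
    ]
    if len(mig) == 0:
        return mig
    patches = state.grid.random_marine_patch(state.rng, len(mig))
    pop.habitat[mig] = MARINE
    pop.parasitised[mig] = state.grid.lice_flags[patches]
    pop.weeks_at_sea[mig] = 0
    pop.times_at_sea[mig] += 1
    return mig


def accrue_sea_quality(
    state: SimulationState, weeks: int = 1, exclude: np.ndarray | None = None
) -> None:
    """Weekly sea growth: +gain/82 mm per week, scaled down while infested.

    Fish accrue every week at sea except the arrival week (``exclude`` is
    that week's fresh migrants) and including the return week, so a first
    sojourn accrues exactly 82 weeks and a repeat sojourn exactly 30.
    """
    pop = state.pop
    idx = pop.alive_indices
    at_sea = idx[pop.habitat[idx] == MARINE]
    if exclude is not None and len(exclude):
        at_sea = np.setdiff1d(at_sea, exclude, assume_unique=True)
    if len(at_sea) == 0:
        return
    rate = state.qual.anad_quality_gain / state.sched.first_sojourn_weeks
    gain = np.full(len(at_sea), weeks * rate)
    infested = pop.parasitised[at_sea]
    if infested.any():
        gain[infested] *= 1.0 - state.qual.paras_quality
    pop.quality[at_sea] += gain
    pop.weeks_at_sea[at_sea] += weeks


def return_to_freshwater(state: SimulationState) -> tuple[int, int]:
    """Week 44: fish with a completed sojourn return and shed their lice.

    First-timers return after 82 weeks at sea (the autumn of the year
    after outmigration); repeat spawners after 30 (the same autumn).
    Quality deficits accrued while infested are not restored.  Returns
    ``(n_returners, n_parasitised_returners)``.
    """
    pop = state.pop
    sched = state.sched
    idx = pop.alive_indices
    sea = idx[pop.habitat[idx] == MARINE]
    if len(sea) == 0:
        return 0, 0
    ws = pop.weeks_at_sea[sea]
    first = pop.times_at_sea[sea] == 1
    done = np.where(first, ws >= sched.first_sojourn_weeks, ws >= sched.repeat_sojourn_weeks)
    ret = sea[done]
    if len(ret) == 0:
        return 0, 0
    n_parasitised = int(pop.parasitised[ret].sum())
    x, y = state.grid.random_freshwater_patch(state.rng, len(ret))
    pop.habitat[ret] = FRESHWATER
    pop.x[ret] = x
    pop.y[ret] = y
    pop.parasitised[ret] = False  # lice do not survive fresh water
    return len(ret), n_parasitised


def _mature_masks(state: SimulationState):
    """Indices of mature freshwater males and females at spawning time."""
    pop = state.pop
    sched = state.sched
    idx = pop.alive_indices
    fw = pop.habitat[idx] == FRESHWATER
    age = pop.age_weeks[idx]
    mature = fw & np.where(
        pop.tactic[idx] == RESIDENT,
        age >= sched.resident_maturity_weeks,
        age >= sched.anadromous_maturity_weeks,
    )
    males = idx[mature & (pop.sex[idx] == MALE)]
    females = idx[mature & (pop.sex[idx] == FEMALE)]
    return males, females


def apply_sneaker_tactic(state: SimulationState) -> int:
    """Week 48, before mate choice: frequency-dependent sneaking.

    A mature resident male sneaks when the local ratio of mature
    anadromous to mature resident males (self included in the
    denominator) exceeds the threshold; sneaking temporarily boosts his
    quality.  No-op when the sneaker switch is off.
    """
    if not state.sneaker_on:
        return 0
    pop = state.pop
    males, _ = _mature_masks(state)
    res = males[pop.tactic[males] == RESIDENT]
    if len(res) == 0:
        return 0
    anad = males[pop.tactic[males] == ANADROMOUS]
    r2 = state.search_radius**2
    rx = pop.x[res].astype(np.int32)
    ry = pop.y[res].astype(np.int32)
    # resident-resident neighbour counts (self included via distance 0)
    dx = rx[:, None] - rx[None, :]
    dy = ry[:, None] - ry[None, :]
    n_res = ((dx * dx + dy * dy) <= r2).sum(axis=1)
    if len(anad):
        ax = pop.x[anad].astype(np.int32)
        ay = pop.y[anad].astype(np.int32)
        dx = rx[:, None] - ax[None, :]
        dy = ry[:, None] - ay[None, :]
        n_anad = ((dx * dx + dy * dy) <= r2).sum(axis=1)
    else:
        n_anad = np.zeros(len(res), dtype=np.int64)
    sneak = res[n_anad / n_res > state.sneaker_threshold_ratio]
    if len(sneak):
        pop.base_quality[sneak] = pop.quality[sneak]
        pop.quality[sneak] += state.qual.sneaker_boost
        pop.sneaking[sneak] = True
    return len(sneak)


def reset_sneakers(state: SimulationState) -> None:
    """After reproduction: sneakers restore their pre-boost quality."""
    pop = state.pop
    idx = pop.alive_indices
    s = idx[pop.sneaking[idx]]
    if len(s):
        pop.quality[s] = pop.base_quality[s]
        pop.sneaking[s] = False


def reproduce(state: SimulationState) -> tuple[int, int]:
    """Week 48 spawning.  Returns (total eggs, number of spawning females).

    Each mature freshwater female takes as mates the up-to-5
    highest-quality mature males within the search radius (quality ties
    broken by a random shuffle before sorting).  Fecundity is the
    allometric ``round(alpha * quality^beta)``; each egg survives to fry
    with probability ``surv_rate``; each fry draws a uniformly random
    father from its mother's mates, inherits Mendelianly, and receives
    its lifetime threshold, condition and tactic at birth.
    """
    pop = state.pop
    rng = state.rng
    males, females = _mature_masks(state)
    if len(males) == 0 or len(females) == 0:
        return 0, 0

    # males in random-tie-broken descending quality order
    perm = rng.permutation(len(males))
    order = perm[np.argsort(-pop.quality[males][perm], kind="stable")]
    msort = males[order]

    fx = pop.x[females].astype(np.int32)
    fy = pop.y[females].astype(np.int32)
    mx = pop.x[msort].astype(np.int32)
    my = pop.y[msort].astype(np.int32)
    dx = fx[:, None] - mx[None, :]
    dy = fy[:, None] - my[None, :]
    within = (dx * dx + dy * dy) <= state.search_radius**2
    rank = np.cumsum(within, axis=1)
    sel = within & (rank <= 5)
    n_mates = sel.sum(axis=1)
    spawning = n_mates > 0
    if not spawning.any():
        return 0, 0

    # (n_females, 5) mate table in ranking order
    rows, cols = np.nonzero(sel)
    mate_table = np.zeros((len(females), 5), dtype=np.int64)
    mate_table[rows, rank[rows, cols] - 1] = msort[cols]

    q = pop.quality[females]
    eggs = np.rint(
        state.qual.fecundity_alpha * q**state.qual.fecundity_beta
    ).astype(np.int64)
    eggs[~spawning] = 0
    eggs_total = int(eggs.sum())
    n_spawning = int(spawning.sum())

    fry = rng.binomial(eggs[spawning], state.mort.surv_rate)
    n_fry = int(fry.sum())
    if n_fry == 0:
        return eggs_total, n_spawning

    frow = np.repeat(np.flatnonzero(spawning), fry)  # row in the female arrays
    mothers = females[frow]
    pick = (rng.random(n_fry) * n_mates[frow]).astype(np.int64)
    fathers = mate_table[frow, pick]

    # per-tactic mating-market diagnostics (not part of the yearly record)
    father_tactics = pop.tactic[fathers]
    state.last_spawning_stats = {
        "mature_males_resident": int((pop.tactic[males] == RESIDENT).sum()),
        "mature_males_anadromous": int((pop.tactic[males] == ANADROMOUS).sum()),
        "fry_sired_resident": int((father_tactics == RESIDENT).sum()),
        "fry_sired_anadromous": int((father_tactics == ANADROMOUS).sum()),
        "mature_females_resident": int((pop.tactic[females] == RESIDENT).sum()),
        "mature_females_anadromous": int((pop.tactic[females] == ANADROMOUS).sum()),
    }

    genomes = genetics.inherit(pop.genomes[mothers], pop.genomes[fathers], rng)
    sexes = rng.integers(0, 2, size=n_fry).astype(np.int8)
    G = genetics.genetic_values(genomes, sexes, state.arch)
    thresholds = genetics.threshold_phenotype(G, state.arch, rng)
    conditions = draw_condition(sexes, state.cond_means, state.condition_variance, rng)
    tactics = decide_tactic(conditions, thresholds)
    x, y = state.grid.random_freshwater_patch(rng, n_fry)
    fields = {
        "sex": sexes,
        "age_weeks": np.zeros(n_fry, dtype=np.int32),
        "habitat": np.full(n_fry, FRESHWATER, dtype=np.int8),
        "tactic": tactics.astype(np.int8),
        "threshold": thresholds,
        "condition": conditions,
        "quality": np.full(n_fry, state.qual.resident_quality),
        "base_quality": np.full(n_fry, state.qual.resident_quality),
        "parasitised": np.zeros(n_fry, dtype=bool),
        "sneaking": np.zeros(n_fry, dtype=bool),
        "x": x,
        "y": y,
        "weeks_at_sea": np.zeros(n_fry, dtype=np.int32),
        "times_at_sea": np.zeros(n_fry, dtype=np.int32),
    }
    pop.append(fields, genomes)
    return eggs_total, n_spawning


def density_dependent_cull(state: SimulationState) -> int:
    """Remove random surplus newborns until the river is back at capacity.

    Only this year's age-0 fry are ever culled — they cannot outcompete
    older fish — so the freshwater count may exceed the carrying capacity
    when older fish alone exceed it.
    """
    pop = state.pop
    idx = pop.alive_indices
    fw = idx[pop.habitat[idx] == FRESHWATER]
    excess = len(fw) - state.carrying_capacity
    if excess <= 0:
        return 0
    newborns = fw[pop.age_weeks[fw] == 0]
    n_cull = min(excess, len(newborns))
    if n_cull == 0:
        return 0
    cull = state.rng.choice(newborns, size=n_cull, replace=False)
    pop.kill(cull)
    return n_cull


def make_yearly_record(state: SimulationState) -> YearlyRecord:
    pop = state.pop
    idx = pop.alive_indices
    adults = idx[pop.age_weeks[idx] >= state.sched.resident_maturity_weeks]
    anad = pop.tactic[adults] == ANADROMOUS

    def prop(mask: np.ndarray) -> float:
        return float(anad[mask].mean()) if mask.any() else 0.0

    n_adults = len(adults)
    sex = pop.sex[adults]
    prod = (
        state.eggs_year / state.spawning_females_year
        if state.spawning_females_year
        else float("nan")
    )
    return YearlyRecord(
        year=state.year,
        prop_anad_total=float(anad.mean()) if n_adults else 0.0,
        prop_anad_female=prop(sex == FEMALE),
        prop_anad_male=prop(sex == MALE),
        eggs_total=state.eggs_year,
        spawning_females=state.spawning_females_year,
        productivity=prod,
        pop_size_freshwater=int((pop.habitat[idx] == FRESHWATER).sum()),
        pop_size_marine=int((pop.habitat[idx] == MARINE).sum()),
        n_sneakers=state.sneakers_year,
        n_parasitised_returners=state.parasitised_returners_year,
    )


def _spawning_block(state: SimulationState) -> None:
    state.sneakers_year = apply_sneaker_tactic(state)
    eggs, spawners = reproduce(state)
    state.eggs_year = eggs
    state.spawning_females_year = spawners
    reset_sneakers(state)
    density_dependent_cull(state)
    state.pop.compact()


def step_week(state: SimulationState) -> YearlyRecord | None:
    """Advance exactly one week; returns the yearly record at week 52.

    Within-week order: mortality/aging, outmigration (week 14), sea
    growth, return (week 44), sneaking -> spawning -> sneaker reset ->
    cull (week 48), record (week 52).
    """
    sched = state.sched
    week = state.week
    apply_weekly_mortality(state, 1)
    migrants = None
    if week == sched.migration_week:
        migrants = migrate_to_sea(state)
    accrue_sea_quality(state, 1, exclude=migrants)
    if week == sched.return_week:
        _, n_par = return_to_freshwater(state)
        state.parasitised_returners_year = n_par
    if week == sched.spawning_week:
        _spawning_block(state)
    record = None
    if week == sched.weeks_per_year:
        record = make_yearly_record(state)
        state.week = 1
        state.year += 1
        state.eggs_year = 0
        state.spawning_females_year = 0
        state.sneakers_year = 0
        state.parasitised_returners_year = 0
    else:
        state.week = week + 1
    return record


def _advance(state: SimulationState, weeks: int) -> None:
    apply_weekly_mortality(state, weeks)
    accrue_sea_quality(state, weeks)
    state.week += weeks


def advance_year(state: SimulationState) -> YearlyRecord:
    """Advance one full year with the uneventful weeks aggregated.

    Produces the same process distribution as 52 :func:`step_week` calls
    (only the order in which random numbers are consumed differs).
    """
    sched = state.sched
    assert state.week == 1, "advance_year must start at week 1"
    _advance(state, sched.migration_week - 1)  # weeks 1..13
    apply_weekly_mortality(state, 1)  # week 14
    migrants = migrate_to_sea(state)
    accrue_sea_quality(state, 1, exclude=migrants)
    state.week += 1
    _advance(state, sched.return_week - sched.migration_week - 1)  # weeks 15..43
    apply_weekly_mortality(state, 1)  # week 44
    accrue_sea_quality(state, 1)
    _, n_par = return_to_freshwater(state)
    state.parasitised_returners_year = n_par
    state.week += 1
    _advance(state, sched.spawning_week - sched.return_week - 1)  # weeks 45..47
    apply_weekly_mortality(state, 1)  # week 48
    accrue_sea_quality(state, 1)
    _spawning_block(state)
    state.week += 1
    _advance(state, sched.weeks_per_year - sched.spawning_week - 1)  # weeks 49..51
    apply_weekly_mortality(state, 1)  # week 52
    accrue_sea_quality(state, 1)
    record = make_yearly_record(state)
    state.week = 1
    state.year += 1
    state.eggs_year = 0
    state.spawning_females_year = 0
    state.sneakers_year = 0
    state.parasitised_returners_year = 0
    return record
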