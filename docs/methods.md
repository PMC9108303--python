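# troutmig: model description and methods

## Scope and intent

`troutmig` simulates the eco-evolutionary dynamics of a facultatively
anadromous brown trout population in which the migration decision is governed
by an environmentally cued threshold trait with a shared, sex-specifically
expressed genetic basis. The model is an individual-based system with a
weekly clock; population genetics, demography and behaviour all emerge from
per-fish rules. It is intended for scenario exploration (how do intersex
genetic correlations, marine mortality and parasite pressure reshape tactic
frequencies and egg production?), not for forecasting any particular river
system.

## Entities and state

Each trout carries: sex; age in weeks; habitat (freshwater or marine);
lifetime tactic (resident/anadromous); the liability threshold *z*; the
condition cue *c*; quality (body length, mm); parasite and sneaking flags; a
diploid 20-locus genome; a freshwater patch position; and sojourn counters.
The world is two 100 × 50 grids of square patches (5000 patches per region)
with plain Euclidean distance and no wrap-around; a fixed, random
`prop-parasites` fraction of marine patches carries sea lice (exactly
`round(prop × 5000)` patches, sampled without replacement at initialisation).
Freshwater has a carrying capacity of 3000 fish.

## Genetics

Twenty unlinked, biallelic, equal-effect additive loci. Inheritance is
Mendelian with free recombination: at each locus the offspring receives one
uniformly chosen allele from each parent, the father being drawn uniformly
from the mother's mate list. There is no mutation — evolution proceeds purely
by allele-frequency change, so very long runs can exhaust additive variance.

Sex-specific architecture: the effects of the first `n-loci` loci (a fixed
prefix, for reproducibility) are multiplied by −1 when expressed in a male.
The expected intersex genetic correlation of the trait is
(20 − 2·`n-loci`)/40, i.e. +0.5 / 0 / −0.5 at 0 / 10 / 20 flipped loci.
The pair-based estimator (`estimate_intersex_correlation`) is a Pearson
correlation of opposite-sex parent–offspring genetic values; the pair
simulator centres father–daughter and mother–son pairs on their own means
before pooling, because the two pair types have different mean *G* whenever
loci are sign-flipped and the uncentred pooled correlation would otherwise be
dominated by that between-group contrast rather than by transmission.

## Threshold trait and tactic choice

Threshold *z* = *G* + *e* with *e* ~ N(0, σ²_E) drawn once at birth and
never redrawn. Condition *c* is non-heritable, drawn once at birth from
N(μ_sex, σ²_C) where μ_sex is the mean threshold of that sex in the founding
generation, frozen for the whole run — this makes residency and anadromy
equally likely for both sexes at initialisation, for any `n-loci`. A fish
becomes resident iff *c* > *z* (ties go to anadromy; "exceeds" is read
strictly). Defaults: initial allele frequency 0.5 at every locus, σ²_E =
V_A(init) = 10 (giving liability *h*² = 0.5 in generation 1; recomputed
automatically if the initial frequency is changed), and σ²_C = V_A + σ²_E
= 20, i.e. the cue has the same variance as the threshold it is compared
against. The σ²_C choice is a package decision (the cue's scale is otherwise
unidentified); it sets the sensitivity of tactic frequencies to threshold
evolution and is config-exposed (`condition-variance`).

## Weekly schedule

Within a week, in order: (1) mortality and aging; (2) week 14: all
anadromous fish aged ≥ 2 years move to a uniformly random marine patch and
become infested if the patch carries lice (exposure is decided once, at
arrival; repeat spawners re-roll on each outmigration); (3) sea growth;
(4) week 44: fish with completed sojourns return to a random freshwater
patch and shed all lice (growth already lost is not restored); (5) week 48:
sneaker decision → spawning → sneaker reset → density-dependent cull;
(6) week 52: the yearly record.

Sea growth is 200/82 mm per week at sea, counted every week except the
arrival week and including the return week: a first-time migrant (out week
14, back week 44 of the following year) accrues exactly 82 weeks (+200 mm,
returning at 430 mm), a repeat spawner exactly 30 (+73.2 mm). Infested fish
accrue at the factor (1 − `paras_quality`).

## Mortality

Weekly probabilities compose multiplicatively: males in fresh water die at
`mortalityM` (default 0.01543, which makes egg-to-migration survival
0.10 × (1 − 0.01543)¹²² ≈ 1.5%); male marine mortality is `mortalityM ×
anad-death-multiplierM` (default 1.262 ⇒ 82-week marine survival ≈ 20%).
Female rates scale from the male freshwater baseline: freshwater
`mortalityM × mortalityF`, marine `mortalityM × mortalityF ×
anad-death-multiplierF` — each sex's marine multiplier is the ratio of that
sex's marine to freshwater mortality, which is the axis swept in the
female-mortality experiment. Infested fish at sea multiply further by
`parasite-load`. Probabilities are clamped at 1 after composition. Egg-to-fry
survival is `SurvRate` = 0.10, applied at egg creation; the lifespan cap is
8 years (416 weeks). The density-dependent cull removes uniformly random
age-0 fry until the freshwater count is back at 3000 — never older fish, so
the count may briefly exceed capacity when older fish alone exceed it.

## Reproduction and sneaking

Week-48 maturity: residents from age 2; anadromous fish from age 3 *and*
only when in fresh water (first-timers are at sea through their third
autumn, so they first spawn at age 4 — delayed maturity is the intrinsic
cost of anadromy). Each mature female mates with the up-to-5 highest-quality
mature males within the search radius (quality ties shuffled before
sorting); with no male in radius she does not spawn. Fecundity is
`round(α · quality^β)` eggs; each fry draws its father uniformly from the
mother's mates. Before mate choice, each mature resident male whose local
ratio of mature anadromous to mature resident males (self included in the
denominator) exceeds 1.0 temporarily adds +250 mm to its quality ("sneaker"),
outranking unparasitised anadromous rivals; the boost is reverted after
spawning. The sneaker switch, threshold and boost are config-exposed.

## Calibration

Two parameters of the mating/fecundity submodel are not identified by the
life-history values above and were calibrated jointly, once, against the
model's defining baseline property — that with a strongly positive intersex
correlation (`n-loci` = 0) and marine multipliers ≈ 1.26 for both sexes the
population sits at a stable ~50:50 anadromy:residency split, with females
alone selected toward anadromy and males alone toward residency (`n-loci` =
10). That pins the fecundity exponent **β = 3.5** (α = 100/230^3.5, so a
230 mm resident female produces ~100 eggs) and the **search radius = 14
patches**. The two knobs act on different sexes: β sets the size-fecundity
premium that makes anadromy pay for females, while the radius sets the
number of males competing per female and hence how strongly a 430 mm male
out-competes 230 mm residents (at radius 14, roughly 15–25 mature males fall
within a female's circle, making the anadromous per-season siring advantage
offset — but not exceed — the survival-and-delay cost of anadromy for
males). Flatter β or smaller radii collapse the baseline to residency;
steeper β or larger radii flip it to anadromy or invert the sexes' roles.

## Experiments

Four factorial designs are packaged as presets (750-year runs; equilibrium
summaries are medians over years 601–750; 50 replicates by default, fewer
for desk-scale work): **exp1** baseline (multipliers 1.264 both sexes,
sneaking on, `n-loci` ∈ {0, 10, 20}); **exp2** no marine mortality cost
(multipliers 1, `n-loci` 0–20 step 2, sneaking on/off; 22 scenarios);
**exp3** female-specific marine mortality (male multiplier 1, female
multiplier 8 values evenly spaced over [1.1, 2.0], `n-loci` ∈ {0, 10, 20};
24 scenarios); **exp4** sea lice (`prop-parasites` {0.1, 0.4, 0.6} ×
`paras_quality` {0.4, 0.8} × `parasite-load` {1, 1.25, 1.6} × `n-loci`
{0, 10, 20}; 54 scenarios). Replicates get independent random streams
(`SeedSequence([base, scenario, replicate])`); every summary row records its
seed. The equilibrium window is fixed, not adaptively detected.

## Numerics and performance

Two drivers share all event code. `step_week` is the reference single-week
scheduler. `advance_year` aggregates the uneventful stretches between event
weeks: survival over k identical weeks is drawn as one Bernoulli with
probability (1 − p)^k, aging and sea growth advance by k — distributionally
identical to k weekly steps because no observable or state-coupled event
occurs inside a block (a statistical-equivalence test compares the two). A
750-year run takes a few seconds on one CPU. The population is a
struct-of-arrays with an alive mask; dead rows are reclaimed yearly. The
desk-scale problem sizes used by the test suite and the acceptance script —
3 replicates per scenario instead of 50 — were chosen as the smallest
replication at which the equilibrium medians are stable to within a few
percent.

## What the tests do and do not show

The test suite verifies exact identities (Mendelian segregation, survival
calibration, the 430 mm agent trace, sojourn accounting), estimator
behaviour (heritability, intersex-correlation sign pattern), structural
invariants (no resident at sea, cull spares older fish, no resurrection,
sex symmetry when all asymmetries are disabled) and the equilibrium outcomes
of the four experiments at reduced replication. All of this concerns the
model's internal consistency and its published behaviour under its own
assumptions; it says nothing about any real river's dynamics. Known
simplifications: no mutation, no tactic switching, no variation in smolt age
or sea-sojourn duration, no marine density dependence, no extra
repeat-spawner mortality, no within-river movement or network topology, no
heritable condition, and a purely additive genetic architecture (no
dominance, epistasis, linkage or large-effect loci). The 8 female marine
multipliers of exp3 are evenly spaced because only the range and count of
the sweep are fixed by the design.
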