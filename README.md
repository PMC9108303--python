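# troutmig

A genetically explicit, agent-based eco-evolutionary simulator of **partial
migration** in brown trout (*Salmo trutta*): every fish carries a heritable
liability threshold that, compared against an environmentally drawn condition
cue at birth, decides between lifelong freshwater **residency** and sea
migration (**anadromy**). The package is aimed at evolutionary ecologists and
fisheries scientists studying how **intralocus sexual conflict** — a shared
genetic basis for a trait under opposing selection in males and females —
shapes migration-tactic evolution, population productivity, and responses to
marine stressors such as sea lice.

## The model in brief

**Trait and genetics.** The condition threshold is controlled by 20 unlinked,
biallelic, purely additive loci. An individual's additive genetic value is
*G* = Σ<sub>ℓ</sub> *g*<sub>ℓ</sub> with per-locus genotypic values
*g*<sub>ℓ</sub> ∈ {0, 1, 2}; the threshold phenotype is *z* = *G* + *e*,
*e* ~ N(0, σ²<sub>E</sub>). Sex-specific expression multiplies the effect of
the first *n* loci (`n-loci`, 0–20) by −1 in males, which moves the intersex
genetic correlation *r*<sub>G</sub> (father–daughter / mother–son *G*) from
+0.5 through 0 (*n* = 10) to −0.5 (*n* = 20). At an initial allele frequency
of 0.5, V<sub>A</sub> = 20 · 2*p*(1−*p*) = 10 and σ²<sub>E</sub> = 10 gives
liability heritability *h*² = 0.5 in generation 1.

**Tactic choice (environmentally cued threshold model).** A fish becomes
resident iff its condition *c* (drawn once at birth from a sex-specific
normal whose mean is frozen at the founding generation's mean threshold)
strictly exceeds *z*; otherwise anadromous. Tactics are fixed for life.

**Life cycle (weekly time step).** Sex- and habitat-specific background
mortality every week; anadromous fish aged 2+ migrate to sea at week 14, gain
200 mm of "quality" (body length) over an 82-week first sojourn (so
first-time spawners return at 230 + 200 = 430 mm), return at week 44, and
spawn annually thereafter with 30-week sea sojourns. Marine patches can carry
sea lice: infested fish suffer extra marine mortality (`parasite-load`) and
reduced growth (`paras_quality`). Spawning at week 48: each mature female
takes up to five highest-quality mates within a search radius, produces
`round(α · quality^β)` eggs, 10% of eggs become fry, and each fry draws a
random father from its mother's mates. Resident males can adopt a
frequency-dependent **sneaker** tactic when locally outnumbered by anadromous
males. A density-dependent cull removes surplus newborns above the freshwater
carrying capacity of 3000.

## Worked example

```python
from troutmig import ScenarioConfig, run_scenario, summarize

cfg = ScenarioConfig(n_loci=20, anad_death_multiplierM=1.264,
                     anad_death_multiplierF=1.264, duration_years=300, seed=1)
records = run_scenario(cfg)
print(summarize(records, 251, 300))
```

prints (values from this exact run):

```
{'median_prop_anad_total': 0.4713..., 'median_prop_anad_female': 0.9416...,
 'median_prop_anad_male': 0.0482..., 'median_eggs_total': 49877.5,
 'median_productivity': 960.17..., 'n_undefined_productivity': 0}
```

Under a strongly negative intersex correlation (`n_loci=20`) females evolve
to ~94% anadromy while males become ~95% resident within 300 years: selection
toward opposite tactic optima is mutually reinforcing when the correlation is
negative. Median egg production (~50,000/yr) is correspondingly higher than
in the genetically "locked" `n_loci=0` scenario (~41,000/yr), because large
anadromous females are the fecund ones. The `examples/` directory holds one
short narrative script per capability (genetics estimators, survival
calibration identities, sexual-conflict scenarios, sea-lice pressure).

A thin CLI wraps the same machinery:

```bash
troutmig run --config my_scenario.yaml --out out/run1
troutmig experiment --preset exp2 --replicates 5 --out out/exp2
troutmig summarize --in out
```

Config files are flat YAML using the model's parameter names
(`mortalityM`, `anad-death-multiplierF`, `n-loci`, `prop-parasites`, ...);
unknown keys are rejected. Every output directory receives a `manifest.json`
from which the run can be reproduced bit-for-bit.

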