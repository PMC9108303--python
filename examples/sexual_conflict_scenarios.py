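"""Sexual conflict in action: three intersex-correlation scenarios.

Runs the baseline preset (marine multiplier 1.264 for both sexes,
sneaking enabled) at n-loci = 0, 10 and 20 for 300 years and prints the
sex-specific anadromy trajectories.  With a strongly positive rG
(n-loci = 0) the sexes are locked together and neither evolves; as rG
drops to zero and then negative, females escape toward anadromy and
males toward residency, and total egg production rises with the
proportion of (large, fecund) anadromous females.

Runs in about 10 s; use duration_years=750 for equilibrium figures.
"""

from troutmig import ScenarioConfig, run_scenario, summarize
from troutmig.experiments import records_to_frame

for n_loci in (0, 10, 20):
    cfg = ScenarioConfig(
        n_loci=n_loci,
        anad_death_multiplierM=1.264,
        anad_death_multiplierF=1.264,
        sneaker_on=True,
        duration_years=300,
        seed=1,
    )
    df = records_to_frame(run_scenario(cfg))
    s = summarize(df, 251, 300)
    print(f"\nn-loci = {n_loci} (rG {'+' if n_loci == 0 else '~0' if n_loci == 10 else '-'}):")
    for year in (50, 150, 300):
        r = df[df.year == year].iloc[0]
        print(
            f"  year {year:3d}: anadromy F={r.prop_anad_female:.2f} "
            f"M={r.prop_anad_male:.2f}  eggs={r.eggs_total:7.0f}"
        )
    print(
        f"  median over years 251-300: F={s['median_prop_anad_female']:.2f} "
        f"M={s['median_prop_anad_male']:.2f} eggs={s['median_eggs_total']:.0f}"
    )
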