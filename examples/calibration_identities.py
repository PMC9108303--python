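"""Survival calibration identities of the default parameterization.

The default weekly mortalities are calibrated so that (i) about 1.5% of
eggs survive to the seaward migration 122 weeks later (including 10%
egg-to-fry survival) and (ii) about 20% of smolts survive the 82-week
first sea sojourn, and a first-time anadromous spawner returns at
230 + 200 = 430 mm.
"""

from troutmig import stage_survival

m_fw = 0.01543          # male freshwater weekly mortality
mult_m = 1.262          # male marine multiplier (calibration value)

egg_to_migration = 0.10 * stage_survival(m_fw, 122)
print(f"egg -> seaward migration survival (122 wk): {egg_to_migration:.4f}  (~0.015)")

smolt_to_return = stage_survival(m_fw * mult_m, 82)
print(f"smolt -> return survival (82 wk at sea):    {smolt_to_return:.4f}  (~0.20)")

size = 230.0 + 82 * (200.0 / 82)
print(f"first-time anadromous spawner size:         {size:.0f} mm   (230 + 200)")
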