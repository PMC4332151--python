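"""Warm-temperature scenarios: PIF4/ATHB2 at 28 C and FT at 27 C in long days.

Warmth weakens EC repression of PIF4 (earlier pre-dawn rise, higher night
levels, 3-4x ATHB2 at dawn) and adds a uniform FT activation (2-3x FT AUC,
CO unchanged), reproducing the distinct temperature routes of the two
pathways.

Writes results/temperature_response.tsv.
"""

from pathlib import Path

import pandas as pd

import photoclock as pc
from photoclock import benchmarks

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

p = pc.default_parameters()

rows = []
for temp in ("reference_22C", "warm_27C", "warm_28C"):
    pt = pc.apply_temperature(p, pc.SCENARIOS[temp])
    env = pc.Environment.make(16, temperature=temp)
    r = pc.simulate(pt, env, days=1)
    for sp in ("PIF4_m", "ATHB2_m", "FT_m", "CO_m"):
        ts = pc.from_simulation(r, sp)
        rows.append({"temperature": temp, "species": sp,
                     "dawn_value": float(ts.value[0]), "auc": pc.auc(ts)})
df = pd.DataFrame(rows)
df.to_csv(OUT / "temperature_response.tsv", sep="\t", index=False)

print(f"PIF4 pre-dawn rise: 22C at ZT{benchmarks.pif4_predawn_rise(p, 'reference_22C'):.1f}, "
      f"28C at ZT{benchmarks.pif4_predawn_rise(p, 'warm_28C'):.1f} "
      f"(advance {benchmarks.pif4_rise_advance_warm(p):.1f} h)")
print(f"ATHB2 dawn fold-change 28C/22C: {benchmarks.athb2_dawn_fold_warm(p):.2f}")
print(f"FT AUC fold-change 27C/22C:    {benchmarks.ft_auc_fold_warm(p):.2f}")

co = df[(df.species == "CO_m")].set_index("temperature")["auc"]
print(f"CO AUC 27C/22C: {co['warm_27C']/co['reference_22C']:.3f} "
      "(CO is temperature-insensitive; the FT response is CO-independent)")
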