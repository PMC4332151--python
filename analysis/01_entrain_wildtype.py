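"""Entrain the wild-type model in short, neutral and long days and tabulate
the peak phases of the core clock and output transcripts.

Writes results/wt_trajectories.tsv and results/wt_phases.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import photoclock as pc
from photoclock import io as pio
from photoclock.simulate import last_cycle

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

REPORT_SPECIES = ["LHY_m", "PRR9_m", "TOC1_m", "ELF4_m", "EC", "GI_m",
                  "FKF1_m", "CDF1_m", "CDF1_p", "CO_m", "CO_p", "FT_m",
                  "PIF4_m", "PIF_p", "ATHB2_m", "IAA29_m"]

p = pc.default_parameters()
rows, frames = [], []
for hours in (8, 12, 16):
    env = pc.Environment.make(hours)
    r = pc.simulate(p, env, days=1)
    zt, X = last_cycle(r)
    label = env.light.photoperiod.label
    print(f"{label}: entrained in {r.solver_report.entrain_cycles} cycles "
          f"(residual {r.solver_report.entrain_residual:.1e})")
    for sp in REPORT_SPECIES:
        ts = pc.from_simulation(r, sp)
        rows.append({"photoperiod": label, "species": sp,
                     "peak_zt": round(pc.peak_time(ts), 2),
                     "peak_value": float(ts.value.max()),
                     "mean": float(ts.value.mean())})
    df = r.to_frame()
    df.insert(0, "photoperiod", label)
    frames.append(df)

pd.concat(frames, ignore_index=True).to_csv(
    OUT / "wt_trajectories.tsv", sep="\t", index=False)
phases = pd.DataFrame(rows)
phases.to_csv(OUT / "wt_phases.tsv", sep="\t", index=False)

w = phases.pivot(index="species", columns="photoperiod", values="peak_zt")
print("\nPeak phases (ZT):")
print(w.loc[REPORT_SPECIES].to_string())
print("\nKey anchors: CCA1/LHY mRNA peaks at dawn; GI/FKF1 peak ZT~9-10 in "
      "10L; EC activity peaks early night; FT peaks ~ZT16 in long days.")
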