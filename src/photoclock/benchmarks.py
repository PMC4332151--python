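"""Headline model behaviours, each computed from scratch by simulation.

These are the quantitative claims the calibrated model makes about wild-type
Arabidopsis under standard photoperiod/temperature protocols; every function
entrains the model and measures the stated quantity on the final cycle.
"""

from __future__ import annotations

import numpy as np

from .environment import Environment, SCENARIOS, apply_temperature
from .genotypes import WT, genotype as get_genotype
from .observables import auc, from_simulation, peak_time, phase_advance
from .parameters import ParameterSet
from .simulate import simulate


def _run(p: ParameterSet, hours: float, temperature: str = "reference_22C",
         genotype: str = "WT"):
    pt = apply_temperature(p, SCENARIOS[temperature])
    env = Environment.make(hours, temperature=temperature)
    return simulate(pt, env, get_genotype(genotype), days=1)


def daytime_pif_vs_sd_peak(p: ParameterSet) -> float:
    """Max daytime (ZT0-16) PIF protein in entrained 16L:8D wild type, as a
    percentage of the full-cycle PIF protein peak in 8L:16D."""
    ld = from_simulation(_run(p, 16), "PIF_p")
    sd = from_simulation(_run(p, 8), "PIF_p")
    day = ld.zt <= 16.0
    return 100.0 * float(ld.value[day].max()) / float(sd.value.max())


def athb2_dawn_fold_warm(p: ParameterSet) -> float:
    """ATHB2 mRNA at dawn (ZT0), warm 28 C scenario over reference, 16L:8D."""
    ref = from_simulation(_run(p, 16), "ATHB2_m")
    warm = from_simulation(_run(p, 16, "warm_28C"), "ATHB2_m")
    return float(warm.value[0] / ref.value[0])


def ft_peak_advance_cca1lhy(p: ParameterSet, hours: float = 10.0) -> float:
    """Circular advance (h) of the FT mRNA peak in cca1;lhy vs WT, short days."""
    wt = from_simulation(_run(p, hours), "FT_m")
    mu = from_simulation(_run(p, hours, genotype="cca1;lhy"), "FT_m")
    return phase_advance(mu, wt)


def pif4_predawn_rise(p: ParameterSet, temperature: str,
                      hours: float = 16.0) -> float:
    """Night-time ZT at which PIF4 mRNA first exceeds half its cycle maximum
    while rising toward dawn, in entrained 16L:8D."""
    ts = from_simulation(_run(p, hours, temperature), "PIF4_m")
    zt, m = ts.zt, ts.value
    half = 0.5 * float(m.max())
    night = (zt >= hours) & (zt < 24.0)
    idx = np.where(night)[0]
    if len(idx) == 0:
        return float("nan")
    trough = idx[int(np.argmin(m[idx]))]
    rising = idx[idx >= trough]
    crossed = rising[m[rising] >= half]
    return float(zt[crossed[0]]) if len(crossed) else float("nan")


def pif4_rise_advance_warm(p: ParameterSet) -> float:
    """Hours by which the warm (28 C) scenario advances the PIF4 pre-dawn rise."""
    return (pif4_predawn_rise(p, "reference_22C")
            - pif4_predawn_rise(p, "warm_28C"))


def ft_auc_fold_warm(p: ParameterSet) -> float:
    """Fold-increase of WT FT mRNA AUC (one cycle) at the 27 C scenario vs
    reference, 16L:8D."""
    ref = from_simulation(_run(p, 16), "FT_m")
    warm = from_simulation(_run(p, 16, "warm_27C"), "FT_m")
    return auc(warm) / auc(ref)
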