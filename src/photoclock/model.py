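"""The coupled ODE system: circadian clock -> flowering and elongation outputs.

Topology
--------
Clock (repressilator-style, entrained by light):
  * CCA1/LHY (pooled): light-activated at dawn, repressed by the PRR/TOC1 pool.
  * PRR wave: CCA1/LHY activates PRR9 (also acutely light-induced, EC-repressed);
    PRR9 -> PRR7 -> PRR5 activation chain; TOC1 is an evening gene (CCA1/LHY- and
    EC-repressed) with ZTL-style dark protein turnover.
  * Evening complex: ELF3, ELF4, LUX are CCA1/LHY- and EC-repressed; their
    proteins assemble into the EC (suppressed by GI); the EC represses PRR9,
    TOC1, GI/FKF1 and the PIF4/PIF5 promoters.
  * GI: CCA1/LHY- and EC-repressed, acutely light-activated; protein is
    dark-degraded and forms the blue-light GI-FKF1 complex.

Flowering output:
  * FKF1 transcription mirrors GI; CDF1 is activated by CCA1/LHY and repressed
    by the PRRs.  CDF1 protein is degraded by the GI-FKF1 complex and, FKF1-
    independently, by GI.  CDF1 represses CO and FT transcription; CO protein
    is dark-degraded and FKF1-stabilised in light, activating FT in a classic
    external-coincidence gate.  PIFs co-activate FT only through a CO-gated
    (hence light/daytime-restricted) term; warm temperature adds a uniform
    activation of FT.

Elongation output:
  * PIF4/PIF5 transcription is repressed by EC activity, read out from the
    leading ELF3*ELF4*LUX assembly signal (~2 h phase advance over the EC
    pool).  The pooled PIF protein is degraded by active phyB (photoactivated,
    slow dark reversion) and competitively inhibited by light-made
    "Interactor" proteins.  Active PIF drives ATHB2, IAA29 and the two
    PIF-induced cluster transcripts, and represses four cluster transcripts.

Non-negativity is structural: every production term is non-negative and every
loss term is proportional to its own species.
"""

from __future__ import annotations

import math

import numpy as np

from .environment import Environment
from .genotypes import Genotype, apply_genotype
from .parameters import ParameterSet
from .registry import N_SPECIES, SPECIES_INDEX

__all__ = ["rhs", "make_rhs", "ec_activity"]


def make_rhs(p: ParameterSet, env: Environment):
    """Compile the right-hand side for a fixed parameter set and environment.

    Returns ``f(t, x) -> dx/dt`` suitable for ``scipy.integrate.solve_ivp``.
    """
    n = p.as_namespace()
    light = env.light  # LightFunction, callable

    def f(t: float, x: np.ndarray) -> np.ndarray:
        (LHY_m, LHY_p, PRR9_m, PRR9_p, PRR7_m, PRR7_p, PRR5_m, PRR5_p,
         TOC1_m, TOC1_p, ELF3_m, ELF3_p, ELF4_m, ELF4_p, LUX_m, LUX_p,
         EC, GI_m, GI_p, CDF1_m, CDF1_p, FKF1_m, FKF1_p, GIFKF1,
         CO_m, CO_p, FT_m, PIF4_m, PIF5_m, PIF_p, INT_p, PHYB_a,
         ATHB2_m, IAA29_m, CL1_m, CL2_m, R1_m, R2_m, R3_m, R4_m) = x

        L = light(t)
        D = 1.0 - L

        dx = np.empty(N_SPECIES)

        # --- clock: CCA1/LHY ---
        prr_pool = PRR9_p + PRR7_p + PRR5_p + TOC1_p
        rep = (prr_pool / n.k_lhy_prr) ** 2
        dx[0] = (n.v_lhy * (1.0 + n.a_lhy_light * L) / (1.0 + rep)
                 + n.ox_lhy - n.d_lhy_m * LHY_m)
        dx[1] = n.p_lhy * LHY_m - n.d_lhy_p * LHY_p

        # --- clock: PRR9 -> PRR7 -> PRR5 wave ---
        act9 = LHY_p * LHY_p / (n.k_prr9_lhy ** 2 + LHY_p * LHY_p)
        dx[2] = (n.v_prr9 * (n.b_prr9 + n.a_prr9_light * L) * act9
                 / (1.0 + (EC / n.k_prr9_ec) ** 2)
                 + n.ox_prr9 - n.d_prr9_m * PRR9_m)
        dx[3] = n.p_prr9 * PRR9_m - n.d_prr9_p * PRR9_p

        act7 = PRR9_p * PRR9_p / (n.k_prr7_prr9 ** 2 + PRR9_p * PRR9_p)
        dx[4] = n.v_prr7 * act7 + n.ox_prr7 - n.d_prr7_m * PRR7_m
        dx[5] = n.p_prr7 * PRR7_m - n.d_prr7_p * (1.0 + n.m_prr7_dark * D) * PRR7_p

        act5 = PRR7_p * PRR7_p / (n.k_prr5_prr7 ** 2 + PRR7_p * PRR7_p)
        dx[6] = n.v_prr5 * act5 + n.ox_prr5 - n.d_prr5_m * PRR5_m
        dx[7] = n.p_prr5 * PRR5_m - n.d_prr5_p * (1.0 + n.m_prr5_dark * D) * PRR5_p

        # --- clock: TOC1 ---
        dx[8] = (n.v_toc1 / (1.0 + (LHY_p / n.k_toc1_lhy) ** 2)
                 / (1.0 + (EC / n.k_toc1_ec) ** 2)
                 + n.ox_toc1 - n.d_toc1_m * TOC1_m)
        dx[9] = n.p_toc1 * TOC1_m - n.d_toc1_p * (1.0 + n.m_toc1_dark * D) * TOC1_p

        # --- clock: evening complex genes ---
        ev_act = 1.0 / (1.0 + (LHY_p / n.k_ev_lhy) ** 2) / (1.0 + (EC / n.k_ev_ec) ** 2)
        dx[10] = n.v_elf3 * ev_act + n.ox_elf3 - n.d_elf3_m * ELF3_m
        dx[11] = n.p_elf3 * ELF3_m - n.d_elf3_p * ELF3_p
        dx[12] = n.v_elf4 * ev_act + n.ox_elf4 - n.d_elf4_m * ELF4_m
        dx[13] = n.p_elf4 * ELF4_m - n.d_elf4_p * ELF4_p
        dx[14] = n.v_lux * ev_act + n.ox_lux - n.d_lux_m * LUX_m
        dx[15] = n.p_lux * LUX_m - n.d_lux_p * LUX_p

        assembly = (n.c_ec * ELF3_p * ELF4_p * LUX_p
                    / (1.0 + (GI_p / n.k_ec_gi) ** 2))
        dx[16] = assembly - n.d_ec * EC

        # --- clock: GI ---
        dx[17] = (n.v_gi * (1.0 + n.a_gi_light * L)
                  / (1.0 + (LHY_p / n.k_gi_lhy) ** 2)
                  / (1.0 + (EC / n.k_gi_ec) ** 2)
                  + n.ox_gi - n.d_gi_m * GI_m)
        cplx_flux = n.k_cplx * L * GI_p * FKF1_p
        dx[18] = (n.p_gi * GI_m - n.d_gi_p * (1.0 + n.m_gi_dark * D) * GI_p
                  - cplx_flux)

        # --- flowering: CDF1 ---
        cdf1_act = (n.b_cdf1 + (1.0 - n.b_cdf1) * LHY_p * LHY_p
                    / (n.k_cdf1_lhy ** 2 + LHY_p * LHY_p))
        dx[19] = (n.v_cdf1 * cdf1_act / (1.0 + (prr_pool / n.k_cdf1_prr) ** 2)
                  + n.ox_cdf1 - n.d_cdf1_m * CDF1_m)
        dx[20] = (n.p_cdf1 * CDF1_m - n.d_cdf1_p * CDF1_p
                  - n.k_cdf1_cplx * GIFKF1 * CDF1_p
                  - n.k_cdf1_gi * GI_p * CDF1_p)

        # --- flowering: FKF1 and the GI-FKF1 complex ---
        dx[21] = (n.v_fkf1 * (1.0 + n.a_fkf1_light * L)
                  / (1.0 + (LHY_p / n.k_fkf1_lhy) ** 2)
                  / (1.0 + (EC / n.k_fkf1_ec) ** 2)
                  + n.ox_fkf1 - n.d_fkf1_m * FKF1_m)
        dx[22] = (n.p_fkf1 * FKF1_m
                  - n.d_fkf1_p * (1.0 + n.m_fkf1_dark * D) * FKF1_p
                  - cplx_flux)
        dx[23] = cplx_flux - n.d_cplx * GIFKF1

        # --- flowering: CO ---
        dx[24] = (n.v_co / (1.0 + (CDF1_p / n.k_co_cdf1) ** 2)
                  + n.ox_co - n.d_co_m * CO_m)
        co_deg = (n.d_co_p * (1.0 + n.m_co_dark * D)
                  / (1.0 + n.s_co_fkf1 * L * (FKF1_p + GIFKF1)))
        dx[25] = n.p_co * CO_m - co_deg * CO_p

        # --- elongation: PIF transcription, protein, inhibitors ---
        eca = assembly / n.d_ec if n.ec_readout_assembly else EC
        dx[27] = (n.v_pif4 / (1.0 + (eca / n.k_ec_pif4) ** 2)
                  + n.ox_pif4 - n.d_pif4_m * PIF4_m)
        dx[28] = (n.v_pif5 / (1.0 + (eca / n.k_ec_pif5) ** 2)
                  + n.ox_pif5 - n.d_pif5_m * PIF5_m)
        dx[29] = (n.p_pif * (n.w_pif4 * PIF4_m + n.w_pif5 * PIF5_m)
                  - (n.d_pif + n.d_pif_phyb * PHYB_a) * PIF_p)
        dx[30] = n.v_int * L - n.d_int * INT_p
        dx[31] = n.k_phyb_on * L * (n.phyb_total - PHYB_a) - n.k_phyb_off * PHYB_a

        pif_act = PIF_p / (1.0 + INT_p / n.k_int_pif)

        # --- flowering: FT (CO gate + CO-gated PIF term + temperature) ---
        co_hill = CO_p * CO_p / (n.k_ft_co ** 2 + CO_p * CO_p)
        pif_ft = pif_act * CO_p * CO_p / (n.k_ftpif_co ** 2 + CO_p * CO_p)
        dx[26] = (n.v_ft * (n.b_ft + co_hill + n.r_ft_pif * pif_ft)
                  / (1.0 + (CDF1_p / n.k_ft_cdf1) ** 2)
                  + n.ft_temp_activation + n.ox_ft - n.d_ft_m * FT_m)

        # --- elongation: PIF-induced targets ---
        for i, (v0, v, k, h, d, m) in enumerate((
            (n.v0_athb2, n.v_athb2, n.k_athb2, n.h_athb2, n.d_athb2, ATHB2_m),
            (n.v0_iaa29, n.v_iaa29, n.k_iaa29, n.h_iaa29, n.d_iaa29, IAA29_m),
            (n.v0_cluster1, n.v_cluster1, n.k_cluster1, n.h_cluster1,
             n.d_cluster1, CL1_m),
            (n.v0_cluster2, n.v_cluster2, n.k_cluster2, n.h_cluster2,
             n.d_cluster2, CL2_m),
        )):
            ph = pif_act ** h
            dx[32 + i] = v0 + v * ph / (k ** h + ph) - d * m

        # --- elongation: PIF-repressed cluster transcripts ---
        for i, (v, k, h, d, m) in enumerate((
            (n.v_rep1, n.k_rep1, n.h_rep1, n.d_rep1, R1_m),
            (n.v_rep2, n.k_rep2, n.h_rep2, n.d_rep2, R2_m),
            (n.v_rep3, n.k_rep3, n.h_rep3, n.d_rep3, R3_m),
            (n.v_rep4, n.k_rep4, n.h_rep4, n.d_rep4, R4_m),
        )):
            dx[36 + i] = v / (1.0 + (pif_act / k) ** h) + 0.0 - d * m

        return dx

    return f


def rhs(t: float, x, p: ParameterSet, env: Environment,
        genotype: Genotype | None = None) -> np.ndarray:
    """Time-derivative of every species at state ``x``.

    Convenience single-call form of :func:`make_rhs`; raises on non-finite
    state or parameters.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (N_SPECIES,):
        raise ValueError(f"state must have {N_SPECIES} entries, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains NaN/Inf")
    if genotype is not None:
        p = apply_genotype(p, genotype)
    return make_rhs(p, env)(t, x)


def ec_activity(p: ParameterSet, env: Environment, t: float, x) -> float:
    """The EC activity the PIF4/PIF5 promoters experience at state ``x``.

    With ``ec_readout_assembly`` set (default) this is the leading
    ELF3*ELF4*LUX assembly signal (scaled to EC-equivalent units); otherwise
    the accumulated EC pool itself.
    """
    i = SPECIES_INDEX
    if p["ec_readout_assembly"]:
        asm = (p["c_ec"] * x[i["ELF3_p"]] * x[i["ELF4_p"]] * x[i["LUX_p"]]
               / (1.0 + (x[i["GI_p"]] / p["k_ec_gi"]) ** 2))
        return asm / p["d_ec"]
    return x[i["EC"]]
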