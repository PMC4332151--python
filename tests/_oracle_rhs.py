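"""Independent, deliberately plain re-implementation of every model equation.

Written scalar-by-scalar from the documented rate laws (docs/methods.md),
using dict lookups and explicit Hill helpers — no code shared with
photoclock.model — to serve as a per-equation oracle for the vectorised rhs.
"""

import math


def hill_act(x, k, h=2.0):
    return x ** h / (k ** h + x ** h)


def hill_rep(x, k, h=2.0):
    return 1.0 / (1.0 + (x / k) ** h)


def oracle_rhs(t, state, p, light):
    """state: dict species -> value; p: mapping name -> value; light: L(t)."""
    s = state
    L = light(t)
    D = 1.0 - L
    d = {}

    pool = s["PRR9_p"] + s["PRR7_p"] + s["PRR5_p"] + s["TOC1_p"]

    d["LHY_m"] = (p["v_lhy"] * (1 + p["a_lhy_light"] * L)
                  * hill_rep(pool, p["k_lhy_prr"])
                  + p["ox_lhy"] - p["d_lhy_m"] * s["LHY_m"])
    d["LHY_p"] = p["p_lhy"] * s["LHY_m"] - p["d_lhy_p"] * s["LHY_p"]

    d["PRR9_m"] = (p["v_prr9"] * (p["b_prr9"] + p["a_prr9_light"] * L)
                   * hill_act(s["LHY_p"], p["k_prr9_lhy"])
                   * hill_rep(s["EC"], p["k_prr9_ec"])
                   + p["ox_prr9"] - p["d_prr9_m"] * s["PRR9_m"])
    d["PRR9_p"] = p["p_prr9"] * s["PRR9_m"] - p["d_prr9_p"] * s["PRR9_p"]

    d["PRR7_m"] = (p["v_prr7"] * hill_act(s["PRR9_p"], p["k_prr7_prr9"])
                   + p["ox_prr7"] - p["d_prr7_m"] * s["PRR7_m"])
    d["PRR7_p"] = (p["p_prr7"] * s["PRR7_m"]
                   - p["d_prr7_p"] * (1 + p["m_prr7_dark"] * D) * s["PRR7_p"])

    d["PRR5_m"] = (p["v_prr5"] * hill_act(s["PRR7_p"], p["k_prr5_prr7"])
                   + p["ox_prr5"] - p["d_prr5_m"] * s["PRR5_m"])
    d["PRR5_p"] = (p["p_prr5"] * s["PRR5_m"]
                   - p["d_prr5_p"] * (1 + p["m_prr5_dark"] * D) * s["PRR5_p"])

    d["TOC1_m"] = (p["v_toc1"] * hill_rep(s["LHY_p"], p["k_toc1_lhy"])
                   * hill_rep(s["EC"], p["k_toc1_ec"])
                   + p["ox_toc1"] - p["d_toc1_m"] * s["TOC1_m"])
    d["TOC1_p"] = (p["p_toc1"] * s["TOC1_m"]
                   - p["d_toc1_p"] * (1 + p["m_toc1_dark"] * D) * s["TOC1_p"])

    ev = hill_rep(s["LHY_p"], p["k_ev_lhy"]) * hill_rep(s["EC"], p["k_ev_ec"])
    for gene in ("elf3", "elf4", "lux"):
        up = gene.upper()
        d[f"{up}_m"] = (p[f"v_{gene}"] * ev + p[f"ox_{gene}"]
                        - p[f"d_{gene}_m"] * s[f"{up}_m"])
        d[f"{up}_p"] = (p[f"p_{gene}"] * s[f"{up}_m"]
                        - p[f"d_{gene}_p"] * s[f"{up}_p"])

    assembly = (p["c_ec"] * s["ELF3_p"] * s["ELF4_p"] * s["LUX_p"]
                * hill_rep(s["GI_p"], p["k_ec_gi"]))
    d["EC"] = assembly - p["d_ec"] * s["EC"]

    d["GI_m"] = (p["v_gi"] * (1 + p["a_gi_light"] * L)
                 * hill_rep(s["LHY_p"], p["k_gi_lhy"])
                 * hill_rep(s["EC"], p["k_gi_ec"])
                 + p["ox_gi"] - p["d_gi_m"] * s["GI_m"])
    cplx = p["k_cplx"] * L * s["GI_p"] * s["FKF1_p"]
    d["GI_p"] = (p["p_gi"] * s["GI_m"]
                 - p["d_gi_p"] * (1 + p["m_gi_dark"] * D) * s["GI_p"] - cplx)

    cdf1_act = p["b_cdf1"] + (1 - p["b_cdf1"]) * hill_act(s["LHY_p"], p["k_cdf1_lhy"])
    d["CDF1_m"] = (p["v_cdf1"] * cdf1_act * hill_rep(pool, p["k_cdf1_prr"])
                   + p["ox_cdf1"] - p["d_cdf1_m"] * s["CDF1_m"])
    d["CDF1_p"] = (p["p_cdf1"] * s["CDF1_m"] - p["d_cdf1_p"] * s["CDF1_p"]
                   - p["k_cdf1_cplx"] * s["GIFKF1"] * s["CDF1_p"]
                   - p["k_cdf1_gi"] * s["GI_p"] * s["CDF1_p"])

    d["FKF1_m"] = (p["v_fkf1"] * (1 + p["a_fkf1_light"] * L)
                   * hill_rep(s["LHY_p"], p["k_fkf1_lhy"])
                   * hill_rep(s["EC"], p["k_fkf1_ec"])
                   + p["ox_fkf1"] - p["d_fkf1_m"] * s["FKF1_m"])
    d["FKF1_p"] = (p["p_fkf1"] * s["FKF1_m"]
                   - p["d_fkf1_p"] * (1 + p["m_fkf1_dark"] * D) * s["FKF1_p"]
                   - cplx)
    d["GIFKF1"] = cplx - p["d_cplx"] * s["GIFKF1"]

    d["CO_m"] = (p["v_co"] * hill_rep(s["CDF1_p"], p["k_co_cdf1"])
                 + p["ox_co"] - p["d_co_m"] * s["CO_m"])
    co_deg = (p["d_co_p"] * (1 + p["m_co_dark"] * D)
              / (1 + p["s_co_fkf1"] * L * (s["FKF1_p"] + s["GIFKF1"])))
    d["CO_p"] = p["p_co"] * s["CO_m"] - co_deg * s["CO_p"]

    if p["ec_readout_assembly"]:
        eca = assembly / p["d_ec"]
    else:
        eca = s["EC"]
    d["PIF4_m"] = (p["v_pif4"] * hill_rep(eca, p["k_ec_pif4"])
                   + p["ox_pif4"] - p["d_pif4_m"] * s["PIF4_m"])
    d["PIF5_m"] = (p["v_pif5"] * hill_rep(eca, p["k_ec_pif5"])
                   + p["ox_pif5"] - p["d_pif5_m"] * s["PIF5_m"])
    d["PIF_p"] = (p["p_pif"] * (p["w_pif4"] * s["PIF4_m"] + p["w_pif5"] * s["PIF5_m"])
                  - (p["d_pif"] + p["d_pif_phyb"] * s["PHYB_a"]) * s["PIF_p"])
    d["INT_p"] = p["v_int"] * L - p["d_int"] * s["INT_p"]
    d["PHYB_a"] = (p["k_phyb_on"] * L * (p["phyb_total"] - s["PHYB_a"])
                   - p["k_phyb_off"] * s["PHYB_a"])

    act = s["PIF_p"] / (1 + s["INT_p"] / p["k_int_pif"])

    pif_ft = act * hill_act(s["CO_p"], p["k_ftpif_co"])
    d["FT_m"] = (p["v_ft"]
                 * (p["b_ft"] + hill_act(s["CO_p"], p["k_ft_co"])
                    + p["r_ft_pif"] * pif_ft)
                 * hill_rep(s["CDF1_p"], p["k_ft_cdf1"])
                 + p["ft_temp_activation"] + p["ox_ft"]
                 - p["d_ft_m"] * s["FT_m"])

    for gene, sp in (("athb2", "ATHB2_m"), ("iaa29", "IAA29_m"),
                     ("cluster1", "CLUSTER1_m"), ("cluster2", "CLUSTER2_m")):
        d[sp] = (p[f"v0_{gene}"]
                 + p[f"v_{gene}"] * hill_act(act, p[f"k_{gene}"], p[f"h_{gene}"])
                 - p[f"d_{gene}"] * s[sp])
    for gene, sp in (("rep1", "REP1_m"), ("rep2", "REP2_m"),
                     ("rep3", "REP3_m"), ("rep4", "REP4_m")):
        d[sp] = (p[f"v_{gene}"] * hill_rep(act, p[f"k_{gene}"], p[f"h_{gene}"])
                 - p[f"d_{gene}"] * s[sp])
    return d
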