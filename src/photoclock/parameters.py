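"""Kinetic parameter set.

All rates are first-order (1/h) or zero-order (conc/h) in arbitrary relative
concentration units; Hill half-saturation constants share those units.  Every
entry carries a provenance tag: ``default`` for structural choices and
``fitted`` for values calibrated against published diurnal behaviour (peak
phases, mutant effects, temperature fold-changes).
"""

from __future__ import annotations

from types import SimpleNamespace
from typing import Iterator, Mapping

import yaml

#: name -> (value, provenance)
_DEFAULTS: dict[str, tuple[float, str]] = {}


def _d(name: str, value: float, prov: str = "fitted") -> None:
    _DEFAULTS[name] = (float(value), prov)


# ----- CCA1/LHY (pooled morning loop) -----
_d("v_lhy", 1.0)            # max transcription rate
_d("a_lhy_light", 2.0)      # acute light activation at dawn
_d("k_lhy_prr", 1.0)        # half-repression by the PRR/TOC1 protein pool
_d("d_lhy_m", 2.2)
_d("p_lhy", 2.6)            # translation
_d("d_lhy_p", 0.55)

# ----- PRR wave -----
_d("v_prr9", 1.2)
_d("a_prr9_light", 1.0)
_d("b_prr9", 0.15)          # residual dark transcription; PRR9 induction is light-gated
_d("k_prr9_lhy", 0.8)       # half-activation by CCA1/LHY protein
_d("k_prr9_ec", 0.3)        # half-repression by EC
_d("d_prr9_m", 0.8)
_d("p_prr9", 1.0)
_d("d_prr9_p", 0.6)

_d("v_prr7", 1.2)
_d("k_prr7_prr9", 1.2)      # half-activation by PRR9 protein
_d("d_prr7_m", 0.7)
_d("p_prr7", 1.0)
_d("d_prr7_p", 0.35)
_d("m_prr7_dark", 2.0)      # dark-enhanced protein turnover

_d("v_prr5", 1.2)
_d("k_prr5_prr7", 1.5)
_d("d_prr5_m", 0.7)
_d("p_prr5", 1.0)
_d("d_prr5_p", 0.35)
_d("m_prr5_dark", 3.0)

# ----- TOC1 (evening PRR; ZTL-mediated dark turnover) -----
_d("v_toc1", 1.2)
_d("k_toc1_lhy", 0.4)
_d("k_toc1_ec", 0.4)
_d("d_toc1_m", 0.7)
_d("p_toc1", 1.0)
_d("d_toc1_p", 0.35)
_d("m_toc1_dark", 3.0)

# ----- Evening complex genes (shared regulatory logic) -----
_d("k_ev_lhy", 0.2)         # half-repression of ELF3/ELF4/LUX by CCA1/LHY
_d("k_ev_ec", 0.2)         # EC negative feedback on its own components
_d("v_elf3", 1.0)
_d("d_elf3_m", 0.8)
_d("p_elf3", 1.0)
_d("d_elf3_p", 0.22)
_d("v_elf4", 1.0)
_d("d_elf4_m", 0.8)
_d("p_elf4", 1.0)
_d("d_elf4_p", 0.22)
_d("v_lux", 1.0)
_d("d_lux_m", 0.8)
_d("p_lux", 1.0)
_d("d_lux_p", 0.22)

_d("c_ec", 0.5)             # EC assembly rate from ELF3*ELF4*LUX proteins
_d("k_ec_gi", 4.0)          # GI suppression of EC assembly
_d("d_ec", 0.38)            # sets ~2 h lag of EC behind its assembly signal
_d("ec_readout_assembly", 1.0, "default")  # 1: PIFs read the leading assembly signal

# ----- GI -----
_d("v_gi", 1.0)
_d("a_gi_light", 1.0)       # acute (red) light activation
_d("k_gi_lhy", 0.35)
_d("k_gi_ec", 0.3)
_d("d_gi_m", 0.8)
_d("p_gi", 1.0)
_d("d_gi_p", 0.3)
_d("m_gi_dark", 1.5)        # ELF3/COP1-mediated dark turnover

# ----- FKF1 (GI-like transcription; blue-light complex with GI) -----
_d("v_fkf1", 1.0)
_d("a_fkf1_light", 1.0)
_d("k_fkf1_lhy", 0.35)
_d("k_fkf1_ec", 0.3)
_d("d_fkf1_m", 0.8)
_d("p_fkf1", 1.0)
_d("d_fkf1_p", 0.3)
_d("m_fkf1_dark", 1.5)
_d("k_cplx", 0.4)           # blue-light-dependent GI-FKF1 association
_d("d_cplx", 0.5)

# ----- CDF1 (CCA1/LHY activation, PRR repression; GI/FKF1-dependent turnover) -----
_d("v_cdf1", 1.0)
_d("b_cdf1", 0.15)          # basal (CCA1/LHY-independent) transcription fraction
_d("k_cdf1_lhy", 0.6)
_d("k_cdf1_prr", 1.2)
_d("d_cdf1_m", 0.8)
_d("p_cdf1", 1.0)
_d("d_cdf1_p", 0.15)
_d("k_cdf1_cplx", 0.6)      # degradation by the GI-FKF1 complex
_d("k_cdf1_gi", 0.05)       # FKF1-independent, GI-dependent degradation
_d("v_ox", 1.0, "default")  # default constitutive (35S) transcription rate

# ----- CO -----
_d("v_co", 1.0)
_d("k_co_cdf1", 0.4)
_d("d_co_m", 0.7)
_d("p_co", 1.0)
_d("d_co_p", 0.6)
_d("m_co_dark", 8.0)        # COP1-mediated dark degradation of CO protein
_d("s_co_fkf1", 2.0)        # blue-light FKF1-dependent stabilisation

# ----- FT -----
_d("v_ft", 1.0)
_d("b_ft", 0.02)
_d("k_ft_co", 1.0)
_d("k_ft_cdf1", 0.6)
_d("r_ft_pif", 0.6)         # PIF contribution, gated by the CO-like coactivator
_d("k_ftpif_co", 1.0)
_d("d_ft_m", 0.6)
_d("ft_temp_activation", 0.0, "default")  # set by the temperature scenario

# ----- PIF4/PIF5 transcription (EC-repressed) -----
_d("v_pif4", 0.8)
_d("k_ec_pif4", 0.07)       # EC affinity for the PIF4 promoter (temperature knob)
_d("d_pif4_m", 0.7)
_d("v_pif5", 0.8)
_d("k_ec_pif5", 0.07)
_d("d_pif5_m", 0.7)

# ----- PIF protein, phyB, Interactor -----
_d("p_pif", 0.8)
_d("w_pif4", 0.6)           # weights of the two mRNAs in the active-PIF pool
_d("w_pif5", 0.4)
_d("d_pif", 0.2)           # basal PIF turnover
_d("d_pif_phyb", 0.9)       # phyB-stimulated turnover
_d("phyb_total", 1.0)
_d("k_phyb_on", 2.0)        # photoactivation
_d("k_phyb_off", 0.9)      # dark reversion
_d("v_int", 1.2)            # light-stimulated Interactor synthesis
_d("d_int", 0.6)
_d("k_int_pif", 0.5)        # Interactor inhibition of PIF activity

# ----- PIF target genes (five target-specific parameters each) -----
for _name, _v0, _v, _k, _h, _dd in (
    ("athb2", 0.02, 1.2, 2.0, 3.0, 0.35),
    ("iaa29", 0.02, 1.0, 0.6, 2.0, 0.30),
    ("cluster1", 0.02, 1.0, 1.0, 2.5, 0.40),
    ("cluster2", 0.03, 1.0, 0.5, 1.5, 0.25),
):
    _d(f"v0_{_name}", _v0)
    _d(f"v_{_name}", _v)
    _d(f"k_{_name}", _k)
    _d(f"h_{_name}", _h)
    _d(f"d_{_name}", _dd)

# ----- PIF-repressed cluster transcripts -----
for _name, _v, _k, _h, _dd in (
    ("rep1", 0.8, 0.5, 2.0, 0.4),
    ("rep2", 0.8, 0.8, 2.0, 0.3),
    ("rep3", 0.8, 0.3, 1.5, 0.5),
    ("rep4", 0.8, 0.6, 2.5, 0.35),
):
    _d(f"v_{_name}", _v)
    _d(f"k_{_name}", _k)
    _d(f"h_{_name}", _h)
    _d(f"d_{_name}", _dd)

# ----- constitutive (overexpression) rates, zero unless a genotype sets them -----
for _g in ("lhy", "prr9", "prr7", "prr5", "toc1", "elf3", "elf4", "lux",
           "gi", "fkf1", "cdf1", "co", "ft", "pif4", "pif5"):
    _d(f"ox_{_g}", 0.0, "default")


class ParameterSet(Mapping[str, float]):
    """Named kinetic constants with per-entry provenance.

    Behaves as an immutable-keyed mapping: values may be changed, but only for
    names that already exist (guards against typos silently adding knobs).
    """

    def __init__(self, values: dict[str, float] | None = None,
                 provenance: dict[str, str] | None = None):
        if values is None:
            self._values = {k: v for k, (v, _) in _DEFAULTS.items()}
            self._provenance = {k: p for k, (_, p) in _DEFAULTS.items()}
        else:
            self._values = dict(values)
            self._provenance = dict(provenance or {k: "default" for k in values})
        self._check()

    def _check(self) -> None:
        for k, v in self._values.items():
            v = float(v)
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"parameter {k} is not finite: {v}")
            if k.startswith(("h_",)) and v < 1:
                raise ValueError(f"Hill coefficient {k} must be >= 1, got {v}")
            if v < 0:
                raise ValueError(f"rate/constant {k} must be >= 0, got {v}")

    # -- mapping protocol ---------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __setitem__(self, key: str, value: float) -> None:
        if key not in self._values:
            raise KeyError(f"unknown parameter {key!r}")
        value = float(value)
        if value != value:
            raise ValueError(f"parameter {key} set to NaN")
        self._values[key] = value

    def provenance(self, key: str) -> str:
        return self._provenance[key]

    def set(self, key: str, value: float, provenance: str | None = None) -> None:
        self[key] = value
        if provenance is not None:
            self._provenance[key] = provenance

    def copy(self) -> "ParameterSet":
        return ParameterSet(self._values, self._provenance)

    def as_namespace(self) -> SimpleNamespace:
        """Plain attribute-access view used by the compiled right-hand side."""
        return SimpleNamespace(**self._values)

    def diff(self, other: "ParameterSet") -> dict[str, tuple[float, float]]:
        """Parameter-wise differences {name: (self, other)}."""
        return {
            k: (self._values[k], other._values[k])
            for k in self._values
            if self._values[k] != other._values[k]
        }

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            k: {"value": self._values[k], "provenance": self._provenance[k]}
            for k in sorted(self._values)
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        values = {k: float(d["value"]) for k, d in doc.items()}
        prov = {k: str(d.get("provenance", "default")) for k, d in doc.items()}
        return cls(values, prov)


def default_parameters() -> ParameterSet:
    """The calibrated wild-type parameter set."""
    return ParameterSet()
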