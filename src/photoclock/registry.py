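"""Species and gene registries.

Single source of truth for the state-vector ordering and for which parameters
each gene "owns" (used by genotype lesions and locality checks).

CCA1 and LHY act redundantly and are modelled as one pooled gene/species
(``CCA1LHY``); the same pooling applies to its lesions (``cca1;lhy``,
``CCA1-ox``, ``LHYox``).  PIF4 and PIF5 proteins are pooled into one active-PIF
species (``PIF_p``) fed by both mRNAs, which are kept separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: State-vector ordering.  Suffix ``_m`` = mRNA, ``_p`` = protein; ``EC`` is the
#: assembled evening complex; ``PHYB_a`` is the active (Pfr) fraction of phyB;
#: ``GIFKF1`` the blue-light-dependent GI-FKF1 complex; ``REP*_m`` are the four
#: PIF-repressed cluster transcripts.
SPECIES: tuple[str, ...] = (
    "LHY_m", "LHY_p",
    "PRR9_m", "PRR9_p",
    "PRR7_m", "PRR7_p",
    "PRR5_m", "PRR5_p",
    "TOC1_m", "TOC1_p",
    "ELF3_m", "ELF3_p",
    "ELF4_m", "ELF4_p",
    "LUX_m", "LUX_p",
    "EC",
    "GI_m", "GI_p",
    "CDF1_m", "CDF1_p",
    "FKF1_m", "FKF1_p",
    "GIFKF1",
    "CO_m", "CO_p",
    "FT_m",
    "PIF4_m", "PIF5_m",
    "PIF_p",
    "INT_p",
    "PHYB_a",
    "ATHB2_m", "IAA29_m",
    "CLUSTER1_m", "CLUSTER2_m",
    "REP1_m", "REP2_m", "REP3_m", "REP4_m",
)

N_SPECIES = len(SPECIES)
SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class GeneInfo:
    """Parameters owned by a gene for the purpose of genetic lesions."""

    name: str
    transcription_params: tuple[str, ...]  # zeroed by a knockout
    ox_param: str | None = None  # constitutive transcription rate added by -ox
    aliases: tuple[str, ...] = ()


GENES: dict[str, GeneInfo] = {
    g.name: g
    for g in (
        GeneInfo("CCA1LHY", ("v_lhy",), "ox_lhy", aliases=("CCA1", "LHY")),
        GeneInfo("PRR9", ("v_prr9",), "ox_prr9"),
        GeneInfo("PRR7", ("v_prr7",), "ox_prr7"),
        GeneInfo("PRR5", ("v_prr5",), "ox_prr5"),
        GeneInfo("TOC1", ("v_toc1",), "ox_toc1"),
        GeneInfo("ELF3", ("v_elf3",), "ox_elf3"),
        GeneInfo("ELF4", ("v_elf4",), "ox_elf4"),
        GeneInfo("LUX", ("v_lux",), "ox_lux"),
        GeneInfo("GI", ("v_gi",), "ox_gi"),
        GeneInfo("FKF1", ("v_fkf1",), "ox_fkf1"),
        GeneInfo("CDF1", ("v_cdf1",), "ox_cdf1"),
        GeneInfo("CO", ("v_co",), "ox_co"),
        GeneInfo("FT", ("v_ft",), "ox_ft"),
        GeneInfo("PIF4", ("v_pif4",), "ox_pif4"),
        GeneInfo("PIF5", ("v_pif5",), "ox_pif5"),
        # phyB has no mRNA species; a knockout removes the photoreceptor pool.
        GeneInfo("PHYB", ("phyb_total",), None),
    )
}

_ALIAS_TO_GENE: dict[str, str] = {}
for _g in GENES.values():
    _ALIAS_TO_GENE[_g.name.upper()] = _g.name
    for _a in _g.aliases:
        _ALIAS_TO_GENE[_a.upper()] = _g.name


def resolve_gene(name: str) -> str:
    """Map a gene name or alias (case-insensitive) to its canonical name."""
    try:
        return _ALIAS_TO_GENE[name.upper()]
    except KeyError:
        raise KeyError(f"unknown gene {name!r}; known: {sorted(GENES)}") from None
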