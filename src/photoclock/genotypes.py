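"""Genetic lesions: knockouts and constitutive (35S-style) overexpressors.

A knockout zeroes the gene's transcription rate(s); the existing protein pool
then decays through its normal turnover.  An overexpression adds a constitutive
transcription term while leaving all native clock inputs in place, so e.g.
``CDF1-ox;fkf1`` retains the rhythmic GI-dependent turnover of CDF1 protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ParameterSet
from .registry import GENES, resolve_gene


@dataclass(frozen=True)
class Genotype:
    label: str = "WT"
    knockouts: frozenset[str] = frozenset()
    #: gene -> constitutive transcription rate (conc/h)
    overexpressions: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        kos = frozenset(resolve_gene(g) for g in self.knockouts)
        oxs = tuple((resolve_gene(g), float(r)) for g, r in self.overexpressions)
        object.__setattr__(self, "knockouts", kos)
        object.__setattr__(self, "overexpressions", oxs)
        ox_genes = [g for g, _ in oxs]
        if len(set(ox_genes)) != len(ox_genes):
            raise ValueError("a gene may carry at most one overexpression lesion")
        clash = kos & set(ox_genes)
        if clash:
            raise ValueError(f"gene(s) both knocked out and overexpressed: {sorted(clash)}")
        for g, _ in oxs:
            if GENES[g].ox_param is None:
                raise ValueError(f"gene {g} cannot be overexpressed in this model")

    @property
    def is_wild_type(self) -> bool:
        return not self.knockouts and not self.overexpressions

    def compose(self, other: "Genotype") -> "Genotype":
        """Stack two sets of lesions (lesion-by-lesion composition)."""
        return Genotype(
            label=f"{self.label};{other.label}" if not other.is_wild_type else self.label,
            knockouts=self.knockouts | other.knockouts,
            overexpressions=self.overexpressions + other.overexpressions,
        )


WT = Genotype("WT")

_OX = 1.0  # default 35S constitutive rate; overridden per construct below

#: Registry mapping the mutant labels used throughout the analyses to lesions.
GENOTYPES: dict[str, Genotype] = {
    "WT": WT,
    "cca1;lhy": Genotype("cca1;lhy", knockouts=frozenset({"CCA1LHY"})),
    "prr9;7": Genotype("prr9;7", knockouts=frozenset({"PRR9", "PRR7"})),
    "prr9;7;5": Genotype("prr9;7;5", knockouts=frozenset({"PRR9", "PRR7", "PRR5"})),
    "elf3": Genotype("elf3", knockouts=frozenset({"ELF3"})),
    "lux": Genotype("lux", knockouts=frozenset({"LUX"})),
    "gi": Genotype("gi", knockouts=frozenset({"GI"})),
    "fkf1": Genotype("fkf1", knockouts=frozenset({"FKF1"})),
    "cdf1": Genotype("cdf1", knockouts=frozenset({"CDF1"})),
    "ft": Genotype("ft", knockouts=frozenset({"FT"})),
    "phyB": Genotype("phyB", knockouts=frozenset({"PHYB"})),
    "pif4": Genotype("pif4", knockouts=frozenset({"PIF4"})),
    "pif4;pif5": Genotype("pif4;pif5", knockouts=frozenset({"PIF4", "PIF5"})),
    "LHYox": Genotype("LHYox", overexpressions=(("CCA1LHY", _OX),)),
    "CCA1-ox": Genotype("CCA1-ox", overexpressions=(("CCA1LHY", _OX),)),
    "CO-ox": Genotype("CO-ox", overexpressions=(("CO", _OX),)),
    "CDF1-ox": Genotype("CDF1-ox", overexpressions=(("CDF1", _OX),)),
    "CDF1-ox;fkf1": Genotype(
        "CDF1-ox;fkf1", knockouts=frozenset({"FKF1"}), overexpressions=(("CDF1", _OX),)
    ),
    "CDF1-ox;gi": Genotype(
        "CDF1-ox;gi", knockouts=frozenset({"GI"}), overexpressions=(("CDF1", _OX),)
    ),
    "CO-ox;fkf1": Genotype(
        "CO-ox;fkf1", knockouts=frozenset({"FKF1"}), overexpressions=(("CO", _OX),)
    ),
    "CO-ox;CDF1-ox": Genotype(
        "CO-ox;CDF1-ox", overexpressions=(("CO", _OX), ("CDF1", _OX)),
    ),
}


def genotype(label: str) -> Genotype:
    try:
        return GENOTYPES[label]
    except KeyError:
        raise KeyError(f"unknown genotype label {label!r}; known: {sorted(GENOTYPES)}") from None


def apply_genotype(p: ParameterSet, g: Genotype) -> ParameterSet:
    """Return a copy of ``p`` with the genotype's lesions applied.

    Only parameters owned by the named genes change (locality).
    """
    q = p.copy()
    for gene in g.knockouts:
        for name in GENES[gene].transcription_params:
            q.set(name, 0.0, "lesion")
    for gene, rate in g.overexpressions:
        ox = GENES[gene].ox_param
        q.set(ox, rate, "lesion")
    return q
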