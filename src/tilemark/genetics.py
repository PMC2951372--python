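"""Mendelian seed-class expectations for crosses involving maternal-effect loci.

The FIS-class Polycomb genes (e.g. *FIS2*) are imprinted and act through the
maternally transmitted allele: a seed is devoid of FIS activity whenever its
mother contributed a mutant allele, regardless of the paternal genotype.
Ordinary recessive loci (e.g. *MET1* for CG-methylation maintenance) act
zygotically and require homozygosity.  Expected seed-class frequencies are
computed exactly by enumerating parental gamete combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

#: Requirement scopes: ``zygotic_homozygous`` means both alleles of the seed
#: must match; ``maternal_allele`` means the maternally transmitted allele
#: must match (maternal-effect / imprinted locus).
SCOPES = ("zygotic_homozygous", "maternal_allele")


@dataclass(frozen=True)
class LocusRequirement:
    """A per-locus condition defining a seed class."""

    allele: str
    scope: str

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"unknown requirement scope {self.scope!r}")


@dataclass(frozen=True)
class CrossSpec:
    """A (self-)cross with a seed-class predicate.

    Parameters
    ----------
    mother
        Maternal genotype: mapping locus name -> (allele1, allele2).
    predicate
        Per-locus requirement the seed class must satisfy; loci segregate
        independently.
    father
        Paternal genotype; defaults to the maternal genotype (selfing).
    """

    mother: Mapping[str, tuple[str, str]]
    predicate: Mapping[str, LocusRequirement]
    father: Mapping[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        father = self.father if self.father is not None else self.mother
        for parent, name in ((self.mother, "mother"), (father, "father")):
            for locus, alleles in parent.items():
                if len(alleles) != 2:
                    raise ValueError(f"{name} locus {locus!r} must carry two alleles")
        for locus in self.predicate:
            if locus not in self.mother or locus not in father:
                raise ValueError(f"predicate references missing locus {locus!r}")

    @property
    def paternal(self) -> Mapping[str, tuple[str, str]]:
        return self.father if self.father is not None else self.mother


def _gametes(genotype: Mapping[str, tuple[str, str]], loci: list[str]):
    """All equally likely gametes as (alleles, probability) under independence."""
    choices = [genotype[locus] for locus in loci]
    n = len(loci)
    prob = Fraction(1, 2**n)
    for combo in itertools.product(*choices):
        yield dict(zip(loci, combo)), prob


def expected_seed_fraction(cross: CrossSpec) -> Fraction:
    """Exact expected fraction of seeds satisfying the cross predicate.

    Enumerates every maternal x paternal gamete combination (each gamete
    transmits one allele per locus with probability 1/2, loci independent) and
    sums the probability of combinations meeting every requirement.
    ``maternal_allele`` requirements are evaluated on the maternally
    transmitted allele only; ``zygotic_homozygous`` requirements need the
    allele from both gametes.

    For the selfed *fis2/FIS2; met1/MET1* double heterozygote with the
    predicate {FIS2: maternal mutant allele, MET1: homozygous mutant} this is
    1/2 * 1/4 = 1/8 = 12.5% of seeds.
    """
    loci = sorted(cross.predicate)
    total = Fraction(0)
    for m_gamete, mp in _gametes(cross.mother, loci):
        for p_gamete, pp in _gametes(cross.paternal, loci):
            ok = True
            for locus, req in cross.predicate.items():
                if req.scope == "maternal_allele":
                    ok = m_gamete[locus] == req.allele
                else:  # zygotic_homozygous
                    ok = m_gamete[locus] == req.allele and p_gamete[locus] == req.allele
                if not ok:
                    break
            if ok:
                total += mp * pp
    return total


def fis2_met1_cross() -> CrossSpec:
    """The selfed fis2/FIS2; met1/MET1 double heterozygote.

    Seed class of interest: homozygous *met1* (zygotic loss of CG methylation
    maintenance) and devoid of FIS activity (maternally transmitted *fis2*).
    """
    genotype = {"FIS2": ("fis2", "FIS2"), "MET1": ("met1", "MET1")}
    predicate = {
        "FIS2": LocusRequirement(allele="fis2", scope="maternal_allele"),
        "MET1": LocusRequirement(allele="met1", scope="zygotic_homozygous"),
    }
    return CrossSpec(mother=genotype, predicate=predicate)
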