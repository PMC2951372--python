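"""Expected seed classes from the selfed fis2/FIS2; met1/MET1 double mutant.

FIS2 is imprinted: a seed lacks FIS activity whenever the maternally
transmitted allele is mutant (probability 1/2 from a heterozygous mother).
MET1 acts zygotically: homozygous met1 seeds arise at 1/4.  Independent
segregation gives 1/2 x 1/4 = 12.5% seeds in the doubly affected class.
"""

from tilemark import (
    CrossSpec,
    LocusRequirement,
    expected_seed_fraction,
    fis2_met1_cross,
)

frac = expected_seed_fraction(fis2_met1_cross())
print(f"selfed fis2/FIS2; met1/MET1 -> {frac} = {float(frac) * 100:.1f}% of seeds")

single = CrossSpec(
    mother={"FIS2": ("fis2", "FIS2")},
    predicate={"FIS2": LocusRequirement("fis2", "maternal_allele")},
)
print(f"maternal fis2 alone        -> {expected_seed_fraction(single)}")
# The 12.5% expectation is what makes the double-mutant qPCR experiment
# interpretable: one seed in eight lacks both CG methylation maintenance
# and FIS-PRC2 activity.
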