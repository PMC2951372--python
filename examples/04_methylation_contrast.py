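"""Median DNA methylation by H3K27me3 target class, context, and tissue.

Coverage-weighted methylation levels per element are summarised as medians
for all / specific / shared elements, mirroring the antagonism between DNA
methylation and Polycomb targeting: shared targets are unmethylated in both
tissues, endosperm-specific targets are methylated in vegetative tissue and
hypomethylated in the endosperm.
"""

import tilemark as tm

study = tm.simulate_study(seed=1)
scored = tm.score_track(study.track)
regions = tm.call_regions(scored)
calls = tm.build_target_calls(study.features, regions, scored,
                              [study.reference_targets])

medians = tm.median_by_class(study.methylation, calls, study.features)
te_cg = medians[(medians["feature_type"] == "TE") & (medians["context"] == "CG")]
print("TE CG methylation medians:")
print(te_cg[["class", "tissue", "n", "median_level"]].round(3).to_string(index=False))
# Expected ordering: specific/vegetative is highest, specific/endosperm is
# markedly reduced, shared is near zero in both tissues -- methylated loci
# only become Polycomb targets where methylation is lost.
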