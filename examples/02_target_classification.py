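"""Call H3K27me3 target features and classify them shared vs specific.

A feature is a target when an enriched region overlaps its transcribed
extent by >= 1 bp; targets also present in the (simulated) seedling
reference list are "shared", the rest are endosperm-"specific".
"""

import tilemark as tm
from tilemark.targets import class_composition, classify_targets

study = tm.simulate_study(seed=1)
scored = tm.score_track(study.track)
regions = tm.call_regions(scored)
calls = tm.build_target_calls(study.features, regions, scored,
                              [study.reference_targets], spec=study.spec)

targets = calls.loc[calls["is_target"], "feature_id"]
_, summary = classify_targets(targets, [study.reference_targets])
print(f"targets:  {summary['n_targets']} of {len(calls)} features")
print(f"shared:   {summary['n_shared']} ({summary['shared_pct']}%)")
print(f"specific: {summary['n_specific']} ({summary['specific_pct']}%)")

comp = class_composition(calls)
print("\nfeature-type composition (fraction of each group):")
print(comp[["feature_type", "probed_fraction", "targets_fraction",
            "specific_fraction"]].round(3).to_string(index=False))
# The shared percentage tracks the fraction of true targets planted in the
# reference list (86.5% by default); TEs/TEGs rise among specific targets.
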