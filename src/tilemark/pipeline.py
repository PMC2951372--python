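"""End-to-end orchestration: simulate -> score -> call -> analyse -> report.

A single global seed fans out to per-stage seeds (stage-name hashed) so each
stage is independently reproducible; every output directory carries a
summary stamped with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as tio
from ._util import derive_seed, pct
from .expression import DEParams, rank_product_de
from .genome import annotation_frame
from .methylation import median_by_class, methylation_expression_clusters
from .profiles import ProfileParams, chromosome_density, metagene_profile, score_by_group
from .regions import RegionCallParams, call_regions, length_histogram, region_summary
from .scoring import ScoringParams, score_track
from .setstats import category_enrichment, superfamily_enrichment
from .simulate import simulate_study
from .targets import build_target_calls, class_composition, classify_targets


@dataclass
class PipelineConfig:
    """Every stage's parameters plus the global seed and output directory."""

    seed: int = 0
    outdir: str = "tilemark_out"
    scoring: ScoringParams = field(default_factory=ScoringParams)
    region_calling: RegionCallParams = field(default_factory=RegionCallParams)
    profiles: ProfileParams = field(default_factory=ProfileParams)
    de: DEParams = field(default_factory=DEParams)
    #: keyword arguments forwarded to simulate_study
    generator: dict[str, Any] = field(default_factory=dict)
    n_expression_clusters: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in ("seed", "outdir", "generator", "n_expression_clusters"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, typ in (("scoring", ScoringParams), ("region_calling", RegionCallParams),
                         ("profiles", ProfileParams), ("de", DEParams)):
            if key in raw:
                kwargs[key] = typ(**raw[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            return obj

        payload = {k: encode(v) for k, v in dataclasses.asdict(self).items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage in dependency order and write the result bundle.

    Outputs under ``config.outdir``: annotation GFF3, heterochromatin and
    truth-domain BED, probe/score tracks, regions BED, target calls TSV,
    composition, metagene/density/box-plot tables, superfamily and category
    enrichment TSV, methylation medians TSV, DE results TSV, and a
    ``summary.json`` with the headline counts and percentages.  Rerunning
    with the same configuration is bit-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- simulate ---------------------------------------------------------
    study = simulate_study(seed=seed, **config.generator)
    tio.write_gff3(study.features, out / "annotation.gff3")
    het = pd.DataFrame(
        [(c, s, e) for c, ivs in study.spec.centromeres.items() for s, e in ivs],
        columns=["chrom", "start", "end"],
    )
    tio.write_bed(het, out / "heterochromatin.bed")
    tio.write_bed(study.truth.domains, out / "truth_domains.bed")
    tio.write_table(study.track, out / "probe_intensities.tsv")
    tio.write_id_list(sorted(study.reference_targets), out / "reference_targets.tsv")

    # --- score ------------------------------------------------------------
    scored = score_track(study.track, config.scoring)
    tio.write_bedgraph(scored, out / "scores.bedgraph")

    # --- call regions -----------------------------------------------------
    regions = call_regions(scored, config.region_calling)
    tio.write_bed(regions, out / "regions.bed", name_col="region_id",
                  score_col="region_score")
    summary_regions = region_summary(regions, study.spec)
    tio.write_table(length_histogram(regions), out / "region_length_histogram.tsv")

    # --- assign targets ---------------------------------------------------
    calls = build_target_calls(study.features, regions, scored,
                               [study.reference_targets], spec=study.spec)
    tio.write_table(calls, out / "target_calls.tsv")
    target_ids = calls.loc[calls["is_target"], "feature_id"]
    _, class_summary = classify_targets(target_ids, [study.reference_targets])
    tio.write_table(class_composition(calls), out / "class_composition.tsv")

    # --- profiles ---------------------------------------------------------
    ann = annotation_frame(study.features)
    genes = [f for f in study.features if f.feature_type == "gene"]
    target_genes = [f for f in genes if f.feature_id in set(target_ids)]
    if target_genes:
        tio.write_table(metagene_profile(scored, target_genes, config.profiles),
                        out / "metagene_targets.tsv")
    tio.write_table(chromosome_density(regions, study.features, study.spec,
                                       config.profiles), out / "chromosome_density.tsv")
    tio.write_table(score_by_group(calls, params=config.profiles),
                    out / "score_by_group.tsv")

    # --- enrichment -------------------------------------------------------
    sfam = superfamily_enrichment(calls, study.features, group="specific")
    tio.write_table(sfam, out / "superfamily_enrichment.tsv")
    category_map = {f.feature_id: f.categories for f in study.features}
    probed = calls.loc[calls["gene_score"].notna() &
                       calls["feature_type"].isin(["gene", "pseudogene"]), "feature_id"]
    shared_ids = calls.loc[calls["target_class"] == "shared", "feature_id"]
    cats = category_enrichment(shared_ids, category_map, probed)
    tio.write_table(cats, out / "category_enrichment.tsv")

    # --- methylation ------------------------------------------------------
    meth = median_by_class(study.methylation, calls, study.features)
    tio.write_table(meth, out / "methylation_medians.tsv")

    # --- expression clustering & DE --------------------------------------
    cluster_pcts: dict[str, float] = {}
    k = config.n_expression_clusters
    if len(study.tissue_panel) >= k:
        clusters = methylation_expression_clusters(
            study.tissue_panel, k=k, seed=derive_seed(seed, "clustering")
        )
        sizes = clusters.value_counts().sort_index()
        cluster_pcts = {f"cluster_{c}_pct": pct(int(nc), int(sizes.sum()))
                        for c, nc in sizes.items()}
        tio.write_table(clusters.reset_index(), out / "expression_clusters.tsv")
    de_params = dataclasses.replace(config.de, seed=derive_seed(seed, "de"))
    mut_cols = [c for c in study.expression.columns if c.startswith("mutant")]
    wt_cols = [c for c in study.expression.columns if c.startswith("wild_type")]
    de = rank_product_de(study.expression, mut_cols, wt_cols, de_params)
    tio.write_table(de.reset_index(), out / "de_results.tsv")

    # --- summary ----------------------------------------------------------
    summary = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "n_features": len(study.features),
        "n_probes": len(study.layout),
        "regions": summary_regions,
        "targets": class_summary,
        "expression_clusters": cluster_pcts,
        "n_significant_de": int(de["significant"].sum()),
        "annotation": {t: int((ann["feature_type"] == t).sum())
                       for t in ann["feature_type"].unique()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return {
        "study": study, "scored": scored, "regions": regions, "calls": calls,
        "de": de, "summary": summary,
    }
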