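"""Gene-level target scoring, calling, and shared/specific classification.

A feature is an H3K27me3 target when at least one enriched region overlaps
its transcribed extent by >= 1 bp.  Its gene score is the 75th percentile of
the window scores of probes located entirely within the transcribed region.
Targets also found in reference (seedling) target lists are "shared";
targets absent from every reference list are tissue-"specific".
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import pct, percentile
from .genome import FEATURE_TYPES, Feature, GenomeSpec

TARGET_CLASSES = ("shared", "specific", "non_target")


def gene_score(feature: Feature, score_track: pd.DataFrame) -> float | None:
    """75th percentile of scores of probes fully inside the feature.

    A probe qualifies when ``feature.start <= probe.start`` and
    ``probe.end <= feature.end``.  Returns None when no probe qualifies.
    """
    sub = score_track[score_track["chrom"] == feature.chrom]
    mask = (sub["start"] >= feature.start) & (sub["end"] <= feature.end)
    scores = sub.loc[mask, "score"].to_numpy(dtype=float)
    if scores.size == 0:
        return None
    return percentile(scores, 0.75)


def _contained_scores(features: Sequence[Feature], score_track: pd.DataFrame) -> dict[str, float | None]:
    """Gene scores for many features in one pass (sorted-array queries)."""
    out: dict[str, float | None] = {}
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(),
                sub["score"].to_numpy(dtype=float))
        for chrom, sub in score_track.groupby("chrom", sort=False)
    }
    for f in features:
        if f.chrom not in by_chrom:
            out[f.feature_id] = None
            continue
        starts, ends, scores = by_chrom[f.chrom]
        lo = np.searchsorted(starts, f.start, side="left")
        hi = np.searchsorted(starts, f.end, side="right")
        sel = scores[lo:hi][ends[lo:hi] <= f.end]
        out[f.feature_id] = percentile(sel, 0.75) if sel.size else None
    return out


def call_targets(features: Sequence[Feature], regions: pd.DataFrame) -> dict[str, bool]:
    """Per-feature target flag: >= 1 bp overlap with an enriched region.

    Half-open interval intersection: a region ``[a, b)`` abutting a feature
    ``[b, c)`` does not overlap it.
    """
    trees: dict[str, IntervalTree] = {}
    for row in regions.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return {
        f.feature_id: bool(trees.get(f.chrom) and trees[f.chrom].overlap(f.start, f.end))
        for f in features
    }


def classify_targets(
    target_ids: Iterable[str],
    reference_lists: Sequence[Iterable[str]],
) -> tuple[dict[str, str], dict]:
    """Split targets into shared (in the reference union) vs specific.

    Returns the per-feature class and a count summary with percentages
    (one decimal).  Duplicate ids are deduplicated; an empty reference
    union makes every target specific.
    """
    targets = set(target_ids)
    reference: set[str] = set()
    for lst in reference_lists:
        reference |= set(lst)
    classes = {t: ("shared" if t in reference else "specific") for t in targets}
    n = len(targets)
    n_shared = sum(1 for c in classes.values() if c == "shared")
    n_specific = n - n_shared
    summary = {
        "n_targets": n,
        "n_shared": n_shared,
        "n_specific": n_specific,
        "shared_pct": pct(n_shared, n) if n else None,
        "specific_pct": pct(n_specific, n) if n else None,
    }
    return classes, summary


def build_target_calls(
    features: Sequence[Feature],
    regions: pd.DataFrame,
    score_track: pd.DataFrame,
    reference_lists: Sequence[Iterable[str]],
    spec: GenomeSpec | None = None,
) -> pd.DataFrame:
    """Full per-feature call table.

    Columns: feature_id, feature_type, gene_score (NaN when no contained
    probe), is_target, target_class in {shared, specific, non_target}, and
    in_heterochromatin (midpoint inside a centromeric interval).
    """
    flags = call_targets(features, regions)
    scores = _contained_scores(features, score_track)
    classes, _ = classify_targets(
        [f.feature_id for f in features if flags[f.feature_id]], reference_lists
    )
    rows = []
    for f in features:
        is_target = flags[f.feature_id]
        rows.append({
            "feature_id": f.feature_id,
            "feature_type": f.feature_type,
            "gene_score": scores[f.feature_id],
            "is_target": is_target,
            "target_class": classes.get(f.feature_id, "non_target"),
            "in_heterochromatin": (
                spec.in_heterochromatin(f.chrom, f.midpoint) if spec else False
            ),
        })
    return pd.DataFrame(rows)


def class_composition(calls: pd.DataFrame) -> pd.DataFrame:
    """Feature-type frequencies among probed features, targets, shared, specific.

    "Probed" features are those with a gene score (>= 1 fully contained
    probe), the background used for all genome-wide comparisons.  Fractions
    sum to 1 within each non-empty group; heterochromatin fractions per type
    and group are reported alongside.
    """
    probed = calls[calls["gene_score"].notna()]
    groups = {
        "probed": probed,
        "targets": probed[probed["is_target"]],
        "shared": probed[probed["target_class"] == "shared"],
        "specific": probed[probed["target_class"] == "specific"],
    }
    rows = []
    for ftype in FEATURE_TYPES:
        row: dict = {"feature_type": ftype}
        for name, grp in groups.items():
            sub = grp[grp["feature_type"] == ftype]
            row[f"{name}_fraction"] = len(sub) / len(grp) if len(grp) else np.nan
            row[f"{name}_het_fraction"] = (
                sub["in_heterochromatin"].mean() if len(sub) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
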