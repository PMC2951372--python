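"""Weighted DNA-methylation levels and their contrast by target class.

The weighted methylation level of an element is the sum of methylated
observations divided by the sum of total observations across its sites —
the standard coverage-weighted estimator for bisulfite-derived data.
Medians are summarised per H3K27me3 target class (all / specific / shared)
by sequence context (CG, CHG, CHH) and tissue (vegetative, endosperm),
separately per feature type, reproducing the shared-unmethylated vs
specific-methylated contrast structure.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._util import percentile
from .genome import Feature
from .simulate import CONTEXTS, TISSUES


def weighted_level(methylated: Sequence[float], totals: Sequence[float]) -> float | None:
    """Coverage-weighted level: sum(methylated) / sum(total).

    Returns None (absent, not zero) when total coverage is zero.  Raises if
    any site reports more methylated than total observations.
    """
    m = np.asarray(methylated, dtype=float)
    t = np.asarray(totals, dtype=float)
    if (m > t).any():
        raise ValueError("methylated weight exceeds total weight at a site")
    if (m < 0).any() or (t < 0).any():
        raise ValueError("weights must be non-negative")
    total = t.sum()
    if total == 0:
        return None
    return float(m.sum() / total)


def aggregate_levels(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-site records to one weighted level per element/context/tissue.

    Input columns: feature_id, tissue, context, methylated_weight,
    total_weight (several rows per key allowed).  Elements with zero total
    coverage are dropped (missing, not zero).
    """
    bad = records["methylated_weight"] > records["total_weight"]
    if bad.any():
        raise ValueError("methylated weight exceeds total weight")
    agg = (
        records.groupby(["feature_id", "tissue", "context"], as_index=False)[
            ["methylated_weight", "total_weight"]
        ].sum()
    )
    agg = agg[agg["total_weight"] > 0].copy()
    agg["level"] = agg["methylated_weight"] / agg["total_weight"]
    return agg


def median_by_class(
    records: pd.DataFrame,
    calls: pd.DataFrame,
    features: Sequence[Feature],
    contexts: Sequence[str] = ("CG", "CHG"),
    tissues: Sequence[str] = TISSUES,
    include_chh: bool = False,
) -> pd.DataFrame:
    """Median methylation per class x context x tissue, per feature type.

    Classes: ``all`` (every element of the type), ``specific`` and
    ``shared`` (H3K27me3 target classes from `calls`).  CHH is excluded by
    default (uniformly low); pass ``include_chh=True`` to add it.  Empty
    cells are absent from the table.
    """
    contexts = list(contexts)
    if include_chh and "CHH" not in contexts:
        contexts.append("CHH")
    for c in contexts:
        if c not in CONTEXTS:
            raise ValueError(f"unknown context {c!r}")
    levels = aggregate_levels(records)
    type_of = {f.feature_id: f.feature_type for f in features}
    class_of = dict(zip(calls["feature_id"], calls["target_class"]))
    missing = set(levels["feature_id"]) - set(class_of)
    if missing:
        raise ValueError(f"records without a target call: {sorted(missing)[:3]}")
    levels = levels.assign(
        feature_type=levels["feature_id"].map(type_of),
        target_class=levels["feature_id"].map(class_of),
    )
    rows = []
    for ftype, tsub in levels.groupby("feature_type"):
        for cls in ("all", "specific", "shared"):
            csub = tsub if cls == "all" else tsub[tsub["target_class"] == cls]
            for context in contexts:
                for tissue in tissues:
                    cell = csub[(csub["context"] == context) & (csub["tissue"] == tissue)]
                    if len(cell) == 0:
                        continue
                    rows.append({
                        "feature_type": ftype, "class": cls, "context": context,
                        "tissue": tissue, "n": len(cell),
                        "median_level": percentile(cell["level"].to_numpy(), 0.5),
                    })
    return pd.DataFrame(rows)


def methylation_expression_clusters(
    panel: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.Series:
    """Centroid clustering of row-standardized expression profiles.

    Rows (elements) are standardized to zero mean and unit variance so that
    Euclidean centroid distance matches correlation-based distance; k-means
    with `n_restarts` initialisations and a fixed seed makes assignments
    deterministic.  k = 2 separates endosperm-repressed from
    endosperm-expressed elements; k = 5 reproduces finer tissue clusters.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(panel) < k:
        raise ValueError(f"need at least k={k} rows, got {len(panel)}")
    x = panel.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = (x - mu) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    return pd.Series(labels, index=panel.index, name="cluster")
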