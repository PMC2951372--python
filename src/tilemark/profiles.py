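"""Metagene profiles, chromosomal densities, and group-wise score summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percentile
from .genome import Feature, GenomeSpec


@dataclass(frozen=True)
class ProfileParams:
    """Metagene and density binning parameters.

    body_bins: equal-length intervals over the gene body (20 = 5% steps);
    flank_bp / flank_bin_bp: extent and resolution of the flanking regions
    (2 kb in 100-bp steps); density_window_bp: chromosomal tiling window;
    expression_split_log2: log2 expression level separating low from
    moderate expression strata.
    """

    body_bins: int = 20
    flank_bp: int = 2000
    flank_bin_bp: int = 100
    density_window_bp: int = 200_000
    expression_split_log2: float = 4.2
    per_gene_average: bool = False

    def __post_init__(self) -> None:
        if self.body_bins < 1:
            raise ValueError("body_bins must be >= 1")
        if self.flank_bp % self.flank_bin_bp != 0:
            raise ValueError("flank_bp must be divisible by flank_bin_bp")

    @property
    def flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp


def metagene_profile(
    score_track: pd.DataFrame,
    genes: Sequence[Feature],
    params: ProfileParams = ProfileParams(),
) -> pd.DataFrame:
    """Average score in strand-oriented bins over gene bodies and flanks.

    Each gene body is divided into ``body_bins`` equal-length intervals
    (5' -> 3' respecting strand); each 2-kb flank into fixed 100-bp bins.  A
    probe contributes its score to the bin containing its start.  The
    per-bin value is the mean over all contributing probes pooled across
    genes (or the mean of per-gene means with ``per_gene_average``); bins
    with no probes have NaN value and n = 0.

    Returns a table with columns segment (upstream/body/downstream),
    bin (0-based within segment, 5'->3'), mean_score, n_probes.
    """
    if not genes:
        raise ValueError("gene_set must be non-empty")
    fb, bb = params.flank_bins, params.body_bins
    total = 2 * fb + bb
    sums = np.zeros(total)
    counts = np.zeros(total, dtype=int)
    gene_sums = np.zeros(total)
    gene_ns = np.zeros(total, dtype=int)

    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["score"].to_numpy(dtype=float))
        for chrom, sub in score_track.groupby("chrom", sort=False)
    }
    for g in genes:
        if g.strand not in ("+", "-"):
            warnings.warn(f"{g.feature_id}: unstranded feature treated as '+'", stacklevel=2)
        if g.chrom not in by_chrom:
            continue
        starts, scores = by_chrom[g.chrom]
        lo = np.searchsorted(starts, g.start - params.flank_bp, side="left")
        hi = np.searchsorted(starts, g.end + params.flank_bp, side="left")
        if lo == hi:
            continue
        pos = starts[lo:hi]
        val = scores[lo:hi]
        glen = g.end - g.start
        # bin index on the plus-strand layout: [0, fb) upstream-left,
        # [fb, fb+bb) body, [fb+bb, total) downstream-right
        bins = np.empty(len(pos), dtype=int)
        left = pos < g.start
        right = pos >= g.end
        body = ~(left | right)
        bins[left] = (pos[left] - (g.start - params.flank_bp)) // params.flank_bin_bp
        bins[body] = fb + np.minimum(
            ((pos[body] - g.start) * params.body_bins) // glen, params.body_bins - 1
        )
        bins[right] = fb + bb + np.minimum(
            (pos[right] - g.end) // params.flank_bin_bp, fb - 1
        )
        if g.strand == "-":
            bins = total - 1 - bins
        np.add.at(sums, bins, val)
        np.add.at(counts, bins, 1)
        if params.per_gene_average:
            gsum = np.zeros(total)
            gcnt = np.zeros(total, dtype=int)
            np.add.at(gsum, bins, val)
            np.add.at(gcnt, bins, 1)
            has = gcnt > 0
            gene_sums[has] += gsum[has] / gcnt[has]
            gene_ns[has] += 1

    if params.per_gene_average:
        with np.errstate(invalid="ignore"):
            mean = np.where(gene_ns > 0, gene_sums / np.maximum(gene_ns, 1), np.nan)
    else:
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    segment = (["upstream"] * fb) + (["body"] * bb) + (["downstream"] * fb)
    within = list(range(fb)) + list(range(bb)) + list(range(fb))
    return pd.DataFrame({
        "segment": segment,
        "bin": within,
        "mean_score": mean,
        "n_probes": counts,
    })


def chromosome_density(
    regions: pd.DataFrame,
    features: Sequence[Feature],
    spec: GenomeSpec,
    params: ProfileParams = ProfileParams(),
) -> pd.DataFrame:
    """Counts of regions, genes, and TEs per tiling window.

    Windows tile each chromosome without overlap; an element is counted in
    the window containing its midpoint.  Window counts sum exactly to the
    element counts.  All-zero windows (including whole empty chromosomes)
    are retained.
    """
    w = params.density_window_bp
    if w <= 0:
        raise ValueError("density_window_bp must be positive")
    rows = []
    for chrom, length in spec.chromosomes:
        n_windows = (length + w - 1) // w
        counts = {
            "regions": np.zeros(n_windows, dtype=int),
            "genes": np.zeros(n_windows, dtype=int),
            "TEs": np.zeros(n_windows, dtype=int),
        }
        sub = regions[regions["chrom"] == chrom]
        for r in sub.itertuples(index=False):
            counts["regions"][((r.start + r.end) // 2) // w] += 1
        for f in features:
            if f.chrom != chrom:
                continue
            key = "genes" if f.feature_type == "gene" else (
                "TEs" if f.feature_type in ("TE", "TEG") else None
            )
            if key:
                counts[key][f.midpoint // w] += 1
        for i in range(n_windows):
            rows.append((chrom, i * w, min((i + 1) * w, length),
                         counts["regions"][i], counts["genes"][i], counts["TEs"][i]))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end",
                                       "n_regions", "n_genes", "n_TEs"])


def score_by_group(
    calls: pd.DataFrame,
    expression: Mapping[str, float] | pd.Series | None = None,
    params: ProfileParams = ProfileParams(),
) -> pd.DataFrame:
    """Five-number gene-score summaries per target class (x expression stratum).

    When per-feature log2 expression is supplied, each class is split at
    ``expression_split_log2`` into low/moderate strata.  Quartiles follow
    the package-wide percentile convention; empty groups are omitted.
    """
    df = calls[calls["gene_score"].notna()].copy()
    if expression is not None:
        expr = pd.Series(expression)
        df["stratum"] = np.where(
            df["feature_id"].map(expr) < params.expression_split_log2, "low", "moderate"
        )
        df.loc[~df["feature_id"].isin(expr.index), "stratum"] = "unknown"
        keys = ["target_class", "stratum"]
    else:
        keys = ["target_class"]
    rows = []
    for key, grp in df.groupby(keys):
        vals = grp["gene_score"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        key = key if isinstance(key, tuple) else (key,)
        rows.append({
            **dict(zip(keys, key)),
            "n": len(vals),
            "min": float(vals.min()),
            "q1": percentile(vals, 0.25),
            "median": percentile(vals, 0.5),
            "q3": percentile(vals, 0.75),
            "max": float(vals.max()),
        })
    return pd.DataFrame(rows)
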