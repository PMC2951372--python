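"""Enriched-region calling from thresholded probe runs.

A region is a maximal run of qualifying probes (score >= threshold) in which
the gap between consecutive qualifying probes (next start minus previous
end) never exceeds ``max_gap`` bp; the run spans from the first probe's
start to the last probe's end and is kept only if that genomic span reaches
``min_run`` bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import percentile, pct
from .genome import GenomeSpec

REGION_COLUMNS = ("region_id", "chrom", "start", "end", "n_probes", "region_score")


@dataclass(frozen=True)
class RegionCallParams:
    """Region-calling constraints (score threshold, minRun, maxGap in bp)."""

    score_threshold: float = 3.5
    min_run: int = 300
    max_gap: int = 200
    #: statistic summarising probe scores into the region score
    score_stat: str = "max"

    def __post_init__(self) -> None:
        if self.min_run <= 0:
            raise ValueError("min_run must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")
        if self.score_stat not in ("max", "mean", "q75"):
            raise ValueError("score_stat must be one of max/mean/q75")


def _region_score(scores: np.ndarray, stat: str) -> float:
    if stat == "max":
        return float(scores.max())
    if stat == "mean":
        return float(scores.mean())
    return percentile(scores, 0.75)


def call_regions(
    score_track: pd.DataFrame, params: RegionCallParams = RegionCallParams()
) -> pd.DataFrame:
    """Chain qualifying probes into enriched regions.

    Requires a track sorted by (chrom, start) with a ``score`` column.
    Returns a sorted, non-overlapping region table
    (region_id, chrom, start, end, n_probes, region_score).
    """
    if "score" not in score_track.columns:
        raise ValueError("score column missing")
    chroms = score_track["chrom"].to_numpy()
    starts = score_track["start"].to_numpy()
    order_ok = True
    for i in range(1, len(score_track)):
        if chroms[i] == chroms[i - 1] and starts[i] < starts[i - 1]:
            order_ok = False
            break
    if not order_ok:
        raise ValueError("score track must be sorted by (chrom, start)")

    rows = []
    qualifying = score_track[score_track["score"] >= params.score_threshold]
    for chrom, sub in qualifying.groupby("chrom", sort=True):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        sc = sub["score"].to_numpy(dtype=float)
        run_start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or s[i] - e[i - 1] > params.max_gap:
                span_start, span_end = int(s[run_start]), int(e[i - 1])
                if span_end - span_start >= params.min_run:
                    rows.append(
                        (chrom, span_start, span_end, i - run_start,
                         _region_score(sc[run_start:i], params.score_stat))
                    )
                run_start = i
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes", "region_score"])
    regions = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    regions.insert(0, "region_id", [f"region_{i + 1:05d}" for i in range(len(regions))])
    return regions


def region_summary(regions: pd.DataFrame, spec: GenomeSpec) -> dict:
    """Count, coverage, and heterochromatin summary of a region set.

    The genome fraction uses total chromosome length; the median length uses
    the package-wide percentile convention; a region is heterochromatic when
    its midpoint falls inside a centromeric/pericentromeric interval.
    """
    n = len(regions)
    lengths = (regions["end"] - regions["start"]).to_numpy() if n else np.array([])
    total_bp = int(lengths.sum()) if n else 0
    het = 0
    for row in regions.itertuples(index=False):
        if spec.in_heterochromatin(row.chrom, (row.start + row.end) // 2):
            het += 1
    return {
        "n_regions": n,
        "total_bp": total_bp,
        "genome_fraction": total_bp / spec.total_length,
        "median_length": percentile(lengths, 0.5) if n else None,
        "heterochromatic_count": het,
        "heterochromatic_pct": pct(het, n) if n else None,
    }


def domain_recovery(
    regions: pd.DataFrame, truth_domains: pd.DataFrame, tolerance: int = 100
) -> dict:
    """Recovery of true enrichment domains by called regions.

    Base-level metrics with boundary slack: recall is the fraction of truth
    bases covered by called regions after eroding each truth domain by
    `tolerance` bp per side (boundary misses within the tolerance are not
    penalised); precision is the fraction of called bases inside truth
    dilated by `tolerance` bp per side.  Also reports domain-count matching
    (truth domains overlapped by >= 1 call, calls overlapping >= 1 domain).
    """
    rec_num = rec_den = prec_num = prec_den = 0
    matched_domains = 0
    for t in truth_domains.itertuples(index=False):
        es, ee = t.start + tolerance, t.end - tolerance
        sub = regions[regions["chrom"] == t.chrom]
        hit = ((sub["start"] < t.end) & (t.start < sub["end"])).any()
        matched_domains += bool(hit)
        if ee <= es:
            continue
        rec_den += ee - es
        for r in sub.itertuples(index=False):
            rec_num += max(0, min(r.end, ee) - max(r.start, es))
    matched_regions = 0
    for r in regions.itertuples(index=False):
        prec_den += r.end - r.start
        sub = truth_domains[truth_domains["chrom"] == r.chrom]
        hit = False
        for t in sub.itertuples(index=False):
            prec_num += max(0, min(r.end, t.end + tolerance) - max(r.start, t.start - tolerance))
            hit = hit or (r.start < t.end and t.start < r.end)
        matched_regions += hit
    return {
        "recall": rec_num / rec_den if rec_den else float("nan"),
        "precision": prec_num / prec_den if prec_den else float("nan"),
        "n_truth": len(truth_domains),
        "n_called": len(regions),
        "truth_domains_hit": matched_domains,
        "called_regions_hitting_truth": matched_regions,
    }


def length_histogram(regions: pd.DataFrame, bin_width: int = 100) -> pd.DataFrame:
    """Counts of region lengths per half-open bin ``[i*w, (i+1)*w)``.

    The returned table covers every bin from zero through the longest
    region; counts sum to the region count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = (regions["end"] - regions["start"]).to_numpy()
    if len(lengths) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"]).astype(int)
    idx = lengths // bin_width
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_width,
        "bin_end": (np.arange(n_bins) + 1) * bin_width,
        "count": counts,
    })
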