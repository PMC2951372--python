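"""Rank-product differential expression, target-overlap analysis, and qPCR math.

The rank product of a gene is the geometric mean of its fold-change ranks
across all mutant-replicate x wild-type-replicate comparisons.  Up- and
down-regulation are tested as separate one-sided statistics.  Significance
comes from a permutation null (gene labels permuted within comparisons);
for tiny inputs the null is enumerated exhaustively instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .setstats import EnrichmentResult, overlap_significance


@dataclass(frozen=True)
class DEParams:
    """Differential-expression thresholds and permutation settings.

    Significance requires permutation FDR <= `fdr_threshold` and
    |mean log2 fold change| > `log2_fc_threshold` (0.6 in log2 units,
    about 1.5-fold).
    """

    fdr_threshold: float = 0.1
    log2_fc_threshold: float = 0.6
    n_permutations: int = 1000
    seed: int = 0
    #: exhaustive null enumeration when (n_genes!)^k does not exceed this
    exact_limit: int = 100_000

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.log2_fc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Efficiency-corrected qPCR means and standard errors.

    `x_*` are expression values on the E^(-Ct) scale (E = primer efficiency,
    1 < E <= 2); `se_*` their standard errors over technical replicates.
    """

    gene: str
    x_target: float
    se_target: float
    x_reference: float
    se_reference: float

    def __post_init__(self) -> None:
        if self.x_target <= 0 or self.x_reference <= 0:
            raise ValueError("expression values must be positive")
        if self.se_target < 0 or self.se_reference < 0:
            raise ValueError("standard errors must be non-negative")


def efficiency_corrected(efficiency: float, ct: float) -> float:
    """Expression on the E^(-Ct) scale from a raw Ct value."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("primer efficiency must lie in (1, 2]")
    return efficiency ** (-ct)


def qpcr_relative_expression(m: QpcrMeasurement) -> tuple[float, float]:
    """Relative expression with propagated standard error.

    ``R = x_target / x_reference``;
    ``se_R = R * sqrt((se_t / x_t)^2 + (se_r / x_r)^2)``.
    """
    r = m.x_target / m.x_reference
    se = r * math.sqrt(
        (m.se_target / m.x_target) ** 2 + (m.se_reference / m.x_reference) ** 2
    )
    return r, se


def _rank_matrix(lfc: np.ndarray, direction: str) -> np.ndarray:
    """Per-comparison ranks: rank 1 = strongest change in `direction`."""
    if direction == "up":
        return np.apply_along_axis(stats.rankdata, 0, -lfc)
    return np.apply_along_axis(stats.rankdata, 0, lfc)


def _geometric_mean_ranks(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.log(ranks).mean(axis=1))


def _null_rp_pool(n_genes: int, k: int, params: DEParams) -> np.ndarray:
    """Null rank products from permuted gene labels within comparisons.

    Exhaustive over all (n!)^k rank assignments when small enough,
    otherwise `n_permutations` random permutations; each draw contributes
    one RP value per gene.
    """
    try:
        n_exact = math.factorial(n_genes) ** k
    except OverflowError:
        n_exact = params.exact_limit + 1
    if n_exact * n_genes <= params.exact_limit:
        pool = []
        perms = list(itertools.permutations(range(1, n_genes + 1)))
        for combo in itertools.product(perms, repeat=k):
            ranks = np.asarray(combo, dtype=float).T  # genes x comparisons
            pool.append(_geometric_mean_ranks(ranks))
        return np.sort(np.concatenate(pool))
    rng = np.random.default_rng(params.seed)
    pool = np.empty((params.n_permutations, n_genes))
    base = np.arange(1, n_genes + 1, dtype=float)
    for p in range(params.n_permutations):
        logsum = np.zeros(n_genes)
        for _ in range(k):
            logsum += np.log(rng.permutation(base))
        pool[p] = np.exp(logsum / k)
    return np.sort(pool.ravel())


def _fdr_from_p(p: np.ndarray, n_genes: int) -> np.ndarray:
    """FDR at each gene's RP cut: expected false positives / observed positives.

    Expected false positives at the cut equal ``p * n_genes``; observed
    positives equal the gene's rank when ordered by RP.  The step-up
    minimum over worse cuts makes the estimate monotone.
    """
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, n_genes + 1)
    raw = (p[order] * n_genes) / ranks
    q = np.minimum.accumulate(raw[::-1])[::-1]
    out = np.empty(n_genes)
    out[order] = np.minimum(q, 1.0)
    return out


def rank_product_de(
    expr: pd.DataFrame,
    mutant_cols: Sequence[str],
    wildtype_cols: Sequence[str],
    params: DEParams = DEParams(),
) -> pd.DataFrame:
    """Rank-product differential expression between two replicated conditions.

    `expr` is a genes x samples log2 matrix.  Replicates are paired one to
    one (k = min(n_mut, n_wt) comparisons, so comparisons share no
    replicate and are independent under the null); genes are ranked by
    fold change within each comparison
    (rank 1 = most up-regulated for the up statistic, most down-regulated
    for the down statistic) and RP is the geometric mean of a gene's ranks.
    Permutation p-values are the fraction of null RPs at most the observed
    value; significance requires FDR <= threshold and |mean log2 FC| above
    the fold-change threshold.

    Returns a per-gene table with rp/p/fdr for both directions, the mean
    log2 fold change, and significance flags.
    """
    if len(mutant_cols) < 2 or len(wildtype_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    x = expr[list(mutant_cols) + list(wildtype_cols)].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("expression matrix contains non-finite values")
    n_genes = len(expr)
    mut = expr[list(mutant_cols)].to_numpy(dtype=float)
    wt = expr[list(wildtype_cols)].to_numpy(dtype=float)
    # one-to-one replicate pairings: each replicate enters one comparison, so
    # comparisons are independent and the label-permutation null is valid
    k = min(mut.shape[1], wt.shape[1])
    lfc = np.column_stack([mut[:, i] - wt[:, i] for i in range(k)])

    out = pd.DataFrame(index=expr.index)
    out["mean_log2_fc"] = lfc.mean(axis=1)
    null = _null_rp_pool(n_genes, k, params)
    for direction in ("up", "down"):
        rp = _geometric_mean_ranks(_rank_matrix(lfc, direction))
        p = np.searchsorted(null, rp, side="right") / len(null)
        out[f"rp_{direction}"] = rp
        out[f"p_{direction}"] = p
        out[f"fdr_{direction}"] = _fdr_from_p(p, n_genes)
    out["significant_up"] = (
        (out["fdr_up"] <= params.fdr_threshold)
        & (out["mean_log2_fc"] > params.log2_fc_threshold)
    )
    out["significant_down"] = (
        (out["fdr_down"] <= params.fdr_threshold)
        & (out["mean_log2_fc"] < -params.log2_fc_threshold)
    )
    out["significant"] = out["significant_up"] | out["significant_down"]
    return out


def deregulated_target_overlap(
    significant_a: Iterable[str],
    significant_b: Iterable[str],
    target_set: Iterable[str],
    universe: Iterable[str],
) -> dict:
    """Venn counts and overlap significance for two deregulated sets vs targets.

    Returns the seven Venn cell counts for (A = first timepoint,
    B = second timepoint, T = H3K27me3 targets) plus pairwise
    hypergeometric overlap tests within the shared universe.
    """
    universe = set(universe)
    a, b, t = set(significant_a), set(significant_b), set(target_set)
    for name, s in (("significant_a", a), ("significant_b", b), ("target_set", t)):
        if not s <= universe:
            raise ValueError(f"{name} is not a subset of the universe")
    counts = {
        "a_only": len(a - b - t),
        "b_only": len(b - a - t),
        "t_only": len(t - a - b),
        "a_and_b_only": len((a & b) - t),
        "a_and_t_only": len((a & t) - b),
        "b_and_t_only": len((b & t) - a),
        "a_and_b_and_t": len(a & b & t),
    }
    tests: dict[str, EnrichmentResult] = {
        "a_vs_b": overlap_significance(a, b, universe),
        "a_vs_targets": overlap_significance(a, t, universe),
        "b_vs_targets": overlap_significance(b, t, universe),
    }
    return {"venn": counts, "tests": tests}
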