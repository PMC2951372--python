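"""Hypergeometric set-enrichment machinery with Benjamini-Hochberg control.

All tests draw without replacement from a finite background (the features
probed by the array, never the whole annotation): with N population
elements of which K are marked, and a sample of n containing k marked
elements, enrichment is the upper tail P(X >= k) and depletion the lower
tail P(X <= k) of the hypergeometric distribution.  Families of tests
(superfamilies, categories) are corrected with the BH step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Feature


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric test with its context counts.

    population: N; population_successes: K; sample: n; sample_successes: k;
    p_enrich / p_deplete: upper / lower tails; p_adjusted: BH-adjusted
    enrichment p (when tested within a family).
    """

    label: str
    population: int
    population_successes: int
    sample: int
    sample_successes: int
    p_enrich: float
    p_deplete: float
    p_adjusted: float | None = None


def _validate(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"inconsistent hypergeometric arguments N={N}, K={K}, n={n}, k={k}"
        )
    if k < max(0, n - (N - K)):
        raise ValueError(
            f"impossible overlap k={k} < n - (N - K) = {n - (N - K)}"
        )


def hypergeom_tail(N: int, K: int, n: int, k: int, tail: str = "upper") -> float:
    """Exact hypergeometric tail probability.

    ``upper``: P(X >= k); ``lower``: P(X <= k), for X ~ Hypergeom(N, K, n).
    """
    _validate(N, K, n, k)
    dist = stats.hypergeom(N, K, n)
    if tail == "upper":
        return float(dist.sf(k - 1))
    if tail == "lower":
        return float(dist.cdf(k))
    raise ValueError("tail must be 'upper' or 'lower'")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved.

    ``adj_(i) = min_{j >= i} (p_(j) * m / j)`` on the ascending order, capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Upper-tail significance of the overlap of two sets in a universe."""
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(a & b)
    N, K, n = len(universe), len(a), len(b)
    return EnrichmentResult(
        label="overlap",
        population=N, population_successes=K, sample=n, sample_successes=k,
        p_enrich=hypergeom_tail(N, K, n, k, "upper"),
        p_deplete=hypergeom_tail(N, K, n, k, "lower"),
    )


def _family_tests(
    memberships: Mapping[str, set[str]],
    background: set[str],
    sample: set[str],
) -> pd.DataFrame:
    """Both-tailed hypergeometric tests for each label, BH within the family."""
    N, n = len(background), len(sample)
    rows = []
    for label, members in sorted(memberships.items()):
        members = members & background
        K = len(members)
        k = len(members & sample)
        if K == 0:
            continue
        rows.append({
            "label": label, "population": N, "population_successes": K,
            "sample": n, "sample_successes": k,
            "p_enrich": hypergeom_tail(N, K, n, k, "upper"),
            "p_deplete": hypergeom_tail(N, K, n, k, "lower"),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_enrich_adjusted"] = bh_adjust(df["p_enrich"].to_numpy())
        df["p_deplete_adjusted"] = bh_adjust(df["p_deplete"].to_numpy())
    return df


def superfamily_enrichment(
    calls: pd.DataFrame,
    features: Sequence[Feature],
    group: str = "specific",
) -> pd.DataFrame:
    """TE-superfamily enrichment/depletion within a target group.

    Background: all probed TE/TEG elements (gene score present).  `group`
    selects the sample: ``shared``, ``specific``, or ``all-targets``.  BH
    correction across superfamilies, enrichment and depletion separately.
    """
    te_ids = {f.feature_id: f.superfamily for f in features
              if f.feature_type in ("TE", "TEG")}
    probed = calls[calls["gene_score"].notna()]
    background = set(probed["feature_id"]) & set(te_ids)
    if not background:
        raise ValueError("empty TE/TEG background")
    if group == "all-targets":
        sample_df = probed[probed["is_target"]]
    elif group in ("shared", "specific"):
        sample_df = probed[probed["target_class"] == group]
    else:
        raise ValueError("group must be shared, specific, or all-targets")
    sample = set(sample_df["feature_id"]) & background
    memberships: dict[str, set[str]] = {}
    for fid in background:
        memberships.setdefault(te_ids[fid], set()).add(fid)
    return _family_tests(memberships, background, sample)


def category_enrichment(
    target_ids: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    background_ids: Iterable[str],
    critical_p: float = 1.0e-3,
) -> pd.DataFrame:
    """Functional-category enrichment among targets at a critical adjusted p.

    `category_map` maps feature id -> categories.  Upper-tail tests per
    category, BH across categories; the ``passes`` column marks categories
    with adjusted p <= `critical_p`.  Empty categories are skipped.
    """
    background = set(background_ids)
    sample = set(target_ids) & background
    memberships: dict[str, set[str]] = {}
    for fid in background:
        for cat in category_map.get(fid, ()):
            memberships.setdefault(cat, set()).add(fid)
    df = _family_tests(memberships, background, sample)
    if len(df):
        df["passes"] = df["p_enrich_adjusted"] <= critical_p
    return df
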