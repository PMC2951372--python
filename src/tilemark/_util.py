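"""Shared numeric conventions used by every analysis module."""

from __future__ import annotations

import hashlib

import numpy as np


def percentile(values, q: float) -> float:
    """Percentile under the package-wide convention.

    Linear interpolation on ascending order statistics:
    ``h = (n - 1) * q``; ``value = x[floor(h)] + (h - floor(h)) *
    (x[floor(h) + 1] - x[floor(h)])``.  Every quantile reported anywhere in
    the package (gene scores, region medians, box-plot quartiles, methylation
    medians) goes through this function so that conventions cannot drift
    between modules.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of an empty collection is undefined")
    return float(np.quantile(arr, q, method="linear"))


def pct(k: int, n: int, decimals: int = 1) -> float:
    """Percentage ``100 * k / n`` rounded to `decimals` (report convention)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, decimals)


def derive_seed(seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from a global seed and a stage name.

    Stable across runs and platforms (blake2b based), so each pipeline stage
    is independently reproducible from the single configured seed.
    """
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)
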