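"""Genome layout and feature annotation containers.

All in-memory coordinates are 0-based, half-open ``[start, end)``.  On-disk
GFF3 is 1-based inclusive and converted at the I/O boundary (see
:mod:`tilemark.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

#: Annotation classes distinguished throughout: protein-coding genes,
#: pseudogenes, transposable elements, and transposable-element genes
#: (genes encoded within a TE).
FEATURE_TYPES = ("gene", "pseudogene", "TE", "TEG")


@dataclass(frozen=True)
class GenomeSpec:
    """A multi-chromosome genome with a heterochromatin partition.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs.
    centromeres
        Per-chromosome list of ``(start, end)`` intervals marking centromeric
        or pericentromeric heterochromatin; used to classify regions and
        features as heterochromatic (by midpoint).
    seed
        Base RNG seed for generators built on this genome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for chrom, intervals in self.centromeres.items():
            if chrom not in lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom!r}")
            prev_end = -1
            for start, end in sorted(intervals):
                if not (0 <= start < end <= lengths[chrom]):
                    raise ValueError(
                        f"centromere interval [{start}, {end}) outside {chrom!r}"
                    )
                if start < prev_end:
                    raise ValueError(f"overlapping centromere intervals on {chrom!r}")
                prev_end = end

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def in_heterochromatin(self, chrom: str, pos: int) -> bool:
        """True if `pos` lies within a centromeric/pericentromeric interval."""
        for start, end in self.centromeres.get(chrom, ()):
            if start <= pos < end:
                return True
        return False


@dataclass(frozen=True)
class Feature:
    """One annotated element (gene, pseudogene, TE, or TEG)."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_type: str
    superfamily: str = ""
    categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.feature_id}: start must be < end")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"{self.feature_id}: unknown type {self.feature_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")
        if self.feature_type in ("gene", "pseudogene") and self.superfamily:
            raise ValueError(
                f"{self.feature_id}: superfamily only applies to TE/TEG features"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


def annotation_frame(features: Iterable[Feature]) -> pd.DataFrame:
    """Tabular view of an annotation (one row per feature)."""
    rows = [
        {
            "feature_id": f.feature_id,
            "chrom": f.chrom,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "feature_type": f.feature_type,
            "superfamily": f.superfamily,
            "categories": ",".join(sorted(f.categories)),
        }
        for f in features
    ]
    cols = [
        "feature_id", "chrom", "start", "end", "strand",
        "feature_type", "superfamily", "categories",
    ]
    return pd.DataFrame(rows, columns=cols)


def features_from_frame(frame: pd.DataFrame) -> list[Feature]:
    out = []
    for row in frame.itertuples(index=False):
        cats = getattr(row, "categories", "") or ""
        out.append(
            Feature(
                feature_id=row.feature_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                feature_type=row.feature_type,
                superfamily=getattr(row, "superfamily", "") or "",
                categories=frozenset(c for c in str(cats).split(",") if c),
            )
        )
    return out


def default_genome(seed: int = 0, n_chromosomes: int = 3, chrom_length: int = 400_000,
                   centromere_fraction: float = 0.2) -> GenomeSpec:
    """A compact multi-chromosome genome used as the default study condition.

    Each chromosome carries a central heterochromatic block covering
    `centromere_fraction` of its length, mimicking the gene-poor, TE-rich
    pericentromeric organisation of the Arabidopsis genome at reduced scale.
    """
    chroms = tuple((f"Chr{i + 1}", chrom_length) for i in range(n_chromosomes))
    half = int(chrom_length * centromere_fraction / 2)
    mid = chrom_length // 2
    cents = {name: ((mid - half, mid + half),) for name, _ in chroms}
    return GenomeSpec(chromosomes=chroms, centromeres=cents, seed=seed)
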