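"""Readers and writers for the on-disk formats.

Conventions: GFF3 is 1-based inclusive on disk and converted to 0-based
half-open in memory; BED and bedGraph are natively 0-based half-open;
probe layouts, intensities, methylation and expression travel as
tab-separated tables with headers.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

from .genome import FEATURE_TYPES, Feature

_GFF_SOURCE = "tilemark"
_TYPE_TO_GFF = {
    "gene": "gene",
    "pseudogene": "pseudogene",
    "TE": "transposable_element",
    "TEG": "transposable_element_gene",
}
_GFF_TO_TYPE = {v: k for k, v in _TYPE_TO_GFF.items()}


def write_gff3(features: Iterable[Feature], path: str | os.PathLike) -> None:
    """Write an annotation as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.feature_id}"]
            if f.superfamily:
                attrs.append(f"superfamily={f.superfamily}")
            if f.categories:
                attrs.append("categories=" + "|".join(sorted(f.categories)))
            fh.write(
                "\t".join([
                    f.chrom, _GFF_SOURCE, _TYPE_TO_GFF[f.feature_type],
                    str(f.start + 1), str(f.end), ".", f.strand, ".",
                    ";".join(attrs),
                ]) + "\n"
            )


def _prescan_gff3(path: str | os.PathLike) -> None:
    """Line-numbered structural validation ahead of parsing."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno} "
                                 f"({len(fields)} columns)")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric coordinates on line {lineno}"
                ) from exc
            if end < start:
                raise ValueError(f"{path}: end < start on line {lineno}")


def read_gff3(path: str | os.PathLike) -> list[Feature]:
    """Read an annotation from GFF3, converting to 0-based half-open.

    Feature types map from the GFF type column (gene, pseudogene,
    transposable_element, transposable_element_gene); unknown types are
    skipped.  A missing ID attribute or end < start is an error.
    """
    _prescan_gff3(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, id_spec="ID",
    )
    features = []
    skipped = 0
    for rec in db.all_features():
        ftype = _GFF_TO_TYPE.get(rec.featuretype)
        if ftype is None:
            skipped += 1
            continue
        if "ID" not in rec.attributes:
            raise ValueError(f"{path}: feature without ID attribute at "
                             f"{rec.seqid}:{rec.start}-{rec.end}")
        sfam = rec.attributes.get("superfamily", [""])[0]
        cats = rec.attributes.get("categories", [""])[0]
        features.append(
            Feature(
                feature_id=rec.attributes["ID"][0],
                chrom=rec.seqid,
                start=rec.start - 1,
                end=rec.end,
                strand=rec.strand if rec.strand in ("+", "-") else "+",
                feature_type=ftype,
                superfamily=sfam,
                categories=frozenset(c for c in cats.split("|") if c),
            )
        )
    features.sort(key=lambda f: (f.chrom, f.start, f.feature_id))
    return features


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike,
              score_col: str | None = None, name_col: str | None = None) -> None:
    """Write intervals as BED3 or BED6 (0-based half-open, native).

    With `name_col`/`score_col` a BED6 is written; the score is clamped to
    the BED range [0, 1000].
    """
    cols = intervals[["chrom", "start", "end"]].copy()
    if (cols["start"] < 0).any():
        raise ValueError("negative coordinates cannot be written to BED")
    if name_col or score_col:
        cols["name"] = intervals[name_col] if name_col else "."
        score = intervals[score_col] if score_col else 0
        cols["score"] = np.clip(np.asarray(score, dtype=float), 0, 1000)
        cols["strand"] = intervals.get("strand", ".")
    cols.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike, sort: bool = True) -> pd.DataFrame:
    """Read BED3/BED6 into a table (chrom, start, end[, name, score, strand]).

    Sorted by (chrom, start) unless ``sort=False`` preserves file order.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:3])
    df.columns = names[: df.shape[1]]
    if (df["start"] < 0).any():
        raise ValueError(f"{path}: negative coordinates in BED")
    if sort:
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df


def write_bedgraph(score_track: pd.DataFrame, path: str | os.PathLike,
                   value_col: str = "score") -> None:
    """Write a per-probe score track as 4-column bedGraph."""
    score_track[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "score"], comment="#")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_id_list(path: str | os.PathLike) -> frozenset[str]:
    """One-column TSV of feature ids (header optional)."""
    p = Path(path)
    ids = []
    with open(p) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if token and token != "feature_id":
                ids.append(token)
    return frozenset(ids)


def write_id_list(ids: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\n")
        for i in sorted(ids):
            fh.write(f"{i}\n")
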