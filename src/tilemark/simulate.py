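"""Synthetic study generator with embedded ground truth.

Emulates, at reduced scale, the inputs of an endosperm H3K27me3 ChIP-chip
study: a multi-chromosome annotation (genes, pseudogenes, TEs, TEGs with
superfamily labels), dense probe tiling, IP/input/IgG replicate intensities
with enrichment domains and probe-affinity structure embedded, two-tissue
CG/CHG/CHH methylation with the shared-unmethylated / specific-methylated
contrast, and replicated expression matrices with spiked deregulation.

Every generator is deterministic for a fixed seed.  The probe-affinity model
is a scalar covariate per probe (uniform on [0, 1]) entering the intensity
model linearly; it plays the statistical role of a sequence-derived
probe-specific baseline and feeds the same quantile binning used for
standardization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import FEATURE_TYPES, Feature, GenomeSpec, default_genome

PROBE_COLUMNS = ("probe_id", "chrom", "start", "end", "affinity")
CHANNELS = ("IP", "input", "IgG")
TISSUES = ("vegetative", "endosperm")
CONTEXTS = ("CG", "CHG", "CHH")

#: Tissue panel used for expression clustering; the final three columns are
#: endosperm samples, the rest vegetative/seed tissues.
PANEL_TISSUES = (
    "seedling", "leaf", "stem", "root", "flower", "silique",
    "seed_torpedo", "seed_walking_stick", "seed_curled_cotyledon",
    "seed_early_green", "seed_green_cotyledon",
    "endosperm_preglobular", "endosperm_globular", "endosperm_heart",
)

DEFAULT_SUPERFAMILY_WEIGHTS = {
    "LTR/COPIA": 0.14,
    "LTR/GYPSY": 0.28,
    "LINE/L1": 0.10,
    "DNA/MuDR": 0.16,
    "RC/Helitron": 0.20,
    "RathE1": 0.05,
    "SINE": 0.07,
}

DEFAULT_CATEGORY_WEIGHTS = {
    "transcription_regulation": 0.12,
    "metabolism": 0.25,
    "cell_wall_organization": 0.08,
    "transport": 0.15,
    "chromatin_organization": 0.06,
    "signal_transduction": 0.14,
    "unknown_function": 0.20,
}

_LENGTH_RANGES = {
    "gene": (500, 3000),
    "pseudogene": (300, 1500),
    "TE": (300, 4000),
    "TEG": (500, 3000),
}

#: Mean methylation level per (target class, context, tissue).  Structure:
#: shared-class elements are essentially unmethylated in both tissues;
#: specific-class elements are densely methylated in vegetative tissue with a
#: marked reduction in the naturally hypomethylated endosperm; CHH is low
#: everywhere.  Background follows the genome-wide TE-like average.
DEFAULT_METHYLATION_MEANS: dict[tuple[str, str, str], float] = {
    ("shared", "CG", "vegetative"): 0.02,
    ("shared", "CG", "endosperm"): 0.02,
    ("shared", "CHG", "vegetative"): 0.01,
    ("shared", "CHG", "endosperm"): 0.01,
    ("shared", "CHH", "vegetative"): 0.02,
    ("shared", "CHH", "endosperm"): 0.015,
    ("specific", "CG", "vegetative"): 0.65,
    ("specific", "CG", "endosperm"): 0.30,
    ("specific", "CHG", "vegetative"): 0.35,
    ("specific", "CHG", "endosperm"): 0.15,
    ("specific", "CHH", "vegetative"): 0.04,
    ("specific", "CHH", "endosperm"): 0.03,
    ("background", "CG", "vegetative"): 0.45,
    ("background", "CG", "endosperm"): 0.32,
    ("background", "CHG", "vegetative"): 0.22,
    ("background", "CHG", "endosperm"): 0.14,
    ("background", "CHH", "vegetative"): 0.04,
    ("background", "CHH", "endosperm"): 0.03,
}


class PlacementError(RuntimeError):
    """Raised when requested features cannot be placed without overlap."""


@dataclass(frozen=True)
class SimTruth:
    """Ground truth embedded in a simulated ChIP experiment.

    domains: per-domain genomic interval and effect size (standardized-score
    units added to the IP channel); target_ids: features whose transcribed
    extent overlaps a domain; methylation_class: per-feature class in
    {shared, specific, background}.
    """

    domains: pd.DataFrame
    target_ids: frozenset[str]
    methylation_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.domains) and (self.domains["effect"] <= 0).any():
            raise ValueError("truth domain effect sizes must be positive")


def _rng(seed: int | None, spec: GenomeSpec | None = None) -> np.random.Generator:
    if seed is None and spec is not None:
        seed = spec.seed
    return np.random.default_rng(seed)


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float], size: int):
    labels = list(weights)
    p = np.asarray([weights[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=size, p=p)


def generate_annotation(
    spec: GenomeSpec,
    counts: Mapping[str, int],
    superfamily_weights: Mapping[str, float] | None = None,
    te_heterochromatin_bias: float | Mapping[str, float] = 0.16,
    category_weights: Mapping[str, float] | None = None,
    seed: int | None = None,
    max_tries: int = 300,
) -> list[Feature]:
    """Place non-overlapping features of each type on the genome.

    TEs and TEGs are placed with their midpoint in heterochromatin with
    probability `te_heterochromatin_bias` (a single fraction, or a mapping
    per feature type); genes and pseudogenes are placed uniformly.  Features
    never overlap another feature of the same type.  Deterministic for a
    fixed seed.

    Raises
    ------
    PlacementError
        If a feature cannot be placed without overlap within `max_tries`
        attempts, naming the feature type.
    """
    for ftype, n in counts.items():
        if ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {ftype!r}")
        if n < 0:
            raise ValueError("feature counts must be non-negative")
    if isinstance(te_heterochromatin_bias, Mapping):
        bias = dict(te_heterochromatin_bias)
    else:
        bias = {"TE": float(te_heterochromatin_bias), "TEG": float(te_heterochromatin_bias)}
    for b in bias.values():
        if not 0.0 <= b <= 1.0:
            raise ValueError("heterochromatin bias must lie in [0, 1]")
    superfamily_weights = dict(superfamily_weights or DEFAULT_SUPERFAMILY_WEIGHTS)
    category_weights = dict(category_weights or DEFAULT_CATEGORY_WEIGHTS)
    rng = _rng(seed, spec)
    chrom_names = [c for c, _ in spec.chromosomes]
    chrom_lengths = np.asarray([l for _, l in spec.chromosomes], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    features: list[Feature] = []
    for ftype in FEATURE_TYPES:  # fixed order => deterministic
        n = int(counts.get(ftype, 0))
        if n == 0:
            continue
        occupied = {c: IntervalTree() for c in chrom_names}
        lo, hi = _LENGTH_RANGES[ftype]
        want_het = (
            rng.random(n) < bias.get(ftype, 0.0)
            if ftype in ("TE", "TEG")
            else np.zeros(n, dtype=bool)
        )
        sfams = (
            _weighted_choice(rng, superfamily_weights, n)
            if ftype in ("TE", "TEG")
            else [""] * n
        )
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            placed = False
            for _ in range(max_tries):
                ci = rng.choice(len(chrom_names), p=chrom_p)
                chrom = chrom_names[ci]
                chrom_len = int(chrom_lengths[ci])
                if length >= chrom_len:
                    continue
                start = int(rng.integers(0, chrom_len - length))
                mid = start + length // 2
                if ftype in ("TE", "TEG"):
                    if spec.in_heterochromatin(chrom, mid) != bool(want_het[i]):
                        continue
                if occupied[chrom].overlap(start, start + length):
                    continue
                occupied[chrom].addi(start, start + length)
                if ftype in ("gene", "pseudogene"):
                    k = int(rng.integers(1, 4))
                    cats = frozenset(_weighted_choice(rng, category_weights, k))
                else:
                    cats = frozenset()
                features.append(
                    Feature(
                        feature_id=f"{ftype}_{i + 1:05d}",
                        chrom=chrom,
                        start=start,
                        end=start + length,
                        strand=str(strands[i]),
                        feature_type=ftype,
                        superfamily=str(sfams[i]),
                        categories=cats,
                    )
                )
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place feature {i + 1}/{n} of type {ftype!r} "
                    f"after {max_tries} attempts"
                )
    features.sort(key=lambda f: (f.chrom, f.start, f.feature_id))
    return features


def generate_probes(
    spec: GenomeSpec,
    mean_spacing: int = 35,
    probe_length: int = 25,
    spacing_jitter: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tile the genome with probes at jittered spacing.

    Returns a layout table (probe_id, chrom, start, end, affinity) sorted by
    (chrom, start).  The affinity covariate is uniform on [0, 1] per probe.
    A chromosome shorter than one spacing step yields no probes.
    """
    if mean_spacing < 1:
        raise ValueError("mean_spacing must be >= 1")
    if probe_length < 1:
        raise ValueError("probe_length must be >= 1")
    rng = _rng(seed, spec)
    rows = []
    for chrom, length in spec.chromosomes:
        pos = int(rng.integers(0, mean_spacing))
        i = 0
        while pos + probe_length <= length:
            rows.append((f"{chrom}_p{i:06d}", chrom, pos, pos + probe_length))
            step = int(round(rng.normal(mean_spacing, spacing_jitter * mean_spacing)))
            pos += max(1, step)
            i += 1
    layout = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    layout["affinity"] = rng.uniform(0.0, 1.0, size=len(layout))
    layout = layout.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return layout


def generate_truth(
    spec: GenomeSpec,
    features: Sequence[Feature],
    n_gene_domains: int = 30,
    n_te_domains: int = 10,
    effect: float = 2.0,
    min_length: int = 600,
    pad: int = 150,
    min_separation: int = 2000,
    seed: int | None = None,
) -> SimTruth:
    """Sample enrichment domains over gene bodies and TE/TEG elements.

    Domains cover the transcribed extent of sampled features (padded by
    `pad` bp and expanded to at least `min_length` bp) so that gene-body
    metagene structure and region-boundary recovery are both exercised.
    Domains are kept at least `min_separation` bp apart so each maps to one
    called region.
    """
    if effect <= 0:
        raise ValueError("domain effect must be positive")
    rng = _rng(seed, spec)
    genes = [f for f in features if f.feature_type == "gene"]
    tes = [f for f in features if f.feature_type in ("TE", "TEG")]
    rng.shuffle(genes)
    rng.shuffle(tes)

    chosen: list[tuple[str, int, int]] = []

    def try_add(f: Feature) -> bool:
        start = max(0, f.start - pad)
        end = min(spec.chrom_length(f.chrom), f.end + pad)
        if end - start < min_length:
            extra = min_length - (end - start)
            start = max(0, start - extra // 2)
            end = min(spec.chrom_length(f.chrom), start + min_length)
        for c, s, e in chosen:
            if c == f.chrom and s - min_separation < end and start < e + min_separation:
                return False
        chosen.append((f.chrom, start, end))
        return True

    placed_genes = 0
    for f in genes:
        if placed_genes >= n_gene_domains:
            break
        placed_genes += try_add(f)
    placed_tes = 0
    for f in tes:
        if placed_tes >= n_te_domains:
            break
        placed_tes += try_add(f)

    domains = pd.DataFrame(chosen, columns=["chrom", "start", "end"])
    domains["effect"] = effect
    domains = domains.sort_values(["chrom", "start"]).reset_index(drop=True)

    target_ids = set()
    for f in features:
        sub = domains[domains["chrom"] == f.chrom]
        if ((sub["start"] < f.end) & (f.start < sub["end"])).any():
            target_ids.add(f.feature_id)
    return SimTruth(domains=domains, target_ids=frozenset(target_ids))


def simulate_chip(
    layout: pd.DataFrame,
    truth: SimTruth,
    noise_sd: float = 1.0,
    affinity_effect: float = 1.0,
    n_reps: int = 3,
    baseline: float = 10.0,
    spec: GenomeSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate IP/input/IgG log2 intensities over a probe layout.

    Model per probe and replicate::

        log2 intensity = baseline + affinity_effect * affinity
                         + effect (IP channel only, probe midpoint inside a
                           truth domain)
                         + Normal(0, noise_sd)

    With the default ``noise_sd = 1`` the per-probe standardized scale is
    ~1, so domain effects are expressed directly in standardized-score
    units.  Returns the layout with one column per channel x replicate
    (``IP_1`` ... ``IgG_n``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if spec is not None and len(truth.domains):
        for row in truth.domains.itertuples(index=False):
            if not (0 <= row.start < row.end <= spec.chrom_length(row.chrom)):
                raise ValueError(
                    f"truth domain [{row.start}, {row.end}) outside {row.chrom!r}"
                )
    rng = _rng(seed, spec)
    track = layout.copy()
    mid = (track["start"].to_numpy() + track["end"].to_numpy()) // 2
    effect = np.zeros(len(track))
    for row in truth.domains.itertuples(index=False):
        inside = (track["chrom"].to_numpy() == row.chrom) & (mid >= row.start) & (mid < row.end)
        effect[inside] += row.effect
    base = baseline + affinity_effect * track["affinity"].to_numpy()
    for channel in CHANNELS:
        for rep in range(1, n_reps + 1):
            noise = rng.normal(0.0, noise_sd, size=len(track))
            signal = base + noise + (effect if channel == "IP" else 0.0)
            track[f"{channel}_{rep}"] = signal
    return track


def simulate_methylation(
    features: Sequence[Feature],
    class_map: Mapping[str, str],
    params: Mapping[tuple[str, str, str], float] | None = None,
    mean_coverage: float = 50.0,
    concentration: float = 120.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-element weighted methylation for two tissues.

    `class_map` assigns every feature to {shared, specific, background};
    `params` gives the mean level per (class, context, tissue).  Element
    levels are Beta-distributed around the class mean; counts are binomial
    with Poisson coverage weights.  Levels are fractions in [0, 1].
    """
    params = dict(params or DEFAULT_METHYLATION_MEANS)
    for key, mu in params.items():
        if not 0.0 <= mu <= 1.0:
            raise ValueError(f"mean methylation for {key} outside [0, 1]")
    missing = [f.feature_id for f in features if f.feature_id not in class_map]
    if missing:
        raise ValueError(f"features without methylation class: {missing[:3]}...")
    rng = np.random.default_rng(seed)
    rows = []
    for f in features:
        cls = class_map[f.feature_id]
        for context in CONTEXTS:
            for tissue in TISSUES:
                mu = params[(cls, context, tissue)]
                if mu <= 0.0:
                    level = 0.0
                elif mu >= 1.0:
                    level = 1.0
                else:
                    level = rng.beta(mu * concentration, (1.0 - mu) * concentration)
                total = int(rng.poisson(mean_coverage)) + 1
                meth = int(rng.binomial(total, level))
                rows.append((f.feature_id, tissue, context, meth, total))
    rec = pd.DataFrame(
        rows, columns=["feature_id", "tissue", "context", "methylated_weight", "total_weight"]
    )
    rec["level"] = rec["methylated_weight"] / rec["total_weight"]
    return rec


def simulate_expression(
    feature_ids: Sequence[str],
    deregulated_set: Iterable[str],
    log2_effect: float = 2.0,
    n_reps: int = 3,
    noise_sd: float = 0.4,
    baseline_mean: float = 6.0,
    baseline_sd: float = 2.0,
    conditions: tuple[str, str] = ("wild_type", "mutant"),
    seed: int | None = None,
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Two-condition replicated log2 expression with spiked deregulation.

    Null genes share their mean across conditions; deregulated genes are
    shifted by `log2_effect` in the second (mutant) condition.  Returns the
    genes x samples matrix and the truth labels (empty when the effect is
    zero, by construction).
    """
    if n_reps < 2:
        raise ValueError("rank-product analysis needs >= 2 replicates per condition")
    dereg = frozenset(deregulated_set)
    unknown = dereg - set(feature_ids)
    if unknown:
        raise ValueError(f"deregulated ids not in feature set: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)
    ids = list(feature_ids)
    base = rng.normal(baseline_mean, baseline_sd, size=len(ids))
    shift = np.asarray([log2_effect if g in dereg else 0.0 for g in ids])
    data = {}
    for rep in range(1, n_reps + 1):
        data[f"{conditions[0]}_{rep}"] = base + rng.normal(0, noise_sd, len(ids))
    for rep in range(1, n_reps + 1):
        data[f"{conditions[1]}_{rep}"] = base + shift + rng.normal(0, noise_sd, len(ids))
    expr = pd.DataFrame(data, index=pd.Index(ids, name="feature_id"))
    truth = dereg if log2_effect != 0.0 else frozenset()
    return expr, truth


def simulate_tissue_panel(
    feature_ids: Sequence[str],
    archetype_map: Mapping[str, str],
    tissues: Sequence[str] = PANEL_TISSUES,
    noise_sd: float = 0.6,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expression across a tissue panel with planted archetypes.

    Archetypes: ``endosperm_repressed`` (expressed in vegetative/seed
    tissues, silent in endosperm columns) and ``endosperm_expressed`` (the
    converse); anything else gets a flat intermediate profile.
    """
    rng = np.random.default_rng(seed)
    is_endo = np.asarray([t.startswith("endosperm") for t in tissues])
    rows = []
    for g in feature_ids:
        arch = archetype_map.get(g, "flat")
        if arch == "endosperm_repressed":
            mean = np.where(is_endo, 2.0, 8.0)
        elif arch == "endosperm_expressed":
            mean = np.where(is_endo, 9.0, 3.0)
        else:
            mean = np.full(len(tissues), 5.0)
        rows.append(mean + rng.normal(0, noise_sd, len(tissues)))
    return pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature_id"),
                        columns=list(tissues))


@dataclass
class StudyBundle:
    """Everything a full pipeline run consumes, with ground truth attached."""

    spec: GenomeSpec
    features: list[Feature]
    layout: pd.DataFrame
    track: pd.DataFrame
    truth: SimTruth
    reference_targets: frozenset[str]
    methylation: pd.DataFrame
    expression: pd.DataFrame
    deregulated_truth: frozenset[str]
    tissue_panel: pd.DataFrame


def simulate_study(
    seed: int = 0,
    spec: GenomeSpec | None = None,
    counts: Mapping[str, int] | None = None,
    te_heterochromatin_bias: Mapping[str, float] | None = None,
    n_gene_domains: int = 30,
    n_te_domains: int = 10,
    domain_effect: float = 2.0,
    noise_sd: float = 1.0,
    n_reps: int = 3,
    shared_fraction: float = 0.865,
    dereg_fraction: float = 0.02,
    dereg_log2_effect: float = 2.0,
) -> StudyBundle:
    """Generate one complete synthetic study.

    Defaults define the study conditions: a ~1.2 Mb three-chromosome genome
    with central heterochromatic blocks, ~35 bp probe tiling, 40 enrichment
    domains of >= 600 bp at effect 2.0 standardized-score units over three
    IP/input/IgG replicates, a seedling-style reference list containing
    86.5% of the true targets, Fig-5-style two-tissue methylation, and a
    mutant-vs-wild-type expression contrast deregulating 2% of genes.
    """
    from ._util import derive_seed

    spec = spec or default_genome(seed=seed)
    counts = dict(counts or {"gene": 300, "pseudogene": 30, "TE": 150, "TEG": 40})
    bias = dict(te_heterochromatin_bias or {"TE": 0.16, "TEG": 0.46})

    features = generate_annotation(
        spec, counts, te_heterochromatin_bias=bias, seed=derive_seed(seed, "annotation")
    )
    layout = generate_probes(spec, seed=derive_seed(seed, "probes"))
    truth = generate_truth(
        spec, features,
        n_gene_domains=n_gene_domains, n_te_domains=n_te_domains,
        effect=domain_effect, seed=derive_seed(seed, "truth"),
    )
    track = simulate_chip(
        layout, truth, noise_sd=noise_sd, n_reps=n_reps, spec=spec,
        seed=derive_seed(seed, "chip"),
    )

    rng = np.random.default_rng(derive_seed(seed, "reference"))
    gene_like = [f.feature_id for f in features if f.feature_type in ("gene", "pseudogene")]
    targets = sorted(truth.target_ids)
    shared = {t for t in targets if rng.random() < shared_fraction}
    extra = {g for g in gene_like if g not in truth.target_ids and rng.random() < 0.3}
    reference = frozenset(shared | extra)

    class_map = {}
    for f in features:
        if f.feature_id in truth.target_ids:
            class_map[f.feature_id] = "shared" if f.feature_id in reference else "specific"
        else:
            class_map[f.feature_id] = "background"
    methylation = simulate_methylation(
        features, class_map, seed=derive_seed(seed, "methylation")
    )

    all_ids = [f.feature_id for f in features]
    n_dereg = max(1, int(round(dereg_fraction * len(all_ids))))
    dereg = rng.choice(all_ids, size=n_dereg, replace=False).tolist()
    expression, dereg_truth = simulate_expression(
        all_ids, dereg, log2_effect=dereg_log2_effect, n_reps=n_reps,
        seed=derive_seed(seed, "expression"),
    )

    specific = [t for t in targets if t not in reference]
    arch = {g: ("endosperm_repressed" if i % 2 == 0 else "endosperm_expressed")
            for i, g in enumerate(specific)}
    panel = simulate_tissue_panel(specific or all_ids[:10], arch,
                                  seed=derive_seed(seed, "panel"))

    truth = SimTruth(domains=truth.domains, target_ids=truth.target_ids,
                     methylation_class=class_map)
    return StudyBundle(
        spec=spec, features=features, layout=layout, track=track, truth=truth,
        reference_targets=reference, methylation=methylation,
        expression=expression, deregulated_truth=dereg_truth, tissue_panel=panel,
    )
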