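"""Synthetic-data generator: determinism, embedded structure, error contracts."""

import numpy as np
import pandas as pd
import pytest

import tilemark as tm
from tilemark.genome import annotation_frame
from tilemark.simulate import SimTruth, simulate_methylation


@pytest.fixture(scope="module")
def genome():
    return tm.default_genome(seed=7)


class TestGenerateAnnotation:
    def test_zero_counts_give_empty_annotation(self, genome):
        assert tm.generate_annotation(genome, {}) == []

    def test_seeded_determinism(self, genome):
        counts = {"gene": 40, "TE": 25, "TEG": 5, "pseudogene": 5}
        a = tm.generate_annotation(genome, counts, seed=7)
        b = tm.generate_annotation(genome, counts, seed=7)
        assert a == b

    def test_type_counts_match_request(self, genome):
        counts = {"gene": 40, "TE": 25, "TEG": 5, "pseudogene": 5}
        ann = annotation_frame(tm.generate_annotation(genome, counts, seed=3))
        assert ann["feature_type"].value_counts().to_dict() == counts

    def test_no_overlap_within_type(self, genome):
        ann = annotation_frame(
            tm.generate_annotation(genome, {"gene": 120}, seed=5)
        ).sort_values(["chrom", "start"])
        for _, sub in ann.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_te_heterochromatin_bias_near_requested_fraction(self):
        """Binomial expectation: TE midpoints in heterochromatin ~ 16 +/- 3 pp."""
        genome = tm.default_genome(seed=0, n_chromosomes=3, chrom_length=2_000_000)
        feats = tm.generate_annotation(
            genome, {"TE": 1000}, te_heterochromatin_bias=0.16, seed=9
        )
        frac = np.mean([genome.in_heterochromatin(f.chrom, f.midpoint) for f in feats])
        assert abs(frac - 0.16) <= 0.03

    def test_impossible_placement_raises_naming_type(self):
        tiny = tm.GenomeSpec(chromosomes=(("Chr1", 4000),), seed=0)
        with pytest.raises(Exception, match="gene"):
            tm.generate_annotation(tiny, {"gene": 500}, seed=0)


class TestGenerateProbes:
    def test_probe_count_and_bounds(self):
        genome = tm.GenomeSpec(chromosomes=(("Chr1", 10_000),), seed=1)
        layout = tm.generate_probes(genome, mean_spacing=35, probe_length=25, seed=2)
        assert abs(len(layout) - 10_000 // 35) <= 15  # jitter tolerance
        assert (layout["start"] >= 0).all() and (layout["end"] <= 10_000).all()
        assert layout["affinity"].between(0, 1).all()

    def test_sorted_and_deterministic(self, genome):
        a = tm.generate_probes(genome, seed=4)
        b = tm.generate_probes(genome, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert a.equals(a.sort_values(["chrom", "start"]).reset_index(drop=True))

    def test_zero_probe_length_rejected(self, genome):
        with pytest.raises(ValueError):
            tm.generate_probes(genome, probe_length=0)

    def test_chromosome_shorter_than_spacing_yields_no_probes(self):
        genome = tm.GenomeSpec(chromosomes=(("Chr1", 10),), seed=0)
        assert len(tm.generate_probes(genome, mean_spacing=50, probe_length=25, seed=0)) == 0


class TestSimulateChip:
    def test_null_signal_ip_matches_input(self, genome):
        layout = tm.generate_probes(genome, seed=1)
        empty = SimTruth(
            domains=pd.DataFrame(columns=["chrom", "start", "end", "effect"]),
            target_ids=frozenset(),
        )
        track = tm.simulate_chip(layout, empty, noise_sd=1e-6, affinity_effect=0.0,
                                 n_reps=1, seed=3)
        assert np.allclose(track["IP_1"], track["input_1"], atol=1e-4)

    def test_domain_effect_recovered_by_sample_mean(self, genome):
        layout = tm.generate_probes(genome, seed=1)
        domains = pd.DataFrame(
            [("Chr1", 10_000, 20_000, 2.0)], columns=["chrom", "start", "end", "effect"]
        )
        truth = SimTruth(domains=domains, target_ids=frozenset())
        track = tm.simulate_chip(layout, truth, noise_sd=1.0, n_reps=1, seed=5)
        mid = (track["start"] + track["end"]) // 2
        inside = (track["chrom"] == "Chr1") & (mid >= 10_000) & (mid < 20_000)
        diff = (track.loc[inside, "IP_1"] - track.loc[inside, "input_1"])
        se = np.sqrt(2.0) / np.sqrt(inside.sum())
        assert abs(diff.mean() - 2.0) < 3 * se

    def test_replicate_columns_per_channel(self, genome):
        layout = tm.generate_probes(genome, seed=1)
        empty = SimTruth(domains=pd.DataFrame(columns=["chrom", "start", "end", "effect"]),
                         target_ids=frozenset())
        track = tm.simulate_chip(layout, empty, n_reps=3, seed=2)
        for ch in ("IP", "input", "IgG"):
            assert [f"{ch}_{r}" for r in (1, 2, 3)] == [
                c for c in track.columns if c.startswith(f"{ch}_")
            ]

    def test_domain_outside_chromosome_rejected(self, genome):
        layout = tm.generate_probes(genome, seed=1)
        domains = pd.DataFrame([("Chr1", 0, 10**9, 2.0)],
                               columns=["chrom", "start", "end", "effect"])
        with pytest.raises(ValueError, match="outside"):
            tm.simulate_chip(layout, SimTruth(domains=domains, target_ids=frozenset()),
                             spec=genome, seed=0)


@pytest.fixture(scope="module")
def elements(genome):
    feats = tm.generate_annotation(genome, {"TE": 120}, seed=21)
    half = len(feats) // 2
    class_map = {f.feature_id: ("shared" if i < half else "specific")
                 for i, f in enumerate(feats)}
    rec = simulate_methylation(feats, class_map, seed=22)
    return feats, class_map, rec


class TestSimulateMethylation:

    def test_shared_elements_near_zero_cg(self, elements):
        feats, class_map, rec = elements
        shared = [fid for fid, c in class_map.items() if c == "shared"]
        sub = rec[(rec["feature_id"].isin(shared)) & (rec["context"] == "CG")]
        assert sub.groupby("tissue")["level"].median().max() < 0.05

    def test_specific_elements_lose_methylation_in_endosperm(self, elements):
        feats, class_map, rec = elements
        spec_ids = [fid for fid, c in class_map.items() if c == "specific"]
        sub = rec[(rec["feature_id"].isin(spec_ids)) & (rec["context"] == "CG")]
        wide = sub.pivot(index="feature_id", columns="tissue", values="level")
        assert (wide["vegetative"] > wide["endosperm"]).mean() >= 0.95

    def test_all_zero_params_give_zero_records(self, genome):
        feats = tm.generate_annotation(genome, {"TE": 10}, seed=2)
        params = {(c, ctx, t): 0.0 for c in ("shared",)
                  for ctx in ("CG", "CHG", "CHH") for t in ("vegetative", "endosperm")}
        rec = simulate_methylation(feats, {f.feature_id: "shared" for f in feats},
                                   params=params, seed=3)
        assert (rec["methylated_weight"] == 0).all()

    def test_mean_outside_unit_interval_rejected(self, genome):
        feats = tm.generate_annotation(genome, {"TE": 2}, seed=2)
        params = {(c, ctx, t): 1.5 for c in ("shared",)
                  for ctx in ("CG", "CHG", "CHH") for t in ("vegetative", "endosperm")}
        with pytest.raises(ValueError, match="outside"):
            simulate_methylation(feats, {f.feature_id: "shared" for f in feats},
                                 params=params)


class TestSimulateExpression:
    def test_zero_effect_means_empty_truth(self):
        _, truth = tm.simulate_expression(["a", "b", "c"], ["a"], log2_effect=0.0, seed=1)
        assert truth == frozenset()

    def test_spiked_effect_recovered_by_sample_mean(self):
        ids = [f"g{i}" for i in range(500)]
        expr, truth = tm.simulate_expression(ids, ids[:50], log2_effect=2.0,
                                             n_reps=3, seed=4)
        mut = expr[[c for c in expr.columns if c.startswith("mutant")]]
        wt = expr[[c for c in expr.columns if c.startswith("wild_type")]]
        diff = (mut.mean(axis=1) - wt.mean(axis=1)).loc[list(truth)]
        assert abs(diff.mean() - 2.0) < 0.1

    def test_seeded_determinism(self):
        a, _ = tm.simulate_expression(["a", "b"], [], seed=9)
        b, _ = tm.simulate_expression(["a", "b"], [], seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            tm.simulate_expression(["a"], [], n_reps=1)


def test_study_bundle_is_reproducible():
    a = tm.simulate_study(seed=42)
    b = tm.simulate_study(seed=42)
    pd.testing.assert_frame_equal(a.track, b.track)
    pd.testing.assert_frame_equal(a.methylation, b.methylation)
    assert a.reference_targets == b.reference_targets
    assert a.truth.target_ids == b.truth.target_ids
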