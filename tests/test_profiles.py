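"""Metagene profiles, chromosomal densities, and box-plot summaries."""

import numpy as np
import pandas as pd
import pytest

import tilemark as tm
from tilemark.genome import Feature
from tilemark.profiles import ProfileParams, chromosome_density, metagene_profile, score_by_group


def make_score_track(starts, scores, chrom="Chr1", probe_len=25):
    return pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(len(starts))],
        "chrom": chrom,
        "start": starts,
        "end": [s + probe_len for s in starts],
        "score": scores,
    })


def feat(fid, start, end, strand="+", chrom="Chr1", ftype="gene"):
    return Feature(feature_id=fid, chrom=chrom, start=start, end=end,
                   strand=strand, feature_type=ftype)


def naive_metagene(track, genes, params):
    """Oracle: explicit per-gene, per-probe binning on oriented coordinates."""
    fb, bb = params.flank_bins, params.body_bins
    total = 2 * fb + bb
    sums, counts = np.zeros(total), np.zeros(total, dtype=int)
    for g in genes:
        sub = track[track["chrom"] == g.chrom]
        for _, p in sub.iterrows():
            pos = p["start"]
            if pos < g.start - params.flank_bp or pos >= g.end + params.flank_bp:
                continue
            if pos < g.start:
                b = int((pos - (g.start - params.flank_bp)) // params.flank_bin_bp)
            elif pos >= g.end:
                b = fb + bb + min(int((pos - g.end) // params.flank_bin_bp), fb - 1)
            else:
                b = fb + min(int((pos - g.start) * bb // (g.end - g.start)), bb - 1)
            if g.strand == "-":
                b = total - 1 - b
            sums[b] += p["score"]
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


class TestMetageneProfile:
    def test_flat_signal_yields_flat_profile(self):
        starts = np.arange(0, 20_000, 50)
        t = make_score_track(starts, np.full(len(starts), 2.5))
        prof = metagene_profile(t, [feat("g", 5000, 9000)])
        assert np.allclose(prof["mean_score"].dropna(), 2.5)

    def test_minus_strand_step_signal_maps_to_five_prime_bins(self):
        """Signal only in the 5'-most 10% of a minus-strand gene peaks in
        body bins 0-1, not 18-19."""
        starts = np.arange(0, 20_000, 50)
        scores = np.zeros(len(starts))
        # minus-strand gene [5000, 15000): its 5' end is at 15000
        scores[(starts >= 14_000) & (starts < 15_000)] = 10.0
        t = make_score_track(starts, scores)
        prof = metagene_profile(t, [feat("g", 5000, 15_000, strand="-")])
        body = prof[prof["segment"] == "body"].set_index("bin")["mean_score"]
        assert body.loc[0] > 5 and body.loc[1] > 5
        assert body.loc[18] == 0 and body.loc[19] == 0

    def test_matches_naive_recomputation_on_random_genes(self):
        rng = np.random.default_rng(12)
        starts = np.sort(rng.choice(np.arange(0, 200_000), 3000, replace=False))
        t = make_score_track(starts, rng.normal(size=3000))
        genes = []
        for i in range(50):
            s = int(rng.integers(3000, 180_000))
            genes.append(feat(f"g{i}", s, s + int(rng.integers(800, 5000)),
                              strand=rng.choice(["+", "-"])))
        params = ProfileParams()
        prof = metagene_profile(t, genes, params)
        mean, counts = naive_metagene(t, genes, params)
        np.testing.assert_allclose(prof["mean_score"].to_numpy(), mean, atol=1e-10)
        np.testing.assert_array_equal(prof["n_probes"].to_numpy(), counts)

    def test_empty_gene_set_rejected(self):
        t = make_score_track([0], [1.0])
        with pytest.raises(ValueError, match="non-empty"):
            metagene_profile(t, [])


class TestChromosomeDensity:
    def test_midpoint_assigns_window(self):
        spec = tm.GenomeSpec(chromosomes=(("Chr1", 600_000),))
        regions = pd.DataFrame({"chrom": ["Chr1"], "start": [245_000], "end": [255_000]})
        dens = chromosome_density(regions, [], spec)
        # midpoint 250 kb -> second 200-kb window
        assert dens.loc[dens["window_start"] == 200_000, "n_regions"].iloc[0] == 1
        assert dens["n_regions"].sum() == 1

    def test_counts_conserved_on_random_inputs(self):
        rng = np.random.default_rng(13)
        spec = tm.GenomeSpec(chromosomes=(("Chr1", 1_000_000), ("Chr2", 700_000)))
        n = 300
        chroms = rng.choice(["Chr1", "Chr2"], n)
        starts = rng.integers(0, 600_000, n)
        regions = pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + 500})
        feats = [feat(f"f{i}", int(s), int(s) + 300, chrom=c,
                      ftype=rng.choice(["gene", "TE"]))
                 for i, (c, s) in enumerate(zip(chroms, starts))]
        dens = chromosome_density(regions, feats, spec)
        assert dens["n_regions"].sum() == n
        assert dens["n_genes"].sum() + dens["n_TEs"].sum() == n

    def test_empty_chromosome_keeps_zero_rows(self):
        spec = tm.GenomeSpec(chromosomes=(("Chr1", 400_000), ("Chr2", 400_000)))
        regions = pd.DataFrame({"chrom": ["Chr1"], "start": [0], "end": [100]})
        dens = chromosome_density(regions, [], spec)
        chr2 = dens[dens["chrom"] == "Chr2"]
        assert len(chr2) == 2 and (chr2["n_regions"] == 0).all()


class TestScoreByGroup:
    def _calls(self, scores, cls="shared"):
        return pd.DataFrame({
            "feature_id": [f"f{i}" for i in range(len(scores))],
            "feature_type": "gene",
            "gene_score": scores,
            "is_target": True,
            "target_class": cls,
            "in_heterochromatin": False,
        })

    def test_hand_quartiles(self):
        out = score_by_group(self._calls([1, 2, 3, 4, 5]))
        row = out.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (2, 3, 4)

    def test_singleton_group_collapses_five_numbers(self):
        row = score_by_group(self._calls([4.2])).iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 4.2

    def test_empty_group_absent(self):
        out = score_by_group(self._calls([]))
        assert len(out) == 0

    def test_expression_split_at_threshold(self):
        calls = self._calls([1.0, 2.0, 3.0, 4.0])
        expr = {"f0": 1.0, "f1": 2.0, "f2": 6.0, "f3": 8.0}
        out = score_by_group(calls, expression=expr)
        strata = dict(zip(out["stratum"], out["n"]))
        assert strata == {"low": 2, "moderate": 2}


def test_target_profile_dominates_non_targets(study, scored, calls):
    """Gene-body enrichment separates targets from non-targets in every bin."""
    tset = set(calls.loc[calls["is_target"], "feature_id"])
    genes = [f for f in study.features if f.feature_type == "gene"]
    t_prof = metagene_profile(scored, [f for f in genes if f.feature_id in tset])
    n_prof = metagene_profile(scored, [f for f in genes if f.feature_id not in tset])
    t_body = t_prof[t_prof["segment"] == "body"]["mean_score"].to_numpy()
    n_body = n_prof[n_prof["segment"] == "body"]["mean_score"].to_numpy()
    assert (t_body > n_body).all()
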