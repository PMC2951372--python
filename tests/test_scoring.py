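"""Standardization and windowed scoring, against hand values and a naive
window-by-window oracle."""

import math

import numpy as np
import pandas as pd
import pytest

import tilemark as tm
from tilemark.scoring import ScoringParams, enrichment_signal, mat_score, standardize


def make_track(starts, values=None, chrom="Chr1", probe_len=25):
    df = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(len(starts))],
        "chrom": chrom,
        "start": starts,
        "end": [s + probe_len for s in starts],
        "affinity": np.linspace(0.1, 0.9, len(starts)),
    })
    if values is not None:
        df["enrichment"] = values
    return df


class TestStandardize:
    def test_hand_computed_bin(self):
        """Values {1,2,3} in one bin: median 2, MAD 1 -> t = +/-1/1.4826."""
        track = make_track([0, 100, 200])
        for ch in ("IP", "input", "IgG"):
            track[f"{ch}_1"] = [1.0, 2.0, 3.0]
        out = standardize(track, ScoringParams(n_affinity_bins=1))
        np.testing.assert_allclose(
            out["z_IP_1"], [-0.6745, 0.0, 0.6745], atol=1e-4
        )

    def test_constant_bin_floored_to_zero(self):
        track = make_track([0, 100, 200])
        for ch in ("IP", "input", "IgG"):
            track[f"{ch}_1"] = 5.0
        out = standardize(track, ScoringParams(n_affinity_bins=1))
        assert (out["z_IP_1"] == 0).all()

    def test_shift_equivariance_within_bin(self):
        """Adding a constant to a bin's intensities leaves t unchanged."""
        rng = np.random.default_rng(0)
        track = make_track(np.arange(0, 3000, 100))
        for ch in ("IP", "input", "IgG"):
            track[f"{ch}_1"] = rng.normal(10, 1, len(track))
        base = standardize(track, ScoringParams(n_affinity_bins=1))
        shifted = track.copy()
        shifted["IP_1"] = shifted["IP_1"] + 7.5
        out = standardize(shifted, ScoringParams(n_affinity_bins=1))
        np.testing.assert_allclose(out["z_IP_1"], base["z_IP_1"], atol=1e-12)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        track = make_track(np.arange(0, 5000, 50))
        for ch in ("IP", "input", "IgG"):
            track[f"{ch}_1"] = rng.normal(10, 1, len(track))
        out = standardize(track, ScoringParams(n_affinity_bins=4))
        shuffled = track.sample(frac=1.0, random_state=3)
        out2 = standardize(shuffled, ScoringParams(n_affinity_bins=4))
        pd.testing.assert_frame_equal(out, out2)

    def test_missing_intensity_names_probe(self):
        track = make_track([0, 100])
        for ch in ("IP", "input", "IgG"):
            track[f"{ch}_1"] = [1.0, np.nan]
        with pytest.raises(ValueError, match="p1"):
            standardize(track)

    def test_fewer_probes_than_bins_collapses_with_warning(self):
        track = make_track([0, 100])
        for ch in ("IP", "input", "IgG"):
            track[f"{ch}_1"] = [1.0, 2.0]
        with pytest.warns(UserWarning, match="collapsing"):
            standardize(track, ScoringParams(n_affinity_bins=20))


class TestEnrichmentSignal:
    def _standardized(self, z_ip, z_in, z_igg):
        track = make_track(np.arange(len(z_ip)) * 100)
        track["z_IP_1"] = z_ip
        track["z_input_1"] = z_in
        track["z_IgG_1"] = z_igg
        return track

    def test_identical_channels_give_zero(self):
        t = self._standardized([1.0, -2.0], [1.0, -2.0], [1.0, -2.0])
        assert (enrichment_signal(t)["enrichment"] == 0).all()

    def test_equal_weight_average_of_contrasts(self):
        """IP-input = 2 and IP-IgG = 1 everywhere -> e = 1.5."""
        t = self._standardized([2.0, 2.0], [0.0, 0.0], [1.0, 1.0])
        assert (enrichment_signal(t)["enrichment"] == 1.5).all()

    def test_matches_probe_by_probe_recomputation(self):
        rng = np.random.default_rng(2)
        n = 300
        track = make_track(np.arange(n) * 40)
        for ch in ("IP", "input", "IgG"):
            for r in (1, 2):
                track[f"z_{ch}_{r}"] = rng.normal(size=n)
        out = enrichment_signal(track)
        for i in range(0, n, 37):
            row = out.iloc[i]
            e_in = np.mean([row["z_IP_1"] - row["z_input_1"],
                            row["z_IP_2"] - row["z_input_2"]])
            e_igg = np.mean([row["z_IP_1"] - row["z_IgG_1"],
                             row["z_IP_2"] - row["z_IgG_2"]])
            assert row["enrichment"] == pytest.approx((e_in + e_igg) / 2)

    def test_missing_control_rejected(self):
        track = make_track([0])
        track["z_IP_1"] = [1.0]
        with pytest.raises(ValueError, match="control"):
            enrichment_signal(track)


def naive_mat_score(track, params):
    """Independent O(n*w) oracle: explicit per-probe window recomputation."""
    out = []
    for _, row in track.iterrows():
        window = []
        for _, other in track.iterrows():
            if other["chrom"] == row["chrom"] and \
               abs(other["start"] - row["start"]) <= params.window_size / 2:
                window.append(other["enrichment"])
        window.sort()
        k = int(math.floor(params.trim_fraction * len(window)))
        kept = window[k:len(window) - k] if k else window
        out.append(sum(kept) / len(kept) * math.sqrt(len(kept)))
    return np.asarray(out)


class TestMatScore:
    def test_uniform_window_scales_by_sqrt_count(self):
        """Four probes of value 1 in one window, nothing trimmed -> 2.0."""
        t = make_track([0, 100, 150, 200], values=[1.0, 1.0, 1.0, 1.0])
        out = mat_score(t, ScoringParams(window_size=500, trim_fraction=0.10))
        assert out.loc[out["start"] == 100, "score"].iloc[0] == pytest.approx(2.0)

    def test_isolated_probe_keeps_its_value(self):
        t = make_track([0, 5000], values=[3.7, -1.2])
        out = mat_score(t, ScoringParams(window_size=500))
        np.testing.assert_allclose(out["score"], [3.7, -1.2])

    def test_matches_naive_window_oracle(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.choice(np.arange(0, 40_000, 10), size=1000, replace=False))
        t = make_track(starts, values=rng.normal(size=1000))
        params = ScoringParams(window_size=500, trim_fraction=0.10)
        out = mat_score(t, params)
        np.testing.assert_allclose(out["score"], naive_mat_score(t, params), atol=1e-10)

    def test_windows_do_not_cross_chromosomes(self):
        t1 = make_track([0, 100], values=[1.0, 1.0], chrom="Chr1")
        t2 = make_track([0, 100], values=[5.0, 5.0], chrom="Chr2")
        t = pd.concat([t1, t2], ignore_index=True)
        out = mat_score(t, ScoringParams(window_size=500))
        assert out.loc[out["chrom"] == "Chr1", "score"].max() < 2.0

    def test_reflection_symmetry(self):
        """Mirroring a chromosome maps scores onto mirrored probes."""
        rng = np.random.default_rng(6)
        starts = np.sort(rng.choice(np.arange(0, 20_000), size=200, replace=False))
        values = rng.normal(size=200)
        t = make_track(starts, values=values)
        fwd = mat_score(t, ScoringParams(window_size=500))
        mirrored = make_track(np.sort(20_000 - starts), values=values[::-1])
        rev = mat_score(mirrored, ScoringParams(window_size=500))
        np.testing.assert_allclose(fwd["score"].to_numpy(),
                                   rev["score"].to_numpy()[::-1], atol=1e-10)


def test_null_simulation_rarely_exceeds_threshold():
    """Without domains, fewer than 0.2% of probe scores reach 3.5."""
    from tilemark.simulate import SimTruth

    spec = tm.GenomeSpec(chromosomes=(("Chr1", 40_000),), seed=0)
    empty = SimTruth(domains=pd.DataFrame(columns=["chrom", "start", "end", "effect"]),
                     target_ids=frozenset())
    hits = total = 0
    for s in range(20):
        layout = tm.generate_probes(spec, seed=s)
        track = tm.simulate_chip(layout, empty, seed=500 + s)
        scoredt = tm.score_track(track)
        hits += int((scoredt["score"] >= 3.5).sum())
        total += len(scoredt)
    assert hits / total < 0.002
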