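"""Peak cleaning: size window, signal/noise discrimination, duplicate
consensus, cross-sample binning."""

import numpy as np
import pytest

from trflptools.peaks import (
    PeakProfile,
    bin_across_samples,
    consensus_duplicates,
    denoise,
    export_window,
)


def profile(sizes, areas, sample="S", enzyme="MspI", dye="HEX", rep=0):
    return PeakProfile(sample, enzyme, dye, rep, np.array(sizes, float),
                       np.array(areas, float))


class TestExportWindow:
    def test_bounds_are_inclusive(self):
        p = profile([49.9, 50.0, 550.0, 550.1], [1, 1, 1, 1])
        out = export_window(p)
        assert out.sizes.tolist() == [50.0, 550.0]

    def test_empty_profile_passes_through(self):
        out = export_window(profile([], []))
        assert out.n_peaks == 0

    def test_interior_profile_is_identity(self):
        p = profile([100, 200, 300], [1, 2, 3])
        out = export_window(p)
        assert out.sizes.tolist() == p.sizes.tolist()
        assert out.areas.tolist() == p.areas.tolist()

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            export_window(profile([100], [1]), low=500, high=50)


class TestDenoise:
    def test_few_peaks_cannot_flag_so_all_are_retained(self):
        # hand execution of the iteration: relativized areas
        # (0.952, 5 x 0.0095), sigma about zero = 0.389, 3*sigma = 1.17
        # exceeds every peak, so nothing flags and the whole profile is
        # kept as all-signal
        p = profile([100, 110, 120, 130, 140, 150], [100, 1, 1, 1, 1, 1])
        out = denoise(p)
        assert out.sizes.tolist() == p.sizes.tolist()

    def test_dominant_peak_over_a_wide_noise_floor_is_isolated(self):
        # 1 peak of area 1000 over 10 unit peaks: first pass sigma =
        # 0.2985 (relativized, about zero), 3*sigma = 0.895 < 0.990 so
        # the big peak flags; the remainder never exceeds its own
        # 3*sigma, so the cascade stops with one signal peak
        sizes = [100.0] + [200 + i for i in range(10)]
        p = profile(sizes, [1000] + [1] * 10)
        out = denoise(p)
        assert out.sizes.tolist() == [100.0]
        assert out.areas.tolist() == [1000.0]

    def test_equal_areas_all_retained(self):
        p = profile([100, 110, 120, 130], [5, 5, 5, 5])
        out = denoise(p)
        assert out.n_peaks == 4

    def test_fewer_than_three_peaks_unchanged(self):
        p = profile([100, 200], [1000, 1])
        out = denoise(p)
        assert out.sizes.tolist() == [100, 200]

    def test_idempotent_on_synthetic_profiles(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n_true = rng.integers(2, 7)
            true_areas = rng.dirichlet([5] * n_true) * 1e4
            sizes = np.concatenate([
                rng.uniform(60, 540, n_true),
                rng.uniform(30, 600, 60),
            ])
            areas = np.concatenate([true_areas, rng.exponential(40, 60)])
            once = denoise(profile(sizes, areas))
            twice = denoise(once)
            assert twice.sizes.tolist() == once.sizes.tolist()
            assert twice.areas.tolist() == once.areas.tolist()


class TestConsensus:
    def test_stated_arithmetic_on_partially_shared_peaks(self):
        a = profile([100, 150], [5, 3])
        b = profile([100], [7], rep=1)
        out = consensus_duplicates(a, b, tol=0.5)
        # only the 100 bp peak is in both digests; after relativizing
        # (5/8 vs 7/7), averaging, and re-relativizing it carries area 1
        assert out.sizes.tolist() == [100.0]
        assert out.areas.tolist() == [1.0]

    def test_disjoint_replicates_give_empty_consensus(self):
        out = consensus_duplicates(profile([100], [1]), profile([200], [1], rep=1), 0.5)
        assert out.n_peaks == 0

    def test_commutative(self):
        rng = np.random.default_rng(5)
        a = profile(rng.uniform(50, 550, 8), rng.exponential(10, 8))
        b = profile(rng.uniform(50, 550, 8), rng.exponential(10, 8), rep=1)
        ab = consensus_duplicates(a, b, tol=5.0)
        ba = consensus_duplicates(b, a, tol=5.0)
        np.testing.assert_allclose(ab.sizes, ba.sizes)
        np.testing.assert_allclose(ab.areas, ba.areas)

    def test_identical_replicates_identity_up_to_relativization(self):
        a = profile([100, 200], [2, 6])
        out = consensus_duplicates(a, profile([100, 200], [2, 6], rep=1), 0.5)
        assert out.sizes.tolist() == [100, 200]
        np.testing.assert_allclose(out.areas, [0.25, 0.75])

    def test_mean_size_and_mean_relative_area(self):
        a = profile([100.0], [4])
        b = profile([100.4], [4], rep=1)
        out = consensus_duplicates(a, b, tol=0.5)
        np.testing.assert_allclose(out.sizes, [100.2])

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            consensus_duplicates(profile([100], [1]),
                                 profile([100], [1], enzyme="HhaI", rep=1), 0.5)


class TestBinning:
    def test_nearby_peaks_across_samples_share_a_bin(self):
        a = profile([100.1], [1.0], sample="A")
        b = profile([100.4], [1.0], sample="B")
        bt = bin_across_samples([a, b], gap=1.0)
        assert bt.centers.tolist() == [100.25]
        assert bt.table.loc[100.25, "A"] == 1.0

    def test_separated_peaks_get_distinct_bins(self):
        a = profile([100, 102], [0.5, 0.5], sample="A")
        bt = bin_across_samples([a], gap=1.0)
        assert bt.centers.tolist() == [100, 102]

    def test_single_linkage_chains_into_one_bin(self):
        a = profile([100.0], [1.0], sample="A")
        b = profile([100.8], [1.0], sample="B")
        c = profile([101.6], [1.0], sample="C")
        bt = bin_across_samples([a, b, c], gap=1.0)
        assert len(bt.centers) == 1
        np.testing.assert_allclose(bt.centers, [100.8])

    def test_per_sample_relative_areas_sum_to_one(self):
        rng = np.random.default_rng(23)
        profiles = []
        for sid in "ABCD":
            sizes = rng.uniform(50, 550, 6)
            areas = rng.dirichlet([1] * 6)
            profiles.append(profile(sizes, areas, sample=sid))
        bt = bin_across_samples(profiles, gap=1.0)
        np.testing.assert_allclose(bt.table.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_input_gives_empty_table(self):
        bt = bin_across_samples([], gap=1.0)
        assert len(bt.centers) == 0
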