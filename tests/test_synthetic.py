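"""Synthetic generators: signature planting, communities, profiles, Fe grid."""

import numpy as np
import pytest

from trflptools.digest import (
    DEFAULT_ENZYMES,
    FORWARD,
    NO_CUT,
    REVERSE,
    DigestSignature,
    signature,
)
from trflptools.synthetic import (
    EmptyCommunityError,
    FeGridSpec,
    GEOBACTER_SIGNATURE,
    InfeasibleSignatureError,
    NoiseSpec,
    ShapeSpec,
    default_fe_grid_spec,
    generate_community,
    generate_fe_grid,
    plant_signature,
    random_feasible_signature,
    synthesize_profiles,
)
from trflptools.thermo import select_reduced


class TestPlantSignature:
    def test_reference_clone_signature_round_trips(self):
        # the Geobacter-like clone's six published fragment lengths
        target = DigestSignature.from_row(GEOBACTER_SIGNATURE)
        rec = plant_signature(target, 1450, seed=5)
        assert signature(rec) == target
        assert len(rec.sequence) == 1450

    def test_all_no_cut_sequence_contains_no_recognition_site(self):
        rec = plant_signature({}, 500, seed=1)
        for site in ("CCGG", "GGCC", "GCGC"):
            assert site not in rec.sequence

    def test_one_sided_palindromic_cut_is_infeasible(self):
        with pytest.raises(InfeasibleSignatureError) as err:
            plant_signature({("MspI", FORWARD): 60}, 500, seed=0)
        assert ("MspI", FORWARD) in err.value.slots
        assert ("MspI", REVERSE) in err.value.slots

    def test_incompatibly_overlapping_sites_are_reported(self):
        # MspI site at 99 and HhaI site at 100 demand different bases
        target = {
            ("MspI", FORWARD): 100, ("MspI", REVERSE): 1450 - 99 - 4 + 1,
            ("HhaI", FORWARD): 103, ("HhaI", REVERSE) : 1450 - 100 - 4 + 3,
        }
        with pytest.raises(InfeasibleSignatureError):
            plant_signature(target, 1450, seed=0)

    def test_fragment_outside_amplicon_rejected(self):
        with pytest.raises(InfeasibleSignatureError):
            plant_signature(
                {("MspI", FORWARD): 2000, ("MspI", REVERSE): 100}, 1450, seed=0
            )

    def test_round_trip_over_random_feasible_targets(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            target = random_feasible_signature(rng, amplicon_length=900)
            rec = plant_signature(target, 900, seed=int(rng.integers(2**31)))
            assert signature(rec) == target

    def test_seed_determinism(self):
        target = DigestSignature.from_row(GEOBACTER_SIGNATURE)
        a = plant_signature(target, 1450, seed=9)
        b = plant_signature(target, 1450, seed=9)
        assert a.sequence == b.sequence


class TestGenerateCommunity:
    def test_single_taxon_gets_everything(self):
        comm = generate_community(1, seed=0)
        assert comm.abundances.tolist() == [1.0]

    def test_zero_taxa_rejected(self):
        with pytest.raises(EmptyCommunityError):
            generate_community(0)

    def test_seed_determinism(self):
        a = generate_community(5, seed=4)
        b = generate_community(5, seed=4)
        np.testing.assert_array_equal(a.abundances, b.abundances)

    def test_simplex_invariants(self):
        comm = generate_community(8, concentration=0.5, seed=2)
        assert abs(comm.abundances.sum() - 1) < 1e-9
        assert (comm.abundances >= 0).all()

    def test_symmetric_dirichlet_mean_matches_moment_oracle(self):
        # E[x_i] = 1/4 for symmetric Dirichlet(1) on 4 taxa; component sd
        # is sqrt(3/(16*5)), so 3 standard errors of the grand mean bound
        n, draws = 4, 10_000
        rng = np.random.default_rng(12)
        means = np.vstack([
            generate_community(n, 1.0, seed=int(rng.integers(2**31))).abundances
            for _ in range(draws)
        ]).mean(axis=0)
        se = np.sqrt(3 / (16 * 5)) / np.sqrt(draws)
        assert np.all(np.abs(means - 0.25) < 3 * se)


@pytest.fixture(scope="module")
def members():
    rng = np.random.default_rng(21)
    recs = []
    for i in range(3):
        target = random_feasible_signature(rng, amplicon_length=900, p_nocut=0.0)
        recs.append(
            plant_signature(target, 900, seed=int(rng.integers(2**31)),
                            record_id=f"m{i}", taxon=f"m{i}")
        )
    return recs


class TestSynthesizeProfiles:

    def test_noiseless_profiles_sit_exactly_on_planted_fragments(self, members):
        comm = generate_community(members=members, seed=3)
        profiles = synthesize_profiles(
            comm, DEFAULT_ENZYMES[0], FORWARD, NoiseSpec.none(),
            n_replicates=1, seed=0,
        )
        (profile,) = profiles
        expected = sorted(
            float(signature(m)[("MspI", FORWARD)]) for m in members
        )
        assert profile.sizes.tolist() == expected
        order = np.argsort([signature(m)[("MspI", FORWARD)] for m in members])
        np.testing.assert_allclose(
            profile.relative_areas(), comm.abundances[order], atol=1e-12
        )

    def test_full_dropout_leaves_only_noise_peaks(self, members):
        comm = generate_community(members=members, seed=3)
        noise = NoiseSpec(n_noise_peaks=10, noise_area_scale=5.0,
                          size_jitter_sd=0.1, dropout_prob=1.0)
        (profile,) = synthesize_profiles(
            comm, DEFAULT_ENZYMES[0], FORWARD, noise, n_replicates=1, seed=0
        )
        assert profile.n_peaks == 10
        # true peaks carry areas of order abundance * 1e4; exponential
        # noise areas (scale 5) are orders of magnitude smaller
        assert profile.areas.max() < 100

    def test_replicates_jitter_independently_but_deterministically(self, members):
        comm = generate_community(members=members, seed=3)
        run1 = synthesize_profiles(comm, DEFAULT_ENZYMES[0], FORWARD,
                                   NoiseSpec(), 2, seed=8)
        run2 = synthesize_profiles(comm, DEFAULT_ENZYMES[0], FORWARD,
                                   NoiseSpec(), 2, seed=8)
        for a, b in zip(run1, run2):
            np.testing.assert_array_equal(a.sizes, b.sizes)
        assert not np.array_equal(run1[0].sizes, run1[1].sizes)


class TestFeGrid:
    def test_shape_tags_are_respected_without_noise(self):
        spec = default_fe_grid_spec(noise_sd=0.0)
        records = generate_fe_grid(spec, seed=6)
        by_series = {}
        for r in records:
            key = (r.mineral, r.carbon, r.sample_id[-1])
            by_series.setdefault(key, []).append((r.dilution_exponent, r.percent_reduced))
        for (mineral, carbon, _), series in by_series.items():
            values = [v for _, v in sorted(series)]
            tag = spec.shapes[(mineral, carbon)].tag
            if tag == "decreasing":
                assert all(a >= b for a, b in zip(values, values[1:]))
            elif tag == "unimodal_at_third":
                assert np.argmax(values) == 2

    def test_default_grid_matches_reported_reduction_pattern(self):
        records = generate_fe_grid(seed=6)
        goe_acetate = [r for r in records
                       if r.mineral == "goethite" and r.carbon == "acetate"]
        assert goe_acetate and all(r.percent_reduced <= 10 for r in goe_acetate)
        fer_acetate_d1 = [r for r in records
                         if r.mineral == "ferrihydrite" and r.carbon == "acetate"
                         and r.dilution_exponent == 1]
        spec = default_fe_grid_spec()
        for r in fer_acetate_d1:
            assert 84 <= r.target_percent <= 88
            assert abs(r.percent_reduced - r.target_percent) <= 3 * spec.noise_sd
        assert all(r.fetot_mM == 25.0 for r in records)
        assert len(records) == 120

    def test_zero_amplitude_grid_selects_nothing(self):
        shapes = {
            (m, c): ShapeSpec("flat_low", (0, 0))
            for m in ("ferrihydrite", "goethite", "hematite")
            for c in ("acetate", "lactate", "glucose", "mixed")
        }
        records = generate_fe_grid(FeGridSpec(shapes=shapes, noise_sd=0.0), seed=0)
        assert all(r.percent_reduced == 0 for r in records)
        selected, _ = select_reduced(records)
        assert selected == []

    def test_missing_combination_is_named(self):
        spec = default_fe_grid_spec()
        del spec.shapes[("hematite", "mixed")]
        with pytest.raises(ValueError, match="hematite"):
            generate_fe_grid(spec, seed=0)

    def test_seed_determinism(self):
        a = generate_fe_grid(seed=13)
        b = generate_fe_grid(seed=13)
        assert [(r.sample_id, r.fe2_mM) for r in a] == [
            (r.sample_id, r.fe2_mM) for r in b
        ]
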