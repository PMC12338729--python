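"""Synthetic cohort generator: determinism, geometry, and ground-truth structure."""

import logging

import numpy as np
import pytest

from cofluct import (
    GainProfile,
    SyntheticCohortSpec,
    compute_amplitudes,
    gain_profile,
    generate_cohort,
    generate_parcel_geometry,
    generate_scan,
)


class TestGainProfiles:
    @pytest.mark.parametrize("cls", ["S", "A", "L"])
    def test_default_profiles_satisfy_invariants(self, cls):
        gain_profile(cls).validate()

    def test_sharpening_preserves_invariants_and_contrast(self):
        a = np.linspace(0, 1, 101)
        for cls in "SAL":
            g1 = gain_profile(cls, gamma=1.0).gain_function(a)
            g2 = gain_profile(cls, gamma=2.0).gain_function(a)
            gain_profile(cls, gamma=2.0).validate()
            assert (g2 <= g1 + 1e-12).all()          # interior drops, extremes fixed
            assert g2.max() == pytest.approx(g1.max())

    def test_violating_profile_rejected(self):
        bad = GainProfile("S", lambda a: 1.0 - a, baseline=0.1)
        with pytest.raises(ValueError):
            bad.validate()


class TestGeometry:
    def test_seeded_determinism(self):
        g1 = generate_parcel_geometry(60, seed=7)
        g2 = generate_parcel_geometry(60, seed=7)
        assert g1.equals(g2)

    def test_sa_rank_is_permutation(self):
        g = generate_parcel_geometry(60, seed=7)
        assert sorted(g["sa_rank"]) == list(range(1, 61))

    def test_hemisphere_split_and_unit_centroids(self):
        g = generate_parcel_geometry(200, seed=1)
        assert (g["hemisphere"] == "L").sum() == 100
        assert (g["hemisphere"] == "R").sum() == 100
        norms = np.linalg.norm(g[["x", "y", "z"]].to_numpy(), axis=1)
        assert np.abs(norms - 1).max() < 1e-9

    def test_odd_region_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_parcel_geometry(61, seed=0)

    def test_classes_are_rank_tertiles(self):
        g = generate_parcel_geometry(60, seed=3)
        by_rank = g.sort_values("sa_rank")["region_class"].tolist()
        assert by_rank == ["S"] * 20 + ["A"] * 20 + ["L"] * 20


@pytest.fixture(scope="module")
def spec():
    return SyntheticCohortSpec(
        n_subjects=2, n_regions_per_class=(4, 4, 4), n_frames=500, seed=17)


@pytest.fixture(scope="module")
def geometry(spec):
    return generate_parcel_geometry(spec.n_regions, spec.seed)


class TestGenerateScan:

    def test_seeded_determinism(self, spec, geometry):
        sub = {"age": 30.0, "mean_fd": 0.1, "condition": "rest", "subject_id": "s"}
        s1 = generate_scan(spec, geometry, sub, seed=5)
        s2 = generate_scan(spec, geometry, sub, seed=5)
        assert np.array_equal(s1.values, s2.values, equal_nan=True)

    def test_noiseless_same_class_regions_identical(self, geometry):
        spec = SyntheticCohortSpec(
            n_subjects=1, n_regions_per_class=(4, 4, 4), n_frames=300,
            noise_sd=0.0, seed=17)
        sub = {"age": 30.0, "mean_fd": 0.1, "condition": "rest", "subject_id": "s"}
        scan = generate_scan(spec, geometry, sub, seed=2)
        same_class = np.flatnonzero(geometry["region_class"].to_numpy() == "S")[:2]
        z = scan.z
        r = np.corrcoef(z[:, same_class[0]], z[:, same_class[1]])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_columns_standardized_over_retained_frames(self, spec, geometry):
        sub = {"age": 30.0, "mean_fd": 0.12, "condition": "rest", "subject_id": "s"}
        scan = generate_scan(spec, geometry, sub, seed=9)
        scan.validate(mean_tol=1e-8, var_tol=1e-8)

    def test_high_amplitude_frames_are_s_class_driven(self):
        """Top realized-amplitude decile carries a larger S-class share of
        regional co-fluctuation than the bottom decile (generative oracle)."""
        spec = SyntheticCohortSpec(
            n_subjects=1, n_regions_per_class=(10, 10, 10), n_frames=4000, seed=23)
        geometry = generate_parcel_geometry(spec.n_regions, spec.seed)
        sub = {"age": 30.0, "mean_fd": 0.05, "condition": "rest", "subject_id": "s"}
        scan = generate_scan(spec, geometry, sub, seed=4)
        amp = compute_amplitudes(scan)
        s_mask = (geometry["region_class"] == "S").to_numpy()
        share = (amp.rss_region[:, s_mask] ** 2).sum(1) / (amp.rss_region ** 2).sum(1)
        order = np.argsort(amp.rss_global)
        dec = len(order) // 10
        assert share[order[-dec:]].mean() > share[order[:dec]].mean()

    def test_thin_bin_warning(self, geometry, caplog):
        spec = SyntheticCohortSpec(
            n_subjects=1, n_regions_per_class=(4, 4, 4), n_frames=150, seed=17)
        sub = {"age": 30.0, "mean_fd": 0.1, "condition": "rest", "subject_id": "s"}
        with caplog.at_level(logging.WARNING, logger="cofluct.synthetic"):
            generate_scan(spec, geometry, sub, seed=1)
        assert any("thin" in rec.message for rec in caplog.records)


class TestGenerateCohort:
    def test_single_subject_composition(self):
        spec = SyntheticCohortSpec(
            n_subjects=1, n_regions_per_class=(4, 4, 4), n_frames=300, seed=29)
        cohort = generate_cohort(spec)
        assert len(cohort.scans) == 1
        geometry = generate_parcel_geometry(spec.n_regions, spec.seed)
        direct = generate_scan(spec, geometry, cohort.covariates.iloc[0],
                               spec.scan_seed(0, "rest"))
        assert np.array_equal(cohort.scans[0].values, direct.values, equal_nan=True)

    def test_covariates_reproducible(self):
        spec = SyntheticCohortSpec(
            n_subjects=20, n_regions_per_class=(2, 2, 2), n_frames=100, seed=41)
        ages1 = generate_cohort(spec).covariates["age"]
        ages2 = generate_cohort(spec).covariates["age"]
        assert np.array_equal(ages1, ages2)
        lo, hi = spec.age_range
        assert ages1.between(lo, hi).all()

    def test_dev_sharpening_off_means_age_independent_gains(self):
        spec = SyntheticCohortSpec(dev_sharpening=0.0)
        a = np.linspace(0, 1, 50)
        for cls in "SAL":
            g_young = gain_profile(cls, gamma=1.0 + spec.dev_sharpening * (6 - 6))
            g_old = gain_profile(cls, gamma=1.0 + spec.dev_sharpening * (80 - 6))
            assert np.allclose(g_young.gain_function(a), g_old.gain_function(a))

    def test_rest_and_movie_share_subjects(self):
        spec = SyntheticCohortSpec(
            n_subjects=3, n_regions_per_class=(4, 4, 4), n_frames=200, seed=2)
        rest = generate_cohort(spec, "rest")
        movie = generate_cohort(spec, "movie")
        assert np.array_equal(rest.covariates["age"], movie.covariates["age"])
        assert not np.array_equal(rest.scans[0].values, movie.scans[0].values,
                                  equal_nan=True)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n_subjects=0)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(noise_sd=-0.1)
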