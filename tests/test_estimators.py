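"""Shape-factor and truncated-cone estimators and their sklearn-style API."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from musclevol import (
    AcsaProfile,
    PhantomSpec,
    ShapeFactorVolume,
    TruncatedConeVolume,
    analytic_acsa,
    analytic_volume,
    estimate_shape_factor,
    estimate_truncated_cone,
    find_acsa_max,
    fit_shape_factor_model,
    profile_from_volume,
    reference_volume,
    shape_factor,
    truncated_cone_positions,
    voxelize,
)


def _flat_profile(area=100.0, length=100.0):
    return AcsaProfile(np.full(101, area), length)


class TestShapeFactor:
    def test_direct_arithmetic_vl_magnitude(self):
        # a vastus-lateralis-sized muscle: ~1 L volume, 40 cm length
        assert shape_factor(992_000.0, 400.0, 4000.0) == pytest.approx(0.62)

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            shape_factor(*args)

    def test_cylinder_phantom_shape_factor_is_one(self, cylinder_phantom, cylinder_profile):
        _, vol = cylinder_phantom
        p = shape_factor(
            reference_volume(vol), cylinder_profile.length_mm,
            cylinder_profile.acsa_max_mm2,
        )
        assert p == pytest.approx(1.0, abs=0.02)

    def test_cone_phantom_shape_factor_is_one_third(self, cone_phantom, cone_profile):
        _, vol = cone_phantom
        p = shape_factor(
            reference_volume(vol), cone_profile.length_mm, cone_profile.acsa_max_mm2
        )
        assert p == pytest.approx(1.0 / 3.0, abs=0.02)

    @given(scale_area=st.floats(0.1, 50), scale_len=st.floats(0.1, 50))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, scale_area, scale_len):
        """p is invariant to uniform scaling of all areas and of the length."""
        base = shape_factor(40_000.0, 100.0, 900.0)
        scaled = shape_factor(
            40_000.0 * scale_area * scale_len, 100.0 * scale_len, 900.0 * scale_area
        )
        assert scaled == pytest.approx(base, rel=1e-9)


class TestTruncatedConePositions:
    @pytest.mark.parametrize(
        "loc, expected",
        [
            (0.50, (1.00, 0.75, 0.50, 0.255, 0.01)),
            (0.61, (1.00, 0.805, 0.61, 0.31, 0.01)),
        ],
    )
    def test_halfway_placement(self, loc, expected):
        sampling = truncated_cone_positions(loc)
        assert sampling.positions == pytest.approx(expected)

    def test_distances_cover_99_percent_of_length(self):
        sampling = truncated_cone_positions(0.61)
        d = sampling.distances_mm(400.0)
        assert np.all(d > 0)
        assert d.sum() == pytest.approx(0.99 * 400.0)

    @pytest.mark.parametrize("loc", [0.01, 1.0, 0.0, 1.5])
    def test_degenerate_location_rejected(self, loc):
        with pytest.raises(ValueError):
            truncated_cone_positions(loc)


class TestEstimateTruncatedCone:
    def test_flat_profile_closed_form(self):
        """All five areas equal -> volume is 0.99 * L * A exactly."""
        prof = _flat_profile(100.0, 100.0)
        est = estimate_truncated_cone(prof, truncated_cone_positions(0.5))
        assert est == pytest.approx(9900.0, rel=1e-12)

    def test_voxelized_cylinder_misses_only_the_distal_slab(self, cylinder_profile):
        est = estimate_truncated_cone(cylinder_profile, truncated_cone_positions(0.5))
        target = 0.99 * cylinder_profile.length_mm * cylinder_profile.acsa_max_mm2
        assert est == pytest.approx(target, rel=0.005)

    def test_cone_frustum_quadrature_is_exact(self, cone_phantom, cone_profile):
        """Linear-radius shapes are integrated exactly by the frustum formula."""
        spec, _ = cone_phantom
        est = estimate_truncated_cone(cone_profile, truncated_cone_positions(0.5))
        analytic_1_100 = analytic_volume(spec) * (1 - 0.01**3)
        assert est == pytest.approx(analytic_1_100, rel=0.005)

    def test_frustum_phantom_exactness(self):
        spec = PhantomSpec.frustum(300.0, (10.0, 25.0))
        prof = profile_from_volume(voxelize(spec, (0.65, 0.65, 2.0)))
        truth = integrate.quad(lambda x: analytic_acsa(spec, x), 0.01, 1.0)[0] * 300.0
        est = estimate_truncated_cone(prof, truncated_cone_positions(0.5))
        assert est == pytest.approx(truth, rel=0.005)

    def test_never_exceeds_99pct_of_bounding_cylinder(self, spindle_profile):
        for loc in (0.2, 0.5, 0.8):
            est = estimate_truncated_cone(spindle_profile, truncated_cone_positions(loc))
            bound = 0.99 * spindle_profile.length_mm * spindle_profile.acsa_max_mm2
            assert est <= bound


@pytest.fixture(scope="module")
def small_cohort():
    """Five voxelized spindles with varying length/area/peak location."""
    profiles, refs = [], []
    for L, A, xm in [(240, 1500, 0.45), (260, 1800, 0.55), (300, 2000, 0.6),
                     (280, 1700, 0.65), (250, 1600, 0.5)]:
        vol = voxelize(PhantomSpec.beta_spindle(L, A, xm), (1.0, 1.0, 2.0))
        profiles.append(profile_from_volume(vol))
        refs.append(reference_volume(vol))
    return profiles, np.asarray(refs)


class TestShapeFactorVolume:
    def test_fitted_attributes(self, small_cohort):
        profiles, refs = small_cohort
        model = ShapeFactorVolume().fit(profiles, refs)
        assert model.p_.shape == (5,)
        assert model.p_avg_ == pytest.approx(model.p_.mean())
        assert model.p_sd_ == pytest.approx(model.p_.std(ddof=1))
        assert 0 < model.p_avg_ <= 1
        assert 0 < model.acsa_max_location_ < 1

    def test_identical_subjects_have_zero_p_sd(self, spindle_profile, spindle_phantom):
        _, vol = spindle_phantom
        mv = reference_volume(vol)
        model = ShapeFactorVolume().fit([spindle_profile] * 3, [mv] * 3)
        assert model.p_sd_ == 0.0

    def test_cone_cohort_p_avg_is_one_third(self):
        profiles, refs = [], []
        for L, A in [(250, 1500), (300, 2000), (280, 1800)]:
            vol = voxelize(PhantomSpec.cone(L, A), (0.65, 0.65, 2.0))
            profiles.append(profile_from_volume(vol))
            refs.append(reference_volume(vol))
        model = ShapeFactorVolume().fit(profiles, refs)
        assert model.p_avg_ == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_cylinder_cohort_practice_estimates_match_reference(self):
        """A constant profile makes the sampling location irrelevant."""
        profiles, refs = [], []
        for L, A in [(200, 1000), (260, 1500), (240, 1300)]:
            vol = voxelize(PhantomSpec.cylinder(L, A), (0.65, 0.65, 2.0))
            profiles.append(profile_from_volume(vol))
            refs.append(reference_volume(vol))
        est = ShapeFactorVolume().fit_predict(profiles, refs)
        assert np.allclose(est, refs, rtol=0.02)

    def test_leave_one_out_with_two_subjects_swaps_shape_factors(self, small_cohort):
        profiles, refs = small_cohort
        two_p, two_r = profiles[:2], refs[:2]
        model = ShapeFactorVolume(ideal=True, leave_one_out=True)
        est = model.fit_predict(two_p, two_r)
        # each subject's estimate uses the *other* subject's p with its own ACSA_max
        for i, j in ((0, 1), (1, 0)):
            amax, _ = find_acsa_max(two_p[i])
            expected = model.p_[j] * two_p[i].length_mm * amax
            assert est[i] == pytest.approx(expected, rel=1e-12)

    def test_ideal_identity_with_subject_own_p(self, small_cohort):
        """Own p and own ACSA_max invert the shape-factor definition exactly."""
        profiles, refs = small_cohort
        model = fit_shape_factor_model(profiles, refs)
        for prof, mv, p in zip(profiles, refs, model.p_):
            est = estimate_shape_factor(model, prof, ideal=True, p=p)
            assert est == pytest.approx(mv, rel=1e-12)

    def test_predict_before_fit_raises(self, spindle_profile):
        with pytest.raises(NotFittedError):
            ShapeFactorVolume().predict([spindle_profile])

    def test_requires_at_least_two_subjects(self, spindle_profile):
        with pytest.raises(ValueError):
            ShapeFactorVolume().fit([spindle_profile], [1000.0])

    def test_sklearn_params_round_trip(self):
        model = ShapeFactorVolume(ideal=True, leave_one_out=True)
        assert clone(model).get_params() == {"ideal": True, "leave_one_out": True}


class TestTruncatedConeVolume:
    def test_learned_location_is_cohort_mean(self, small_cohort):
        profiles, _ = small_cohort
        model = TruncatedConeVolume().fit(profiles)
        locs = [find_acsa_max(p)[1] for p in profiles]
        assert model.acsa_max_location_ == pytest.approx(np.mean(locs))

    def test_fixed_location_needs_no_fit(self, cylinder_profile):
        est = TruncatedConeVolume(location=0.5).predict([cylinder_profile])
        target = 0.99 * cylinder_profile.length_mm * cylinder_profile.acsa_max_mm2
        assert est[0] == pytest.approx(target, rel=0.005)

    def test_unfitted_without_location_raises(self, cylinder_profile):
        with pytest.raises(NotFittedError):
            TruncatedConeVolume().predict([cylinder_profile])

    def test_systematic_underestimation_on_spindles(self, small_cohort):
        """Fusiform profiles are concave between samples -> underestimation."""
        profiles, refs = small_cohort
        est = TruncatedConeVolume().fit_predict(profiles)
        assert np.all(est < refs)
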