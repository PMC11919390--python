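"""Young-Laplace profile fitting."""

import math

import numpy as np
import pytest

from condrop import adsa_fit, shapes
from condrop.adsa_fit import (
    FitConfig,
    FitResult,
    estimate_smax,
    fit_profile,
    objective,
    quality_filter,
    rescale_profile,
)
from condrop.shapes import Profile, YLParams


class TestRescale:
    def test_undoes_factor_1p2(self):
        prof = Profile(np.array([[2.0, 0.0], [1.0, 1.2], [0.0, 2.4]]))
        out = rescale_profile(prof)  # default 1/1.2
        np.testing.assert_allclose(out.z, [0.0, 1.0, 2.0])

    def test_identity_and_r_untouched(self, yl_profile_120):
        prof, _ = yl_profile_120
        out = rescale_profile(prof, 1.0)
        np.testing.assert_array_equal(out.points, prof.points)
        out2 = rescale_profile(prof, 0.7)
        np.testing.assert_array_equal(out2.r, prof.r)


class TestEstimateSmax:
    def test_hand_evaluated_collinear_points(self):
        # 20 points, constant radius, z spacing 1 um: smoothed radii are
        # constant so each of the 16 segments (i = 4..19, 1-based) has
        # length 1; estimate = 1.2 * 16.
        pts = np.column_stack([np.full(20, 5.0), np.arange(20.0)])
        prof = Profile(pts)
        assert estimate_smax(prof) == pytest.approx(19.2)

    def test_homogeneous_in_scale(self, yl_profile_120):
        prof, _ = yl_profile_120
        doubled = Profile(prof.points * 2.0)
        assert estimate_smax(doubled) == pytest.approx(2 * estimate_smax(prof), rel=1e-12)

    def test_too_few_points(self):
        prof = Profile(np.column_stack([np.full(7, 1.0), np.arange(7.0)]))
        with pytest.raises(ValueError):
            estimate_smax(prof)


class TestObjective:
    def test_self_consistency(self, yl_profile_120):
        # a profile of 1000 points sampled from the same parameters at the
        # same even arc spacing as the trial points scores ~0
        _, params = yl_profile_120
        prof1000, _ = shapes.integrate_profile(params, n_points=1000)
        lam = objective(params, prof1000)
        assert lam <= 1e-6

    def test_single_displaced_point(self):
        # one point pushed distance d off a dense arc adds d^2/N
        prof, params = shapes.profile_for_contact(90.0, 10.0, 1e5, n_points=150)
        prof1000, _ = shapes.integrate_profile(params, n_points=1000)
        pts = prof1000.points.copy()
        k = 500
        # normal direction of a circle centred near the apex axis
        center = np.array([0.0, prof1000.z_max - 10.0])
        normal = (pts[k] - center) / np.linalg.norm(pts[k] - center)
        d = 0.2
        pts[k] += d * normal
        lam = objective(params, Profile(pts))
        assert lam == pytest.approx(d**2 / len(pts), rel=0.05)

    def test_nearest_point_matches_exhaustive_search(self, rng):
        """The k-d tree assignment equals brute-force pairwise search."""
        from scipy.spatial import cKDTree

        for _ in range(50):
            n = rng.integers(10, 40)
            pts = rng.uniform(0, 30, size=(n, 2))
            trial = rng.uniform(0, 30, size=(200, 2))
            d_tree, _ = cKDTree(trial).query(pts, k=1)
            d_brute = np.min(
                np.linalg.norm(pts[:, None, :] - trial[None, :, :], axis=2), axis=1
            )
            np.testing.assert_allclose(d_tree, d_brute, rtol=1e-12)


class TestFitProfile:
    def test_hemisphere(self):
        prof, _ = shapes.profile_for_contact(90.0, 15.0, 1e5, n_points=150)
        res = fit_profile(prof)
        assert res.theta_deg == pytest.approx(90.0, abs=0.5)
        assert res.accepted

    def test_recovery_theta120(self, yl_profile_120):
        prof, params = yl_profile_120
        res = fit_profile(prof)
        assert res.theta_deg == pytest.approx(120.0, abs=0.5)
        assert res.params.lc == pytest.approx(500.0, rel=0.2)
        assert res.contact_radius_um == pytest.approx(15.0, abs=0.2)

    def test_optimum_not_beaten_by_truth(self, yl_profile_120):
        # compare at the same (optimization-time) smax and trial density
        _, params = yl_profile_120
        prof = shapes.integrate_profile(params, n_points=1000)[0]
        res = fit_profile(prof)
        smax = estimate_smax(prof)
        lam_opt = objective(
            YLParams(res.params.R0, res.params.lc, res.params.z0, smax), prof
        )
        lam_true = objective(YLParams(params.R0, params.lc, 0.0, smax), prof)
        assert lam_opt <= lam_true + 1e-8

    def test_corrupted_profile_discarded(self, yl_profile_120, rng):
        prof, _ = yl_profile_120
        pts = prof.points.copy()
        third = len(pts) // 3
        idx = rng.choice(len(pts) - 1, size=third, replace=False)
        pts[idx, 0] += 1.0  # 1 um corruption on a third of the points
        res = fit_profile(Profile(np.array(sorted(pts.tolist(), key=lambda p: p[1]))))
        assert res.quality_um > 0.5
        assert not res.accepted

    def test_aberrated_profile_needs_rescale(self):
        """A cap stretched axially by 1.2 fits badly raw but well after
        the 1/1.2 correction."""
        cap = shapes.SphericalCap(theta_deg=120.0, r_contact=15.0)
        prof = shapes.cap_profile(cap, 150)
        stretched = prof.with_z_scaled(1.2)
        raw = fit_profile(stretched)
        corrected = fit_profile(rescale_profile(stretched))
        assert abs(corrected.theta_deg - 120.0) <= 2.0
        assert abs(raw.theta_deg - 120.0) > 2.0


class TestParameterRecoverySweep:
    @pytest.mark.parametrize("lc", [200.0, 1000.0])
    @pytest.mark.parametrize("r_c", [12.0, 20.0, 35.0])
    @pytest.mark.parametrize("theta", [70.0, 90.0, 110.0, 130.0])
    def test_noiseless_recovery(self, theta, r_c, lc):
        prof, _ = shapes.profile_for_contact(theta, r_c, lc, n_points=120)
        res = fit_profile(prof)
        assert res.theta_deg == pytest.approx(theta, abs=0.5)

    @pytest.mark.parametrize("theta", [70.0, 110.0])
    def test_noisy_recovery(self, theta, rng):
        prof, _ = shapes.profile_for_contact(theta, 20.0, 500.0, n_points=120)
        pts = prof.points.copy()
        pts[:-1, 0] += rng.normal(0, 0.25, len(pts) - 1)
        pts[:, 0] = np.clip(pts[:, 0], 0, None)
        pts[-1, 0] = 0.0
        res = fit_profile(Profile(pts))
        assert res.theta_deg == pytest.approx(theta, abs=2.0)


class TestQualityFilter:
    def _mk(self, quality, r_c):
        return FitResult(theta_deg=100.0, params=None, lambda_um2=0.0,
                         contact_radius_um=r_c, quality_um=quality,
                         accepted=True, n_points=50)

    def test_partition_rules(self):
        poor = self._mk(0.6, 20.0)
        small = self._mk(0.1, 8.0)
        good = self._mk(0.4, 12.0)
        kept, discarded = quality_filter([poor, small, good])
        assert kept == [good]
        assert set(id(r) for r in discarded) == {id(poor), id(small)}
        assert "quality" in poor.reason
        assert "contact_radius" in small.reason
        assert good.accepted and not poor.accepted
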