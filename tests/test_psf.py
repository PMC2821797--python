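"""PSF maps, RMS superposition, smoothing, Gaussian profile fits, FWHM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from headpsf.leadfield import Leadfield, rereference_average
from headpsf.psf import (
    PSFMap,
    fit_psf_profile,
    fwhm_sigma_factor,
    psf_map,
    psf_stats,
    rms_superposition,
    smooth_on_mesh,
)


def brute_force_pearson(u, v):
    """Textbook correlation formula, written independently of numpy.corrcoef."""
    n = len(u)
    mu, mv = sum(u) / n, sum(v) / n
    num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    du = sum((a - mu) ** 2 for a in u) ** 0.5
    dv = sum((b - mv) ** 2 for b in v) ** 0.5
    return num / (du * dv)


def make_lf(matrix, orientation="x"):
    return Leadfield(np.asarray(matrix, dtype=float), "SPH", orientation)


class TestPsfMap:
    def test_self_correlation_is_exactly_one(self, rng):
        lf = make_lf(rng.standard_normal((8, 12)))
        pm = psf_map(lf, 5)
        assert pm.values[5] == 1.0

    def test_negated_column_gives_minus_one(self, rng):
        m = rng.standard_normal((6, 4))
        m[:, 2] = -m[:, 0]
        pm = psf_map(make_lf(m), 0)
        assert pm.values[2] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle_on_hand_matrix(self):
        m = np.array(
            [
                [0.2, -1.0, 0.5, 3.0],
                [1.1, 0.4, -0.2, -1.0],
                [-0.3, 0.9, 0.8, 0.1],
                [2.0, -0.5, 0.0, 0.7],
                [0.6, 1.5, -1.2, 0.2],
            ]
        )
        pm = psf_map(make_lf(m), 1)
        for j in range(4):
            assert pm.values[j] == pytest.approx(
                brute_force_pearson(m[:, 1], m[:, j]), abs=1e-12
            )

    def test_zero_variance_column_reported_missing(self, rng):
        m = rng.standard_normal((6, 5))
        m[:, 3] = 2.5  # constant
        pm = psf_map(make_lf(m), 0)
        assert np.isnan(pm.values[3])
        assert pm.n_missing == 1

    def test_constant_seed_rejected(self, rng):
        m = rng.standard_normal((6, 5))
        m[:, 0] = 1.0
        with pytest.raises(ValueError):
            psf_map(make_lf(m), 0)

    @settings(deadline=None, max_examples=25)
    @given(
        m=arrays(np.float64, (7, 9), elements=st.floats(-5, 5)),
        scale=st.floats(0.1, 10),
        offset=st.floats(-3, 3),
    )
    def test_invariances(self, m, scale, offset):
        """PSF unchanged by positive column scaling, constant sensor offsets
        and average re-referencing (Pearson centering)."""
        m = m + np.arange(9) * 1.7 + np.linspace(0.5, 3.5, 7)[:, None]  # variance
        lf = make_lf(m)
        base = psf_map(lf, 0).values
        scaled = m.copy()
        scaled[:, 0] *= scale
        np.testing.assert_allclose(psf_map(make_lf(scaled), 0).values, base, atol=1e-9)
        np.testing.assert_allclose(
            psf_map(make_lf(m + offset), 0).values, base, atol=1e-9
        )
        np.testing.assert_allclose(
            psf_map(rereference_average(lf), 0).values, base, atol=1e-9
        )
        assert np.all(np.abs(base) <= 1.0)


class TestRmsSuperposition:
    def test_identical_maps_give_absolute_value(self):
        v = np.array([0.5, -0.3, 1.0, -1.0])
        maps = [PSFMap(0, v, o) for o in ("x", "y", "z")]
        out = rms_superposition(maps)
        np.testing.assert_allclose(out.values, np.abs(v), atol=1e-15)
        assert out.orientation == "RMS"

    def test_formula_spot_check(self):
        """sqrt((0.4^2 + 0.38^2 + 0.16^2)/3) = sqrt(0.11) = 0.3317,
        consistent (to the rounding of the inputs) with the published RMS
        0.34 for source 1."""
        maps = [
            PSFMap(0, np.array([v]), o)
            for v, o in zip((0.4, 0.38, -0.16), ("x", "y", "z"))
        ]
        out = rms_superposition(maps)
        assert out.values[0] == pytest.approx(np.sqrt(0.11), abs=1e-12)
        assert abs(out.values[0] - 0.34) < 0.01

    def test_zero_maps_stay_zero(self):
        maps = [PSFMap(0, np.zeros(5), o) for o in ("x", "y", "z")]
        assert np.all(rms_superposition(maps).values == 0)

    def test_mismatched_seeds_rejected(self):
        maps = [PSFMap(s, np.zeros(5), o) for s, o in zip((0, 0, 1), "xyz")]
        with pytest.raises(ValueError, match="seed"):
            rms_superposition(maps)

    @settings(deadline=None, max_examples=25)
    @given(arrays(np.float64, (3, 11), elements=st.floats(-1, 1)))
    def test_bounds_for_correlation_inputs(self, stack):
        maps = [PSFMap(0, stack[i], o) for i, o in enumerate("xyz")]
        out = rms_superposition(maps).values
        assert np.all(out >= 0) and np.all(out <= 1 + 1e-12)


class TestStats:
    def test_all_ones_map(self):
        assert psf_stats(PSFMap(0, np.ones(10), "x")) == (1.0, 1.0)

    def test_hand_built_map(self):
        v = np.array([1.0, 0.8, -0.2, 0.5, 0.0, 0.3, -0.6, 0.9, 0.2, 0.1])
        mean, mn = psf_stats(PSFMap(0, v, "x"))
        assert mean == pytest.approx(v.mean())
        assert mn == pytest.approx(-0.6)

    def test_missing_excluded(self):
        v = np.array([1.0, np.nan, 0.5, np.nan])
        mean, mn = psf_stats(PSFMap(0, v, "x"))
        assert mean == pytest.approx(0.75) and mn == pytest.approx(0.5)


class TestSmoothing:
    def test_zero_kernel_is_identity(self, rng):
        pm = PSFMap(0, rng.standard_normal(30), "x")
        out = smooth_on_mesh(pm, rng.standard_normal((30, 3)), kernel_fwhm=0)
        np.testing.assert_array_equal(out.values, pm.values)

    def test_constant_map_unchanged(self, rng):
        pos = rng.standard_normal((40, 3)) * 20
        pm = PSFMap(0, np.full(40, 0.7), "x")
        out = smooth_on_mesh(pm, pos, kernel_fwhm=15.0)
        np.testing.assert_allclose(out.values, 0.7, atol=1e-12)

    def test_reduces_variance_of_random_map(self, rng):
        pos = rng.standard_normal((200, 3)) * 30
        pm = PSFMap(0, rng.standard_normal(200), "x")
        out = smooth_on_mesh(pm, pos, kernel_fwhm=20.0)
        assert out.values.var() < pm.values.var()

    def test_missing_values_stay_missing(self, rng):
        pos = rng.standard_normal((50, 3)) * 10
        v = rng.standard_normal(50)
        v[7] = np.nan
        out = smooth_on_mesh(PSFMap(0, v, "x"), pos, kernel_fwhm=10.0)
        assert np.isnan(out.values[7])
        assert np.isfinite(np.delete(out.values, 7)).all()


class TestProfileFit:
    def test_single_gaussian_fwhm(self, rng):
        """sigma = 30 mm profile: FWHM = 2.35482 * 30 = 70.64 mm."""
        pos = rng.uniform(-100, 100, (400, 3))
        seed_pos = np.zeros(3)
        d = np.linalg.norm(pos, axis=1)
        v = np.exp(-(d**2) / (2 * 30.0**2))
        res = fit_psf_profile(PSFMap(0, v, "x"), seed_pos, pos)
        assert res.fwhm == pytest.approx(70.6446, abs=0.1)
        assert res.sigma_equivalent == pytest.approx(30.0, abs=0.05)

    def test_two_gaussian_recovery_with_noise(self, rng):
        a1, s1, a2, s2 = 0.55, 18.0, 0.35, 55.0
        pos = rng.uniform(-120, 120, (800, 3))
        d = np.linalg.norm(pos, axis=1)
        v = a1 * np.exp(-(d**2) / (2 * s1**2)) + a2 * np.exp(-(d**2) / (2 * s2**2))
        v = v + rng.normal(0, 0.01 * v.max(), len(v))
        res = fit_psf_profile(PSFMap(0, v, "x"), np.zeros(3), pos)
        got = res.params
        # components may swap; order by width
        got = sorted([(got[1], got[0]), (got[3], got[2])])
        for (gs, ga), (es, ea) in zip(got, [(s1, a1), (s2, a2)]):
            assert abs(gs - es) / es < 0.05
            assert abs(ga - ea) / ea < 0.05

    def test_constant_profile_rejected(self, rng):
        pos = rng.uniform(-50, 50, (100, 3))
        with pytest.raises(ValueError):
            fit_psf_profile(PSFMap(0, np.ones(100), "x"), np.zeros(3), pos)

    def test_too_few_points_rejected(self, rng):
        pos = rng.uniform(-50, 50, (10, 3))
        with pytest.raises(ValueError, match="20"):
            fit_psf_profile(PSFMap(0, rng.random(10), "x"), np.zeros(3), pos)

    def test_fwhm_consistent_with_curve_half_max(self, rng):
        """Contract: reported FWHM matches the fitted curve's numeric
        half-maximum crossing within 1%."""
        from headpsf.psf import _two_gauss

        pos = rng.uniform(-100, 100, (300, 3))
        d = np.linalg.norm(pos, axis=1)
        v = 0.7 * np.exp(-(d**2) / (2 * 25.0**2)) + 0.3 * np.exp(-(d**2) / (2 * 60.0**2))
        res = fit_psf_profile(PSFMap(0, v, "x"), np.zeros(3), pos)
        half = _two_gauss(0.0, *res.params) / 2
        at_half = _two_gauss(res.fwhm / 2, *res.params)
        assert abs(at_half - half) / half < 0.01


class TestSigmaFactor:
    def test_value_to_five_decimals(self):
        assert round(fwhm_sigma_factor(), 5) == 2.35482

    def test_round_trip(self):
        sigma = 17.3
        assert sigma * fwhm_sigma_factor() / fwhm_sigma_factor() == sigma

    def test_matches_numeric_half_width_of_unit_gaussian(self):
        from scipy.optimize import brentq

        half_width = brentq(lambda x: np.exp(-(x**2) / 2) - 0.5, 0, 3)
        assert fwhm_sigma_factor() == pytest.approx(2 * half_width, abs=1e-12)
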