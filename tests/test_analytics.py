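"""Closed-form stationary statistics against independent oracles.

The independent routes are: scipy's Beta distribution for the density (the
package evaluates the model's own log-gamma formula), adaptive quadrature for
normalization and moments, and numerical maximization for modes.
"""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist

import qsnoise as q
from qsnoise.analytics import (
    NoiseCurveFeatures,
    StationaryDensity,
    k_plus_eff_from_mean,
    lower_endpoint_slope_sign,
    noise_curve_features,
)

from conftest import GAMMAS, D_GRID, N_CELLS, R_RATIO, NR

PRESET_GRID = [
    (name, a, b, D) for name, (a, b) in GAMMAS.items() for D in D_GRID
]


class TestMean:
    def test_diffusionless_duty_cycle(self):
        assert q.mean_dimensionless(15, 5, 0.0, NR) == 0.25

    def test_gamma2_d100(self):
        # (1+0.1)/(1+0.1+100) · 0.25
        assert q.mean_dimensionless(15, 5, 100.0, NR) == pytest.approx(
            0.25 * 1.1 / 101.1, rel=1e-14
        )
        assert q.mean_dimensionless(15, 5, 100.0, NR) == pytest.approx(
            2.7201e-3, rel=1e-4
        )

    def test_infinite_diffusion_limit(self):
        limit = NR / (1.0 + NR) * 0.25
        assert q.mean_dimensionless(15, 5, 1e12, NR) == pytest.approx(limit, rel=1e-9)

    @given(D=st.floats(1e-6, 1e6))
    def test_diffusion_always_lowers_the_mean(self, D):
        assert q.mean_dimensionless(15, 5, D, NR) < 0.25

    def test_strictly_decreasing_in_diffusion(self):
        Ds = np.logspace(-3, 6, 300)
        vals = [q.mean_dimensionless(8, 2, d, NR) for d in Ds]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            q.mean_dimensionless(0.0, 0.0, 1.0, NR)


class TestExternalQSS:
    def test_dilution_factor_eleven(self):
        # ND̃r = 0.1 → c_ext = ⟨c⟩/11
        m = q.mean_dimensionless(15, 5, 100.0, NR)
        assert q.external_qss_concentration(m, 100.0, N_CELLS, R_RATIO) == pytest.approx(
            m / 11.0, rel=1e-14
        )

    def test_large_diffusion_equilibrates(self):
        assert q.external_qss_concentration(0.3, 1e12, N_CELLS, R_RATIO) == pytest.approx(
            0.3, rel=1e-8
        )

    def test_symmetry_point(self):
        # ND̃r = 1 → half the cell average
        assert q.external_qss_concentration(0.2, 1e3, N_CELLS, R_RATIO) == pytest.approx(
            0.1, rel=1e-14
        )

    def test_no_exchange_convention(self):
        assert q.external_qss_concentration(0.2, 0.0, N_CELLS, R_RATIO) == 0.0


class TestSupport:
    def test_diffusionless_full_burst_range(self):
        assert q.support_bounds(15, 5, 0.0, NR) == (0.0, 1.0)

    @pytest.mark.parametrize("name,a,b,D", PRESET_GRID)
    def test_width_is_inverse_keff(self, name, a, b, D):
        lo, hi = q.support_bounds(a, b, D, NR)
        assert hi - lo == pytest.approx(1.0 / (1.0 + D), rel=1e-12)

    def test_gamma2_d100_lower_barrier(self):
        lo, _ = q.support_bounds(15, 5, 100.0, NR)
        # explicit barrier formula D̃²Nr/[(1+D̃)(1+D̃+D̃Nr)]·β̃/(α̃+β̃)
        explicit = 100.0**2 * NR / (101.0 * (101.0 + 0.1)) * 0.25
        assert lo == pytest.approx(explicit, rel=1e-12)
        assert lo == pytest.approx(2.448e-4, rel=1e-3)
        # and the k₊_eff/k_eff route agrees
        m = q.mean_dimensionless(15, 5, 100.0, NR)
        assert lo == pytest.approx(k_plus_eff_from_mean(m, 100.0, NR) / 101.0, rel=1e-12)

    def test_lower_barrier_zero_iff_no_influx(self):
        assert q.support_bounds(15, 5, 0.0, NR)[0] == 0.0
        assert q.support_bounds(15, 0.0, 50.0, NR)[0] == 0.0
        assert q.support_bounds(15, 5, 50.0, NR)[0] > 0.0


class TestDensity:
    def test_matches_beta_oracle_diffusionless(self):
        d = StationaryDensity(15, 5, 0.0, NR)
        grid = np.linspace(0.01, 0.99, 25)
        np.testing.assert_allclose(d.pdf(grid), beta_dist.pdf(grid, 5, 15), rtol=1e-10)
        assert d.pdf(0.25) == pytest.approx(4.0466, abs=2e-4)

    def test_matches_beta_oracle_with_diffusion(self):
        d = StationaryDensity(15, 5, 10.0, NR)
        a, b = d.beta_exponents
        lo, hi = d.support
        grid = np.linspace(lo + 1e-6, hi - 1e-6, 25)
        oracle = beta_dist.pdf(grid, a, b, loc=lo, scale=1.0 / d.k_eff)
        np.testing.assert_allclose(d.pdf(grid), oracle, rtol=1e-9)

    def test_mode_by_numerical_maximization(self):
        d = StationaryDensity(15, 5, 0.0, NR)
        grid = np.linspace(1e-4, 1 - 1e-4, 200001)
        mode = grid[np.argmax(d.pdf(grid))]
        assert mode == pytest.approx(4.0 / 18.0, abs=1e-4)

    def test_zero_outside_support(self):
        d = StationaryDensity(15, 5, 100.0, NR)
        lo, hi = d.support
        assert d.pdf(lo - 1e-9) == 0.0
        assert d.pdf(hi + 1e-9) == 0.0

    def test_singular_endpoints_are_inf_not_nan(self):
        d = StationaryDensity(15, 5, 100.0, NR)  # exponents < 1: U-shaped
        lo, hi = d.support
        assert d.pdf(lo) == math.inf
        assert d.pdf(hi) == math.inf

    def test_cdf_monotone_and_normalized(self):
        d = StationaryDensity(15, 5, 100.0, NR)
        lo, hi = d.support
        grid = np.linspace(lo, hi, 101)
        c = d.cdf(grid)
        assert c[0] == 0.0 and c[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(c) >= 0)


class TestMomentAgreement:
    """Three-way agreement: closed forms, Beta-transform moments, quadrature."""

    @pytest.mark.parametrize("name,a,b,D", PRESET_GRID)
    def test_closed_forms_vs_beta_moments(self, name, a, b, D):
        d = StationaryDensity(a, b, D, NR)
        assert d.moment(0) == 1.0
        assert d.moment(1) == pytest.approx(
            q.mean_dimensionless(a, b, D, NR), rel=1e-12
        )
        cv2 = d.variance() / d.moment(1) ** 2
        assert cv2 == pytest.approx(
            q.transcriptional_noise(a, b, D, N_CELLS, R_RATIO), rel=1e-12
        )

    @staticmethod
    def _weighted_quad(d, f):
        """∫ f(c(x))·x^(a−1)(1−x)^(b−1) dx with QUADPACK's algebraic-weight
        rule, which handles the integrable endpoint singularities that a
        plain adaptive rule cannot resolve at large diffusion."""
        a, b = d.beta_exponents
        val, _ = integrate.quad(
            lambda x: f((x + d.k_plus_eff) / d.k_eff),
            0.0, 1.0, weight="alg", wvar=(a - 1.0, b - 1.0), limit=200,
        )
        return val

    @pytest.mark.parametrize(
        "name,a,b,D", [t for t in PRESET_GRID if t[3] <= 2000.0]
    )
    def test_quadrature_normalization_and_mean(self, name, a, b, D):
        d = StationaryDensity(a, b, D, NR)
        # density integrates to one over its support ...
        norm = math.exp(d.log_norm) / d.k_eff  # Jacobian dc = dx/k_eff
        total = norm * self._weighted_quad(d, lambda c: 1.0)
        assert total == pytest.approx(1.0, abs=1e-8)
        # ... and the quadrature mean matches the closed-form first moment
        m1 = norm * self._weighted_quad(d, lambda c: c)
        assert m1 == pytest.approx(d.moment(1), abs=1e-8)

    @pytest.mark.parametrize("name,a,b,D", [t for t in PRESET_GRID if t[3] <= 2000.0])
    def test_normalization_constant_vs_quadrature(self, name, a, b, D):
        # 𝒩 from log-gamma vs 𝒩 from numerically integrating the raw kernel
        d = StationaryDensity(a, b, D, NR)
        beta_integral = self._weighted_quad(d, lambda c: 1.0)
        assert math.exp(d.log_norm) == pytest.approx(
            d.k_eff / beta_integral, rel=1e-8
        )


class TestSelfConsistency:
    @pytest.mark.parametrize("name,a,b,D", PRESET_GRID)
    def test_fixed_point_equals_closed_form(self, name, a, b, D):
        assert q.self_consistent_mean(a, b, D, NR) == pytest.approx(
            q.mean_dimensionless(a, b, D, NR), rel=1e-10
        )

    def test_single_step_without_diffusion(self):
        assert q.self_consistent_mean(15, 5, 0.0, NR) == 0.25

    def test_no_production(self):
        assert q.self_consistent_mean(15, 0.0, 10.0, NR) == 0.0


class TestShapeClassification:
    @pytest.mark.parametrize(
        "D,expected",
        [
            (1.0, q.ShapeClass.INTERIOR_MAX),
            (10.0, q.ShapeClass.NO_EXTREMUM),
            (100.0, q.ShapeClass.INTERIOR_MIN),
        ],
    )
    def test_gamma2_progression(self, D, expected):
        assert q.classify_shape(15, 5, D) is expected

    def test_degenerate_boundary(self):
        assert q.classify_shape(15, 5, 4.0) is q.ShapeClass.DEGENERATE  # β̃ = k_eff
        assert q.classify_shape(15, 5, 14.0) is q.ShapeClass.DEGENERATE  # α̃ = k_eff

    def test_no_extremum_is_decreasing_in_the_allowed_region(self):
        # β̃ < k_eff < α̃ (the region reachable under low constitutive
        # expression) gives a monotonically decreasing density
        assert q.classify_shape(15, 5, 10.0) is q.ShapeClass.NO_EXTREMUM
        assert lower_endpoint_slope_sign(15, 5, 10.0) == -1
        d = StationaryDensity(15, 5, 10.0, NR)
        lo, hi = d.support
        grid = np.linspace(lo + 1e-4 * (hi - lo), hi - 1e-4 * (hi - lo), 500)
        assert np.all(np.diff(d.pdf(grid)) < 0)

    @given(D=st.floats(0.0, 200.0))
    def test_classification_matches_density_curvature(self, D):
        # near-degenerate parameters give an almost-flat endpoint that a
        # finite grid cannot resolve; stay clear of the transition lines
        assume(min(abs(15.0 - (1 + D)), abs(5.0 - (1 + D))) > 0.05)
        cls = q.classify_shape(15, 5, D)
        d = StationaryDensity(15, 5, D, NR)
        lo, hi = d.support
        grid = np.linspace(lo + 1e-3 * (hi - lo), hi - 1e-3 * (hi - lo), 301)
        vals = d.pdf(grid)
        interior_max = vals.argmax() not in (0, len(grid) - 1)
        interior_min = vals.argmin() not in (0, len(grid) - 1)
        if cls is q.ShapeClass.INTERIOR_MAX:
            assert interior_max and not interior_min
        elif cls is q.ShapeClass.INTERIOR_MIN:
            assert interior_min and not interior_max
        elif cls is q.ShapeClass.NO_EXTREMUM:
            assert not interior_max and not interior_min


class TestTranscriptionalNoise:
    def test_diffusionless_value(self):
        # α̃/(β̃(1+α̃+β̃)) = 15/(5·21) = 1/7
        assert q.transcriptional_noise(15, 5, 0.0, N_CELLS, R_RATIO) == pytest.approx(
            1.0 / 7.0, rel=1e-14
        )

    def test_gamma2_d100(self):
        assert q.transcriptional_noise(15, 5, 100.0, N_CELLS, R_RATIO) == pytest.approx(
            2.0736, abs=1e-4
        )

    def test_vanishes_at_large_diffusion(self):
        assert q.transcriptional_noise(15, 5, 1e6, N_CELLS, R_RATIO) < 1e-4

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            q.transcriptional_noise(15, 0.0, 1.0, N_CELLS, R_RATIO)


class TestExactFiniteNTranscriptionalNoise:
    """Spectral (no quasi-steady pool, finite N) vs closed-form route."""

    @pytest.mark.parametrize("D", [0.0, 1.0, 10.0])
    def test_agrees_with_closed_form_when_pool_decoupled(self, D):
        exact = q.transcriptional_noise_exact(15, 5, D, N_CELLS, R_RATIO)
        approx = q.transcriptional_noise(15, 5, D, N_CELLS, R_RATIO)
        assert exact == pytest.approx(approx, abs=2e-5)

    def test_closure_gap_peaks_near_unit_pool_coupling(self):
        # closed form underestimates by ~1e-3 at D̃·Nr ≈ 1
        gap = q.transcriptional_noise_exact(
            15, 5, 1000.0, N_CELLS, R_RATIO
        ) - q.transcriptional_noise(15, 5, 1000.0, N_CELLS, R_RATIO)
        assert gap == pytest.approx(1.06e-3, rel=0.1)

    def test_gap_vanishes_with_population_size(self):
        # at fixed Nr the correction is a finite-population effect ∝ 1/N
        gap100 = q.transcriptional_noise_exact(
            15, 5, 1000.0, 100, 1e-5
        ) - q.transcriptional_noise(15, 5, 1000.0, 100, 1e-5)
        gap400 = q.transcriptional_noise_exact(
            15, 5, 1000.0, 400, 2.5e-6
        ) - q.transcriptional_noise(15, 5, 1000.0, 400, 2.5e-6)
        assert gap400 == pytest.approx(gap100 / 4.0, rel=0.1)


class TestNoiseCurve:
    def test_gamma2_features(self):
        f = noise_curve_features(15, 5, N_CELLS, R_RATIO)
        assert isinstance(f, NoiseCurveFeatures)
        assert f.slope_at_zero > 0
        assert 50.0 <= f.argmax_D_t <= 150.0
        assert f.max_value == pytest.approx(
            q.transcriptional_noise(15, 5, f.argmax_D_t, N_CELLS, R_RATIO), rel=1e-9
        )
        assert f.max_value > q.transcriptional_noise(15, 5, 0.0, N_CELLS, R_RATIO)

    def test_white_noise_limit_kills_the_initial_slope(self):
        # shrinking τ_c at fixed duty cycle sends the initial slope to zero
        # (like 1/κ); the colored character of the mRNA noise is what makes
        # weak diffusion amplify fluctuations
        slopes = [
            noise_curve_features(15 * k, 5 * k, N_CELLS, R_RATIO).slope_at_zero
            for k in (1, 10, 100, 1000)
        ]
        assert all(s > 0 for s in slopes)
        assert all(s1 > s2 for s1, s2 in zip(slopes, slopes[1:]))
        assert slopes[-1] < 2e-3 * slopes[0]
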