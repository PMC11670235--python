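"""Concentration profiles, the gradient statistic and series comparison."""

import numpy as np
import pytest
from scipy import stats

import mexdiff as m
from mexdiff.exceptions import ComparisonError, ConfigError, InsufficientDataError
from mexdiff.readouts import ConcentrationProfile, profile_from_image
from mexdiff.simulator import sample_uniform_in_ellipsoid


def uniform_ensemble(geometry, n=50_000, seed=0):
    rng = np.random.default_rng(seed)
    pos = sample_uniform_in_ellipsoid(rng, n, geometry)
    states = (rng.random(n) < 0.5).astype(np.uint8)
    return m.Ensemble(pos, states, 0.0, "uniform")


def linear_profile(slope, n_bins=30):
    centers = (np.arange(n_bins) + 0.5) / n_bins
    values = 1.0 + slope * (0.5 - centers)
    return ConcentrationProfile(
        bin_centers=centers, values=values, species_component="total",
        convention="density", counts=np.ones(n_bins, dtype=int), n_total=n_bins,
    )


class TestConcentrationProfile:
    def test_uniform_density_is_flat_after_chord_correction(self, geometry):
        ens = uniform_ensemble(geometry)
        prof = m.concentration_profile(ens, geometry)
        vals = prof.values[np.isfinite(prof.values)]
        # uniform density -> corrected values ~1 everywhere
        assert abs(np.nanmean(vals) - 1.0) < 0.05
        fit = m.gradient_from_profile(prof)
        assert abs(fit.value) < 3 * max(fit.stderr, 0.02)

    def test_count_convention_sums_to_slab_fraction(self, geometry):
        ens = uniform_ensemble(geometry)
        prof = m.concentration_profile(ens, geometry, convention="count")
        total = np.nansum(prof.values)
        assert 0 < total <= 1.0
        # 5 µm slab of a 30 µm LR axis holds roughly a quarter of the mass
        assert 0.15 < total < 0.35

    def test_component_profiles_sum_to_total(self, geometry):
        ens = uniform_ensemble(geometry, n=20_000)
        slow = m.concentration_profile(ens, geometry, convention="count",
                                       component="slow")
        fast = m.concentration_profile(ens, geometry, convention="count",
                                       component="fast")
        total = m.concentration_profile(ens, geometry, convention="count",
                                        component="total")
        assert np.array_equal(slow.counts + fast.counts, total.counts)
        np.testing.assert_allclose(
            np.nan_to_num(slow.values) + np.nan_to_num(fast.values),
            np.nan_to_num(total.values), atol=1e-12,
        )

    def test_point_mass_lands_in_one_bin(self, geometry):
        pos = np.tile([-24.0, 0.0, 0.0], (100, 1))
        ens = m.Ensemble(pos, np.zeros(100, dtype=np.uint8), 0.0, "point")
        prof = m.concentration_profile(ens, geometry, convention="count")
        occupied = np.flatnonzero(np.nan_to_num(prof.values) > 0)
        assert len(occupied) == 1 and occupied[0] == 0

    def test_too_few_bins_rejected(self, geometry):
        ens = uniform_ensemble(geometry, n=100)
        with pytest.raises(ConfigError):
            m.concentration_profile(ens, geometry, n_bins=1)


class TestGradientStatistic:
    def test_flat_profile_gives_zero(self):
        assert m.gradient_from_profile(linear_profile(0.0)).value == pytest.approx(0.0, abs=1e-12)

    def test_constructed_steady_state_scale(self):
        """I(x) = 1.275 - 0.55 x has gradient magnitude 0.55."""
        fit = m.gradient_from_profile(linear_profile(0.55))
        assert fit.value == pytest.approx(0.55, abs=1e-9)
        assert fit.raw_slope == pytest.approx(-0.55, abs=1e-9)

    def test_gain_invariance(self):
        """The statistic is invariant to detector gain (mean normalisation)."""
        prof = linear_profile(0.3)
        scaled = ConcentrationProfile(
            bin_centers=prof.bin_centers, values=7.3 * prof.values,
            species_component="total", convention="density",
            counts=prof.counts, n_total=prof.n_total,
        )
        assert m.gradient_from_profile(scaled).value == pytest.approx(
            m.gradient_from_profile(prof).value, rel=1e-12
        )

    def test_insufficient_occupied_bins(self):
        prof = linear_profile(0.2)
        values = np.full_like(prof.values, np.nan)
        values[10] = 1.0
        values[11] = 1.0
        sparse = ConcentrationProfile(
            bin_centers=prof.bin_centers, values=values,
            species_component="total", convention="density",
            counts=prof.counts, n_total=prof.n_total,
        )
        with pytest.raises(InsufficientDataError):
            m.gradient_from_profile(sparse)

    def test_ols_confidence_interval_coverage(self):
        """95% CI of the fitted slope covers the truth in >= 93% of seeds."""
        truth = 0.55
        n_bins, noise_sd = 50, 0.05
        x = (np.arange(n_bins) + 0.5) / n_bins
        tcrit = stats.t.ppf(0.975, n_bins - 2)
        rng = np.random.default_rng(123)
        hits = 0
        n_trials = 1000
        for _ in range(n_trials):
            y = 1.0 + truth * (0.5 - x) + rng.normal(0, noise_sd, n_bins)
            res = stats.linregress(x, y)
            lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
            hits += lo <= -truth <= hi
        assert hits / n_trials >= 0.93


class TestSeries:
    def test_identical_series_zero_residuals(self):
        s = m.GradientSeries(times=np.array([0.0, 1.0, 2.0]),
                             gradient=np.array([0.1, 0.2, 0.3]),
                             spread=np.zeros(3))
        res = m.compare_series(s, s)
        assert res.rms == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset_gives_rms_equal_to_offset(self):
        t = np.linspace(0, 10, 6)
        a = m.GradientSeries(times=t, gradient=np.sin(t), spread=np.zeros(6))
        b = m.GradientSeries(times=t, gradient=np.sin(t) + 0.25, spread=np.zeros(6))
        assert m.compare_series(b, a).rms == pytest.approx(0.25, abs=1e-12)

    def test_disjoint_supports_rejected(self):
        a = m.GradientSeries(times=np.array([0.0, 1.0]),
                             gradient=np.zeros(2), spread=np.zeros(2))
        b = m.GradientSeries(times=np.array([5.0, 6.0]),
                             gradient=np.zeros(2), spread=np.zeros(2))
        with pytest.raises(ComparisonError):
            m.compare_series(a, b)

    def test_steady_state_extraction_flags_drift(self):
        t = np.linspace(0, 1000, 21)
        flat = m.GradientSeries(times=t, gradient=np.full(21, 0.5),
                                spread=np.full(21, 0.05))
        value, _, drifting = m.steady_state_gradient(flat)
        assert value == pytest.approx(0.5) and not drifting
        rising = m.GradientSeries(times=t, gradient=np.linspace(0, 1, 21),
                                  spread=np.full(21, 0.01))
        _, _, drifting = m.steady_state_gradient(rising)
        assert drifting


class TestImageReadout:
    def test_flat_image_gives_zero_gradient(self):
        img = m.make_gradient_image(0.0, 0.0, seed=1)
        fit = m.gradient_from_image(img.pixels, img.mask)
        assert abs(fit.value) < 1e-9

    def test_noiseless_linear_image_recovers_slope(self):
        img = m.make_gradient_image(0.55, 0.0, seed=1)
        fit = m.gradient_from_image(img.pixels, img.mask)
        assert fit.value == pytest.approx(0.55, abs=0.01)

    def test_profile_from_image_marks_empty_bins(self):
        pixels = np.ones((10, 40))
        mask = np.zeros((10, 40), dtype=bool)
        mask[:, 10:30] = True
        prof = profile_from_image(pixels, mask, n_bins=8)
        assert np.isnan(prof.values[0]) and np.isnan(prof.values[-1])
        assert np.isfinite(prof.values[3])


def test_anterior_slow_fraction_counts_slow_share(geometry):
    rng = np.random.default_rng(0)
    pos = sample_uniform_in_ellipsoid(rng, 10_000, geometry)
    x_hat = geometry.normalized_ap(pos[:, 0])
    states = np.where(x_hat < 0.5, m.SLOW, m.FAST).astype(np.uint8)
    ens = m.Ensemble(pos, states, 0.0, "half")
    assert m.anterior_slow_fraction(ens, geometry) == pytest.approx(1.0)
    assert m.anterior_slow_fraction(ens, geometry, region_frac=1.0) == pytest.approx(
        float(np.mean(states == m.SLOW)), abs=1e-12
    )
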