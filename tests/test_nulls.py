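"""Circular-shift nulls, normal/gamma fits, and significance grids."""

import numpy as np
import pytest
from scipy import stats

import strfkit
from strfkit.exceptions import (
    DegenerateFitError,
    InvalidParameterError,
    TooFewClustersError,
)
from strfkit.nulls import _fit_excluding
from strfkit.sta import StrfEstimate


def make_synthetic_ensemble(values_list, dt=0.001):
    """Wrap raw pixel matrices as a NullEnsemble for fit-level tests."""
    stas = []
    for v in values_list:
        v = np.asarray(v, dtype=np.float64)
        stas.append(
            StrfEstimate(
                values=v,
                freq_axis=np.arange(v.shape[0]) * 0.1,
                lag_axis=np.arange(v.shape[1]) * dt,
                n_spikes_used=100,
            )
        )
    return strfkit.NullEnsemble(
        null_stas=stas, shifts=np.zeros(len(stas)), seed=0
    )


class TestPGrid:
    def test_grid_endpoints_and_retained_levels(self):
        grid = strfkit.make_p_grid()
        assert grid.p_values[0] == 1.0
        assert round(grid.p_values[1], 2) == 0.49
        assert round(grid.p_values[2], 2) == 0.24
        assert len(grid.retained_gain_levels) == 20
        assert grid.retained_gain_levels[0] == grid.p_values[2]

    def test_grid_is_exact_in_exponent_space(self):
        grid = strfkit.make_p_grid()
        np.testing.assert_allclose(
            np.log10(grid.p_values), -9.0 * np.arange(30) / 29.0, atol=1e-14
        )


class TestCircularShift:
    def test_zero_shift_is_identity(self):
        sp = np.array([0.5, 1.25, 7.5])
        np.testing.assert_array_equal(strfkit.circular_shift(sp, 10.0, delta=0.0), sp)

    def test_modular_arithmetic(self):
        shifted = strfkit.circular_shift(np.array([1.0, 2.0, 9.0]), 10.0, delta=3.0)
        np.testing.assert_allclose(shifted, [2.0, 4.0, 5.0])

    def test_circular_isi_multiset_preserved(self):
        sp = np.array([0.3, 1.1, 2.0, 4.7, 9.9])
        T = 10.0

        def circ_isi(s):
            d = np.diff(np.sort(s))
            wrap = T - np.sort(s)[-1] + np.sort(s)[0]
            return np.sort(np.append(d, wrap))

        base = circ_isi(sp)
        for delta in np.linspace(0.0, T, 41):
            np.testing.assert_allclose(
                circ_isi(strfkit.circular_shift(sp, T, delta=delta)), base, atol=1e-9
            )

    def test_invalid_duration(self):
        with pytest.raises(InvalidParameterError):
            strfkit.circular_shift(np.array([1.0]), 0.0, seed=0)


class TestNullEnsemble:
    def test_spike_counts_preserved_within_drop_window(self, noise_unit, env20):
        n_total = len(noise_unit["spikes"])
        expected_drop = n_total * 0.2 / env20.duration
        for sta in noise_unit["ens"].null_stas:
            assert abs(sta.n_spikes_used - n_total) <= 10 * max(expected_drop, 1)

    def test_grand_mean_near_zero(self, noise_unit):
        pooled = noise_unit["ens"].pixel_matrix()
        se = pooled.std() / np.sqrt(pooled.size / 40)  # correlated pixels: be lax
        assert abs(pooled.mean()) < 5 * se + 1e-3

    def test_fixed_seed_reproducible(self, env20):
        sp = np.sort(np.random.default_rng(1).uniform(0, env20.duration, 150))
        a = strfkit.build_null_ensemble(sp, env20, n_null=5, seed=42)
        b = strfkit.build_null_ensemble(sp, env20, n_null=5, seed=42)
        np.testing.assert_array_equal(a.shifts, b.shifts)
        for x, y in zip(a.null_stas, b.null_stas):
            np.testing.assert_array_equal(x.values, y.values)

    def test_fft_path_matches_direct_path(self, env20):
        # dual-route check: the one-correlation FFT evaluation must equal
        # shifting the spikes and recomputing the STA
        rng = np.random.default_rng(9)
        sp = (np.floor(rng.uniform(0, env20.duration, 120) / env20.dt) + 0.5) * env20.dt
        sp = np.sort(sp)
        fa = strfkit.build_null_ensemble(sp, env20, n_null=10, seed=3, method="fft")
        di = strfkit.build_null_ensemble(sp, env20, n_null=10, seed=3, method="direct")
        for a, b in zip(fa.null_stas, di.null_stas):
            assert a.n_spikes_used == b.n_spikes_used
            np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestGainNull:
    def test_normal_fit_consistency(self):
        rng = np.random.default_rng(0)
        ens = make_synthetic_ensemble([rng.normal(0, 1, (100, 100)) for _ in range(100)])
        fit = strfkit.fit_gain_null(ens)
        assert abs(fit.mu) < 0.01
        assert 0.99 < fit.sigma < 1.01
        assert fit.n_samples == 10**6

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        vals = [rng.normal(0, 1, (20, 20)) for _ in range(5)]
        f1 = strfkit.fit_gain_null(make_synthetic_ensemble(vals))
        f3 = strfkit.fit_gain_null(make_synthetic_ensemble([3.0 * v for v in vals]))
        assert f3.sigma == pytest.approx(3.0 * f1.sigma, rel=1e-12)

    def test_fit_equals_pooled_flat_sample(self):
        rng = np.random.default_rng(2)
        vals = [rng.normal(0.3, 2.0, (10, 15)) for _ in range(4)]
        fit = strfkit.fit_gain_null(make_synthetic_ensemble(vals))
        flat = np.concatenate([v.ravel() for v in vals])
        assert fit.mu == pytest.approx(flat.mean(), rel=1e-12)
        assert fit.sigma == pytest.approx(flat.std(), rel=1e-12)

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateFitError):
            strfkit.fit_gain_null(make_synthetic_ensemble([np.ones((5, 5))]))

    @pytest.mark.parametrize(
        "p,expected_hi,tol",
        [(0.01, 2.5758, 1e-3), (0.49, 0.690, 1e-2)],
    )
    def test_cutoffs_match_inverse_cdf(self, p, expected_hi, tol):
        fit = strfkit.GainNullFit(mu=0.0, sigma=1.0, n_samples=1000)
        lo, hi = strfkit.gain_cutoff(fit, p)
        assert hi == pytest.approx(expected_hi, abs=tol)
        assert lo == pytest.approx(-expected_hi, abs=tol)

    def test_p_one_collapses_to_mu(self):
        fit = strfkit.GainNullFit(mu=0.7, sigma=2.0, n_samples=10)
        lo, hi = strfkit.gain_cutoff(fit, 1.0)
        assert lo == hi == pytest.approx(0.7)

    def test_cutoff_monotone_in_p(self):
        fit = strfkit.GainNullFit(mu=0.0, sigma=1.0, n_samples=10)
        his = [strfkit.gain_cutoff(fit, p)[1] for p in strfkit.make_p_grid().p_values]
        assert np.all(np.diff(his) >= 0)  # descending p -> increasing cutoff

    def test_empirical_false_positive_rate_matches_p(self, noise_unit, env20):
        # held-out null STAs thresholded at liberal p survive at ~p rate
        sp = noise_unit["spikes"]
        fit = strfkit.fit_gain_null(noise_unit["ens"])
        fresh = strfkit.build_null_ensemble(sp, env20, n_null=30, seed=777)
        n_pixels = fresh.null_stas[0].values.size
        for p in (0.2395, 0.05, 0.01):
            lo, hi = strfkit.gain_cutoff(fit, p)
            frac = np.mean(
                [
                    np.count_nonzero((s.values <= lo) | (s.values >= hi)) / n_pixels
                    for s in fresh.null_stas
                ]
            )
            assert frac == pytest.approx(p, rel=0.35)


class TestClusterNull:
    def _toy_ensemble(self, n=3, seed=0, peak=100.0):
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n):
            v = rng.normal(0, 0.1, (12, 12))
            v[4, 4] = peak
            vals.append(v)
        return make_synthetic_ensemble(vals)

    def test_pairwise_scheme_samples_ordered_pairs(self):
        # at a very conservative level only the planted peak survives, so
        # each ordered (i, j) pair contributes exactly one cluster mass
        ens = self._toy_ensemble(n=3)
        masses = strfkit.sample_null_cluster_masses(
            ens, 1e-4, stride_i=1, stride_j=1, scheme="pairwise"
        )
        assert len(masses) == 6
        np.testing.assert_allclose(masses, 100.0, rtol=1e-6)

    def test_ultra_conservative_level_yields_empty_sample(self):
        ens = self._toy_ensemble(n=3, peak=0.0)
        masses = strfkit.sample_null_cluster_masses(ens, 1e-9, scheme="pooled")
        assert len(masses) == 0

    def test_pooled_scheme_matches_brute_force(self):
        # independent reimplementation: leave-one-out normal fit, elementwise
        # threshold, recursive flood fill, summed |pixels|
        rng = np.random.default_rng(5)
        vals = [rng.normal(0, 1.0, (10, 10)) for _ in range(4)]
        ens = make_synthetic_ensemble(vals)
        level = 0.1
        got = np.sort(
            strfkit.sample_null_cluster_masses(ens, level, scheme="pooled")
        )

        def flood_masses(v, lo, hi):
            keep = (v <= lo) | (v >= hi)
            seen = np.zeros_like(keep)
            masses = []
            for i in range(v.shape[0]):
                for j in range(v.shape[1]):
                    if keep[i, j] and not seen[i, j]:
                        sign = np.sign(v[i, j])
                        stack, mass = [(i, j)], 0.0
                        seen[i, j] = True
                        while stack:
                            a, b = stack.pop()
                            mass += abs(v[a, b])
                            for da in (-1, 0, 1):
                                for db in (-1, 0, 1):
                                    x, y = a + da, b + db
                                    if (
                                        0 <= x < v.shape[0] and 0 <= y < v.shape[1]
                                        and keep[x, y] and not seen[x, y]
                                        and np.sign(v[x, y]) == sign
                                    ):
                                        seen[x, y] = True
                                        stack.append((x, y))
                        masses.append(mass)
            return masses

        expected = []
        for i in range(4):
            others = np.concatenate([vals[j].ravel() for j in range(4) if j != i])
            mu, sigma = others.mean(), others.std()
            lo = stats.norm.ppf(level / 2, mu, sigma)
            hi = stats.norm.ppf(1 - level / 2, mu, sigma)
            expected.extend(flood_masses(vals[i], lo, hi))
        np.testing.assert_allclose(got, np.sort(expected), rtol=1e-9)

    def test_leave_one_out_fit_identity(self):
        rng = np.random.default_rng(6)
        rows = [rng.normal(0, 1, 50) for _ in range(3)]
        total_sum = sum(r.sum() for r in rows)
        total_sq = sum((r * r).sum() for r in rows)
        fit = _fit_excluding(total_sum, total_sq, 150, rows[1])
        rest = np.concatenate([rows[0], rows[2]])
        assert fit.mu == pytest.approx(rest.mean(), rel=1e-9)
        assert fit.sigma == pytest.approx(rest.std(), rel=1e-9)

    def test_gamma_fit_exponential_closed_form(self):
        rng = np.random.default_rng(7)
        masses = rng.exponential(1.0, 10**5)
        fit = strfkit.fit_cluster_null(masses, 0.05)
        cutoff = strfkit.cluster_cutoff(fit, 0.01)
        assert cutoff == pytest.approx(-np.log(0.01), abs=0.15)

    def test_cluster_cutoff_p_one_is_zero(self):
        fit = strfkit.ClusterNullFit(0.05, shape=2.0, scale=1.5, n_clusters_sampled=100)
        assert strfkit.cluster_cutoff(fit, 1.0) == 0.0

    def test_mass_scale_equivariance(self):
        rng = np.random.default_rng(8)
        masses = rng.gamma(2.0, 1.0, 5000)
        c1 = strfkit.cluster_cutoff(strfkit.fit_cluster_null(masses, 0.05), 0.01)
        c7 = strfkit.cluster_cutoff(strfkit.fit_cluster_null(7.0 * masses, 0.05), 0.01)
        assert c7 == pytest.approx(7.0 * c1, rel=1e-6)

    def test_too_few_masses_carries_gain_level(self):
        with pytest.raises(TooFewClustersError) as err:
            strfkit.fit_cluster_null(np.array([1.0, 2.0]), 0.0281)
        assert err.value.gain_level == pytest.approx(0.0281)

    def test_gamma_cutoffs_match_empirical_quantiles(self):
        rng = np.random.default_rng(9)
        masses = rng.gamma(1.7, 2.3, 10**4)
        fit = strfkit.fit_cluster_null(masses, 0.05)
        for p in (0.2, 0.05, 0.01):
            fitted = strfkit.cluster_cutoff(fit, p)
            empirical = np.quantile(masses, 1 - p)
            assert fitted == pytest.approx(empirical, rel=0.10)

    def test_cluster_cutoffs_monotone_in_p(self):
        fit = strfkit.ClusterNullFit(0.05, shape=1.5, scale=2.0, n_clusters_sampled=50)
        cuts = [strfkit.cluster_cutoff(fit, p) for p in strfkit.make_p_grid().p_values]
        assert np.all(np.diff(cuts) >= 0)


class TestSignificanceGrid:
    def test_grid_has_fits_for_retained_levels(self, driven_unit):
        grids = driven_unit["grids"]
        available = [
            grids.has_cluster_fit(level)
            for level in grids.p_grid.retained_gain_levels
        ]
        # liberal levels must be fitted; very conservative ones may be empty
        assert all(available[:8])

    def test_unavailable_cell_raises(self):
        grid = strfkit.SignificanceGrid(
            p_grid=strfkit.make_p_grid(),
            gain_fit=strfkit.GainNullFit(0.0, 1.0, 100),
        )
        from strfkit.exceptions import UnavailableSettingError

        with pytest.raises(UnavailableSettingError):
            grid.cluster_mass_cutoff(0.05, 0.01)
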