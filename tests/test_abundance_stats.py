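import numpy as np
import pytest
import statsmodels.api as sm

from ihat.abundance_stats import (
    SampleAbundance,
    deviance_f_test,
    esc_normalize,
    estimate_nutrient,
    fit_quasipoisson,
    subsample_db,
)


class TestSubsample:
    def test_full_sample_is_identity(self):
        frags = list(range(10))
        assert subsample_db(frags, 10, seed=1) == frags

    def test_deterministic_and_order_preserving(self):
        frags = list(range(1000))
        a = subsample_db(frags, 500, seed=4)
        b = subsample_db(frags, 500, seed=4)
        assert a == b
        assert a == sorted(a)  # original order retained
        c = subsample_db(frags, 500, seed=5)
        assert a != c

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            subsample_db([1, 2, 3], 4, seed=0)

    def test_inclusion_frequency_is_uniform(self):
        counts = np.zeros(100)
        for seed in range(2000):
            counts[subsample_db(list(range(100)), 50, seed)] += 1
        freq = counts / 2000
        assert abs(freq.mean() - 0.5) < 1e-12  # exactly n/N overall
        assert np.all(np.abs(freq - 0.5) < 0.05)


class TestESC:
    def _sample(self, sid, n, marker, gene=0):
        return SampleAbundance(sid, n, {"g": gene}, marker)

    def test_equal_marker_density_keeps_sample_sizes(self):
        samples = [self._sample("a", 1000, 10), self._sample("b", 2000, 20)]
        out = esc_normalize(samples)
        assert [s.esc for s in out] == [1000.0, 2000.0]

    def test_double_density_doubles_esc(self):
        samples = [
            self._sample("a", 1000, 10),
            self._sample("b", 1000, 10),
            self._sample("c", 1000, 20),
        ]
        out = esc_normalize(samples)
        assert out[2].esc == pytest.approx(2000.0)

    def test_marker_frequency_exactly_constant_after_normalization(self):
        rng = np.random.default_rng(6)
        samples = [
            self._sample(f"s{i}", int(rng.integers(1e3, 1e5)), int(rng.integers(5, 500)))
            for i in range(20)
        ]
        out = esc_normalize(samples)
        freqs = np.array([s.marker_count / s.esc for s in out])
        assert np.all(np.abs(freqs - freqs[0]) < 1e-12)

    def test_zero_marker_count_names_the_sample(self):
        with pytest.raises(ValueError, match="bad_sample"):
            esc_normalize([self._sample("bad_sample", 100, 0)])

    def test_removes_average_genome_size_bias(self):
        """Two communities with equal per-genome gene content but 2 Mb vs
        4 Mb average genomes: per-sequence frequencies differ ~2-fold,
        per-ESC frequencies agree within sampling error."""
        gene_len, marker_len = 2000.0, 5 * 2000.0
        rng = np.random.default_rng(7)

        def community(sid, n, gsize):
            gc = rng.binomial(n, gene_len / gsize)
            mc = rng.binomial(n, marker_len / gsize)
            return SampleAbundance(sid, n, {"g": int(gc)}, int(mc))

        a, b = community("a", 200_000, 2e6), community("b", 200_000, 4e6)
        na, nb = esc_normalize([a, b])
        per_seq = (a.gene_counts["g"] / a.n_sequences) / (
            b.gene_counts["g"] / b.n_sequences
        )
        per_esc = (na.gene_counts["g"] / na.esc) / (nb.gene_counts["g"] / nb.esc)
        assert 1.6 < per_seq < 2.5
        assert 0.8 < per_esc < 1.25


class TestQuasipoisson:
    def test_intercept_only_closed_form(self):
        fit = fit_quasipoisson(np.array([4, 4, 4, 4]))
        assert fit.coefficients[0] == pytest.approx(np.log(4.0))
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    def test_matches_reference_glm_to_1e6(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(20, 80))
            x = rng.normal(0, 1, n)
            off = np.log(rng.uniform(0.5, 2.0, n))
            y = rng.poisson(np.exp(0.5 + 0.8 * x + off))
            if not y.any():
                continue
            fit = fit_quasipoisson(y, x, off)
            ref = sm.GLM(
                y, sm.add_constant(x), family=sm.families.Poisson(), offset=off
            ).fit()
            assert np.abs(fit.coefficients - ref.params).max() < 1e-6
            assert fit.deviance == pytest.approx(ref.deviance, rel=1e-6)

    def test_parameter_recovery_with_dispersion_near_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 500)
        y = rng.poisson(np.exp(1.0 - 2.0 * x))
        fit = fit_quasipoisson(y, x)
        assert np.all(
            np.abs(fit.coefficients - [1.0, -2.0]) < 3 * fit.std_errors
        )
        assert 0.8 < fit.dispersion < 1.2

    def test_dispersion_tends_to_one_for_true_poisson(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 2000)
        y = rng.poisson(np.exp(0.5 + 0.3 * x))
        assert 0.9 < fit_quasipoisson(y, x).dispersion < 1.1

    def test_coefficients_invariant_to_covariate_reordering(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, (60, 2))
        y = rng.poisson(np.exp(0.2 + 0.5 * x[:, 0] - 0.3 * x[:, 1]))
        f1 = fit_quasipoisson(y, x)
        f2 = fit_quasipoisson(y, x[:, ::-1])
        assert f1.coefficients[1] == pytest.approx(f2.coefficients[2])
        assert f1.coefficients[2] == pytest.approx(f2.coefficients[1])

    def test_all_zero_response_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_quasipoisson(np.zeros(10))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_quasipoisson(np.array([1.5, 2.0]))


class TestDevianceFTest:
    def test_identical_fits_give_f_zero_p_one(self):
        y = np.array([3, 5, 2, 8, 4])
        fit = fit_quasipoisson(y)
        assert deviance_f_test(fit, fit) == (0.0, 1.0)

    def test_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(2000)  :
            x = rng.normal(0, 1, 38)
            y = rng.poisson(4.0, 38)
            _, p = deviance_f_test(fit_quasipoisson(y, x), fit_quasipoisson(y))
            rejections += p < 0.05
        assert 0.038 <= rejections / 2000 <= 0.062

    def test_p_values_uniform_under_the_null(self):
        rng = np.random.default_rng(22)
        ps = []
        for _ in range(2000):
            x = rng.normal(0, 1, 38)
            y = rng.poisson(4.0, 38)
            ps.append(
                deviance_f_test(fit_quasipoisson(y, x), fit_quasipoisson(y))[1]
            )
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - np.arange(1, 2001) / 2000.0))
        assert ks < 0.05

    def test_planted_slope_detected_at_small_n(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(200):
            x = rng.uniform(0, 2, 38)
            y = rng.poisson(np.exp(2.0 - 1.5 * x))
            _, p = deviance_f_test(fit_quasipoisson(y, x), fit_quasipoisson(y))
            hits += p < 0.001
        assert hits / 200 >= 0.95

    def test_non_nested_models_rejected(self):
        rng = np.random.default_rng(13)
        y1 = rng.poisson(4.0, 20)
        y2 = rng.poisson(4.0, 30)
        with pytest.raises(ValueError, match="different data"):
            deviance_f_test(fit_quasipoisson(y1), fit_quasipoisson(y2))


class TestNutrientEstimation:
    def test_simple_site_median(self):
        (est,) = estimate_nutrient([("s1", 0.1), ("s1", 0.2), ("s1", 0.3)])
        assert est.accepted and est.median_value == pytest.approx(0.2)

    def test_two_surviving_records_not_accepted(self):
        (est,) = estimate_nutrient([("s1", 0.1), ("s1", 0.2)])
        assert not est.accepted
        assert est.n_records == 2

    def test_extreme_outlier_removed_before_median(self):
        (est,) = estimate_nutrient(
            [("s1", 0.1), ("s1", 0.2), ("s1", 0.3), ("s1", 16000.0)]
        )
        assert est.n_records == 3
        assert est.median_value == pytest.approx(0.2)

    def test_even_count_uses_mean_of_middle_values(self):
        (est,) = estimate_nutrient(
            [("s1", 0.1), ("s1", 0.2), ("s1", 0.4), ("s1", 0.8)]
        )
        assert est.median_value == pytest.approx(0.3)

    def test_order_invariant(self):
        records = [("b", 0.5), ("a", 0.1), ("a", 0.3), ("b", 0.7), ("a", 0.2)]
        assert estimate_nutrient(records) == estimate_nutrient(records[::-1])

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValueError):
            estimate_nutrient([("s1", -0.1)])
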