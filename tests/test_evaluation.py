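import numpy as np
import pytest

from tremorsep.evaluation import (
    compare_methods,
    endpoint_errors,
    mse,
    relative_mse,
    sliding_psd,
    spectral_population_compare,
)
from tremorsep.model import NetworkOutput


class TestMSE:
    def test_zero_residual(self, rng):
        x = rng.standard_normal(100)
        assert mse(x, x) == 0.0

    def test_constant_offset(self):
        a = np.zeros(50)
        assert mse(a + 0.3, a) == pytest.approx(0.09, abs=1e-15)

    def test_matches_summation_loop(self, rng):
        a = rng.standard_normal(400)
        b = rng.standard_normal(400)
        oracle = sum((ai - bi) ** 2 for ai, bi in zip(a, b)) / 400
        assert mse(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_quadratic_scaling(self, rng):
        a, b = rng.standard_normal(64), rng.standard_normal(64)
        assert mse(a, b) == mse(b, a)
        assert mse(3 * a, 3 * b) == pytest.approx(9 * mse(a, b), rel=1e-12)

    def test_normalized_flag_checks_pipeline_scale(self, rng):
        u = rng.uniform(0, 1, 40)
        assert mse(u, u, normalized=True) == 0.0
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            mse(u, u * 5 + 2, normalized=True)

    def test_relative_variant(self, rng):
        b = rng.uniform(0.5, 1.0, 64)
        a = b + 0.1
        assert relative_mse(a, b) == pytest.approx(mse(a, b) / np.mean(b**2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.ones(3), np.ones(4))


class TestEndpointErrors:
    @staticmethod
    def _out(f, b):
        return NetworkOutput(forward_estimate=np.asarray(f), backward_estimate=np.asarray(b))

    def test_perfect_outputs(self):
        tgt = np.linspace(0, 1, 5)
        last, first = endpoint_errors([self._out(tgt, tgt)], [tgt])
        assert last == 0.0 and first == 0.0

    def test_single_sample_arithmetic(self):
        tgt = np.zeros(4)
        f = np.array([0.0, 0.0, 0.0, 0.1])
        last, first = endpoint_errors([self._out(f, tgt)], [tgt])
        assert last == pytest.approx(0.01)
        assert first == 0.0

    def test_matches_indexing_oracle(self, rng):
        outs, tgts = [], []
        for _ in range(10):
            tgt = rng.standard_normal(20)
            outs.append(self._out(rng.standard_normal(20), rng.standard_normal(20)))
            tgts.append(tgt)
        last, first = endpoint_errors(outs, tgts)
        oracle_last = np.mean(
            [(o.forward_estimate[-1] - t[-1]) ** 2 for o, t in zip(outs, tgts)]
        )
        oracle_first = np.mean(
            [(o.backward_estimate[0] - t[0]) ** 2 for o, t in zip(outs, tgts)]
        )
        assert last == pytest.approx(oracle_last, abs=1e-12)
        assert first == pytest.approx(oracle_first, abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            endpoint_errors([], [])


class TestSlidingPSD:
    def test_column_count_formula(self):
        freqs, times, psd = sliding_psd(np.zeros(100), window=50, overlap=45)
        assert psd.shape[1] == 11  # floor((100 - 50) / 5) + 1

    def test_zero_series_all_zero(self):
        _, _, psd = sliding_psd(np.zeros(200), window=50, overlap=45)
        np.testing.assert_array_equal(psd, 0.0)
        assert np.all(psd >= 0)

    def test_pure_tone_peak_location(self):
        # 6 Hz is bin-aligned for a 50-sample window at 100 Hz (2 Hz bins)
        t = np.arange(400) / 100.0
        freqs, _, psd = sliding_psd(np.sin(2 * np.pi * 6.0 * t), window=50, overlap=45)
        assert np.all(freqs[np.argmax(psd, axis=0)] == 6.0)

    def test_out_of_band_component_does_not_leak(self):
        t = np.arange(400) / 100.0
        x = np.sin(2 * np.pi * 6.0 * t)
        y = x + 0.5 * np.sin(2 * np.pi * 20.0 * t)
        f1, _, p1 = sliding_psd(x, window=50, overlap=45)
        _, _, p2 = sliding_psd(y, window=50, overlap=45)
        bin6 = np.argmin(np.abs(f1 - 6.0))
        np.testing.assert_allclose(p2[bin6], p1[bin6], rtol=1e-8, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sliding_psd(np.zeros(40), window=50, overlap=45)
        with pytest.raises(ValueError):
            sliding_psd(np.zeros(100), window=50, overlap=50)


class TestSpectralPopulationCompare:
    def test_identical_populations(self, rng):
        group = rng.standard_normal((30, 64))
        summary = spectral_population_compare(group, group.copy())
        assert np.all(summary.p_values >= 0.99)
        np.testing.assert_allclose(
            summary.input_ci_halfwidth, summary.output_ci_halfwidth
        )
        assert 0.0 not in summary.freqs_hz

    def test_shifted_bin_detected(self, rng):
        inputs = rng.standard_normal((100, 100))
        t = np.arange(100) / 100.0
        outputs = inputs + 40.0 * np.sin(2 * np.pi * 10.0 * t)  # shift the 10 Hz bin
        summary = spectral_population_compare(inputs, outputs)
        bin10 = np.argmin(np.abs(summary.freqs_hz - 10.0))
        assert summary.p_values[bin10] < 1e-10
        far_bin = np.argmin(np.abs(summary.freqs_hz - 30.0))
        assert summary.p_values[far_bin] > 0.01

    def test_ci_halfwidth_formula(self, rng):
        inputs = rng.standard_normal((100, 32))
        summary = spectral_population_compare(inputs, rng.standard_normal((100, 32)))
        mags = np.abs(np.fft.rfft(inputs, axis=1))[:, 1:]
        np.testing.assert_allclose(
            summary.input_ci_halfwidth,
            1.96 * mags.std(axis=0, ddof=1) / np.sqrt(100),
            rtol=1e-12,
        )

    def test_small_groups_rejected(self, rng):
        g = rng.standard_normal((10, 32))
        with pytest.raises(ValueError, match="20"):
            spectral_population_compare(g, g)


class TestCompareMethods:
    def test_improvement_arithmetic(self, rng):
        base = np.full(50, 0.20) + rng.normal(0, 1e-6, 50)
        good = np.full(50, 0.02) + rng.normal(0, 1e-6, 50)
        cmp = compare_methods({"good": good, "base": base}, reference="good")
        assert cmp.improvement_pct["base"] == pytest.approx(90.0, abs=0.01)

    def test_identical_groups_null_case(self, rng):
        errs = np.abs(rng.standard_normal(40))
        cmp = compare_methods({"a": errs, "b": errs.copy()}, reference="a")
        assert cmp.improvement_pct["b"] == pytest.approx(0.0, abs=1e-12)
        assert cmp.anova_p > 0.99

    def test_separated_groups(self, rng):
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(5.0, 1.0, 100)  # 5 pooled sd apart
        cmp = compare_methods({"a": a, "b": b}, reference="a")
        assert cmp.pairwise_p[("a", "b")] < 1e-6
        assert cmp.means["a"] + cmp.ci_halfwidth["a"] < cmp.means["b"] - cmp.ci_halfwidth["b"]
        assert cmp.anova_p < 1e-6

    def test_bonferroni_labelled_adjustment(self, rng):
        groups = {k: rng.normal(i, 1.0, 30) for i, k in enumerate("abc")}
        cmp = compare_methods(groups, reference="a")
        for pair, p in cmp.pairwise_p.items():
            assert cmp.pairwise_p_bonferroni[pair] == pytest.approx(min(1.0, 3 * p))

    def test_default_reference_is_best_method(self, rng):
        cmp = compare_methods(
            {"worse": np.full(30, 0.4), "better": np.full(30, 0.1)}
        )
        assert cmp.reference == "better"

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            compare_methods({"only": np.ones(30)})
        with pytest.raises(ValueError):
            compare_methods({"a": np.ones(30), "b": np.ones(25)})
        with pytest.raises(ValueError):
            compare_methods({"a": np.ones(5), "b": np.ones(5)})
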