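import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import bgoctr
from bgoctr.config import BootstrapSpec
from bgoctr.ctr import (FWHM_FACTOR, bootstrap_ctr, equivalent_ctr_labeled,
                        equivalent_ctr_unlabeled, equivalent_sigma_labeled,
                        equivalent_sigma_unlabeled, evaluate_estimates,
                        fit_double_gaussian, fwhm_fwtm,
                        method_difference_scatter)
from bgoctr.preprocess import CnnExampleSet

from conftest import make_kernel, sample_mixture

GAUSS_FWHM = 2 * np.sqrt(2 * np.log(2))
GAUSS_FWTM = 2 * np.sqrt(2 * np.log(10))


def random_kernel(rng):
    s_c = rng.uniform(20, 200)
    return make_kernel(r_c=rng.uniform(0.01, 0.99), sigma_c=s_c,
                       sigma_s=rng.uniform(s_c, 600),
                       mu=rng.uniform(-100, 100))


def quadrature_sigma_eq(kernel):
    """Independent oracle: adaptive quadrature of the squared kernel."""
    lim = 12 * kernel.sigma_s
    val, _ = quad(lambda x: kernel.density(x) ** 2, kernel.mu - lim,
                  kernel.mu + lim, limit=400, epsabs=0, epsrel=1e-11)
    return 1.0 / (2 * np.sqrt(np.pi) * val)


class TestEquivalentCtr:
    def test_closed_form_matches_quadrature(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = random_kernel(rng)
            closed = equivalent_sigma_unlabeled(k)
            assert closed == pytest.approx(quadrature_sigma_eq(k),
                                           rel=1e-8)

    @pytest.mark.parametrize("sigma", [50.0, 100.0, 300.0])
    def test_gaussian_limit_returns_sigma(self, sigma):
        for k in (make_kernel(1.0, sigma, 400.0),
                  make_kernel(0.0, 30.0, sigma),
                  make_kernel(0.37, sigma, sigma)):
            assert equivalent_sigma_unlabeled(k) == pytest.approx(sigma,
                                                                  abs=1e-9)
            assert equivalent_sigma_labeled(k) == pytest.approx(sigma,
                                                                abs=1e-9)

    def test_worked_example(self):
        k = make_kernel(0.3, 50.0, 200.0)
        assert equivalent_sigma_labeled(k) == \
            pytest.approx(1 / (0.3 / 50 + 0.7 / 200), abs=1e-9)
        assert equivalent_sigma_unlabeled(k) == \
            pytest.approx(quadrature_sigma_eq(k), rel=1e-8)
        assert equivalent_sigma_unlabeled(k) == pytest.approx(140.2, abs=0.5)
        assert equivalent_ctr_labeled(k) == \
            pytest.approx(FWHM_FACTOR * 105.26, abs=0.05)

    def test_labeled_never_exceeds_unlabeled(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            k = random_kernel(rng)
            assert equivalent_sigma_labeled(k) \
                <= equivalent_sigma_unlabeled(k) + 1e-9


class TestWidths:
    @pytest.mark.parametrize("sigma", [40.0, 100.0])
    def test_single_gaussian_closed_forms(self, sigma):
        k = make_kernel(1.0, sigma, 300.0)
        fwhm, fwtm = fwhm_fwtm(k)
        assert fwhm == pytest.approx(GAUSS_FWHM * sigma, abs=0.01)
        assert fwtm == pytest.approx(GAUSS_FWTM * sigma, abs=0.01)

    def test_mixture_width_between_component_widths(self):
        k = make_kernel(0.3, 50.0, 200.0)
        fwhm, fwtm = fwhm_fwtm(k)
        assert GAUSS_FWHM * 50 < fwhm < GAUSS_FWHM * 200
        assert fwtm >= fwhm

    def test_fwtm_at_least_fwhm_random_kernels(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            fwhm, fwtm = fwhm_fwtm(random_kernel(rng))
            assert fwtm >= fwhm


class TestKernelFit:
    def test_single_gaussian_samples(self):
        rng = np.random.default_rng(3)
        x = 100.0 * rng.standard_normal(50_000)
        k = fit_double_gaussian(x)
        fwhm, _ = fwhm_fwtm(k)
        assert fwhm == pytest.approx(GAUSS_FWHM * 100, rel=0.02)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        x = sample_mixture(rng, 100_000, 0.3, 50.0, 200.0)
        k = fit_double_gaussian(x)
        assert abs(k.r_c - 0.3) < 3 * k.param_se["r_c"]
        assert abs(k.sigma_c - 50) < 3 * k.param_se["sigma_c"]
        assert abs(k.sigma_s - 200) < 3 * k.param_se["sigma_s"]

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        x = sample_mixture(rng, 30_000, 0.4, 60.0, 180.0)
        a = fit_double_gaussian(x)
        b = fit_double_gaussian(x + 500.0)
        assert b.mu - a.mu == pytest.approx(500.0, abs=1.0)
        assert b.sigma_c == pytest.approx(a.sigma_c, rel=1e-3)
        assert b.sigma_s == pytest.approx(a.sigma_s, rel=1e-3)

    def test_scale_equivariance_of_metrics(self):
        rng = np.random.default_rng(6)
        x = sample_mixture(rng, 30_000, 0.4, 60.0, 180.0)
        m1, _ = evaluate_estimates(x)
        m2, _ = evaluate_estimates(3.0 * x)
        for key in m1:
            assert m2[key] == pytest.approx(3.0 * m1[key], rel=5e-3)

    def test_width_ordering_convention(self):
        rng = np.random.default_rng(7)
        x = sample_mixture(rng, 20_000, 0.7, 40.0, 160.0)
        k = fit_double_gaussian(x)
        assert k.sigma_c <= k.sigma_s
        assert 0.0 <= k.r_c <= 1.0

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least"):
            fit_double_gaussian(np.zeros(100))


def synthetic_led_records(rng, n, sd=60.0):
    """Gaussian coincidence delays dressed as a timing-record table."""
    t_led = np.sqrt(2) * sd * rng.standard_normal(n)
    records = pd.DataFrame({
        "event_id": np.arange(n), "t_led": t_led,
        "t_rise_l": rng.normal(500, 100, n),
        "t_rise_r": rng.normal(500, 100, n),
    })
    examples = CnnExampleSet(inputs=np.zeros((n, 2, 8), dtype=np.float32),
                             labels=np.zeros(n), t_led=t_led,
                             event_ids=np.arange(n))
    return records, examples


class TestBootstrap:
    def test_single_resample_equals_direct_evaluation(self):
        rng = np.random.default_rng(8)
        records, examples = synthetic_led_records(rng, 4000)
        spec = BootstrapSpec(n_resamples=1, seed=3, fit_min_values=200)
        report = bootstrap_ctr(records, examples, methods=("LED",),
                               bootstrap=spec)
        assert report.n_resamples == 1
        assert report.gains == {}
        for metric, (mean, sd) in report.summary["LED"].items():
            assert sd == 0.0
            assert np.isfinite(mean)

    def test_led_only_no_gain_table(self):
        rng = np.random.default_rng(9)
        records, examples = synthetic_led_records(rng, 3000)
        spec = BootstrapSpec(n_resamples=2, seed=4, fit_min_values=200)
        report = bootstrap_ctr(records, examples, methods=("LED",),
                               bootstrap=spec)
        assert set(report.summary) == {"LED"}
        assert report.gains == {}

    def test_bootstrap_sd_shrinks_with_dataset_size(self):
        """On pure-Gaussian data the bootstrap FWHM sd follows the
        sqrt(n) law: quadrupling the dataset roughly halves it."""
        sds = {}
        for n in (5000, 20000):
            rng = np.random.default_rng(14)
            records, examples = synthetic_led_records(rng, n)
            report = bootstrap_ctr(
                records, examples, methods=("LED",),
                bootstrap=BootstrapSpec(n_resamples=16, seed=15,
                                        fit_min_values=200))
            sds[n] = report.summary["LED"]["ctr_fwhm"][1]
        ratio = sds[5000] / sds[20000]
        assert 2.0 / 1.5 < ratio < 2.0 * 1.5

    def test_misaligned_inputs_rejected(self):
        rng = np.random.default_rng(10)
        records, examples = synthetic_led_records(rng, 1000)
        with pytest.raises(ValueError, match="aligned"):
            bootstrap_ctr(records.iloc[:-5], examples)


class TestDifferenceScatter:
    def test_identical_corrections_on_diagonal(self):
        rng = np.random.default_rng(11)
        led = rng.normal(0, 100, 500)
        twc = led - rng.normal(0, 20, 500)
        df, stats = method_difference_scatter(
            {"LED": led, "TWC": twc, "CNN": twc})
        assert np.allclose(df["led_minus_twc"], df["led_minus_cnn"])
        assert stats["led_minus_twc"]["sd"] == \
            pytest.approx(stats["led_minus_cnn"]["sd"])

    def test_cnn_equal_led_is_point_mass(self):
        rng = np.random.default_rng(12)
        led = rng.normal(0, 100, 500)
        df, stats = method_difference_scatter(
            {"LED": led, "TWC": led - 1.0, "CNN": led})
        assert np.all(df["led_minus_cnn"] == 0.0)
        assert stats["led_minus_cnn"]["sd"] == 0.0

    def test_mismatched_events_rejected(self):
        with pytest.raises(ValueError):
            method_difference_scatter({"LED": np.zeros(10),
                                       "TWC": np.zeros(9),
                                       "CNN": np.zeros(10)})
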