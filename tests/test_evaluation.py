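"""Figures of merit, spike-recovery statistics, marker-band specificity and
pipeline-level guarantees (determinism, no calibration/prediction leakage)."""

import numpy as np
import pytest
from dataclasses import replace

from sersquant import (
    ConfigurationError,
    GeneratorConfig,
    PipelineConfig,
    generate_dataset,
    generate_interferents,
    peak_intensity,
    pearson_r,
    recovery_stats,
    rmse,
    rpd,
    run_pipeline,
)
from conftest import noise_free_config, small_config


class TestMetrics:
    def test_rmse_trivial_and_closed_form(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_rmse_matches_explicit_loop(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=100), rng.normal(size=100)
        total = 0.0
        for x, yv in zip(a, b):
            total += (x - yv) ** 2
        assert rmse(a, b) == pytest.approx(np.sqrt(total / 100), abs=1e-12)

    def test_rmse_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            rmse([], [])

    def test_pearson_r_affine_and_sign(self):
        y = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson_r(y, 2 * y + 1) == pytest.approx(1.0)
        assert pearson_r(y, -y) == pytest.approx(-1.0)

    def test_pearson_r_matches_covariance_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=50), rng.normal(size=50)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pearson_r_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_rpd_is_sd_over_rmsep(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])  # sd (n-1) = 1.2909...
        pred = y + 0.25
        assert rpd(y, pred) == pytest.approx(np.std(y, ddof=1) / 0.25)

    def test_rpd_perfect_prediction_is_infinite(self):
        y = np.array([1.0, 2.0, 3.0])
        with pytest.warns(RuntimeWarning):
            assert rpd(y, y) == np.inf

    def test_rpd_times_rmsep_equals_sd_identity(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        pred = y + rng.normal(0, 0.5, 40)
        assert rpd(y, pred) * rmse(y, pred) == pytest.approx(
            np.std(y, ddof=1), abs=1e-10
        )


class TestRecoveryStats:
    def test_mean_recovery_and_rsd_closed_form(self):
        added = np.array([1.0, 1.0, 1.0])
        predicted = np.array([0.9, 1.0, 1.1])
        (report,) = recovery_stats(added, predicted)
        assert report.recovery_range == (pytest.approx(90.0), pytest.approx(110.0))
        assert report.rsd == pytest.approx(10.0)
        assert np.allclose(report.relative_errors, [-10.0, 0.0, 10.0])

    def test_identical_predictions_give_zero_rsd(self):
        (report,) = recovery_stats([0.5] * 4, [0.47] * 4)
        assert report.rsd == 0.0
        assert report.mean == pytest.approx(0.47)

    def test_small_positive_bias_reports_recovery_above_100(self):
        (report,) = recovery_stats([0.1, 0.1], [0.101, 0.101])
        assert report.recovery_range == (pytest.approx(101.0), pytest.approx(101.0))

    def test_zero_level_is_descriptive_only(self):
        reports = recovery_stats([0.0, 0.0, 1.0, 1.0], [0.01, -0.01, 1.0, 1.1])
        blank = [r for r in reports if r.level == 0.0][0]
        assert blank.recovery_range is None
        assert np.all(np.isnan(blank.relative_errors))

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError, match="2 replicates"):
            recovery_stats([1.0], [1.0])


class TestPeakIntensity:
    def test_lorentzian_height_recovered_on_fine_grid(self):
        wn = np.linspace(1100.0, 1350.0, 2001)
        spectrum = 2.0 * 5.0**2 / ((wn - 1225.0) ** 2 + 5.0**2)
        # the chord at +-50 cm^-1 sits on the Lorentzian tail (~0.02)
        assert peak_intensity(spectrum, wn, 1225.0, window=50.0) == pytest.approx(
            2.0, abs=0.05
        )

    def test_flat_spectrum_gives_zero(self):
        wn = np.linspace(1000.0, 1400.0, 401)
        assert peak_intensity(np.full(401, 7.0), wn, 1225.0) == pytest.approx(0.0)

    def test_window_outside_grid_rejected(self):
        wn = np.linspace(1200.0, 1250.0, 51)
        with pytest.raises(ConfigurationError, match="outside"):
            peak_intensity(np.zeros(51), wn, 1225.0, window=80.0)

    def test_marker_band_specificity_ordering(self):
        # carbendazim at 0.01 mg/L vs five interferents at 10 mg/L: the
        # 1225 cm^-1 intensity of the analyte must exceed every interferent's
        # gain noise scales the (shared) baseline curvature inside the window,
        # which would drown a 0.01 mg/L signal; the comparison is about band
        # positions, so scatter is disabled here
        config = small_config(
            replicates=12, concentrations=(0.01,), noise_sd=0.001,
            background_sd=0.0, sigma_b=0.0,
        )
        analyte = generate_dataset(config)
        others = generate_interferents(config, concentration=10.0)

        def group_mean(spectra, prefix=None):
            rows = (
                [s.startswith(prefix) for s in spectra.sample_ids]
                if prefix
                else slice(None)
            )
            block = spectra.intensities[rows]
            return np.mean(
                [peak_intensity(r, spectra.wavenumbers, 1225.0) for r in block]
            )

        analyte_height = group_mean(analyte)
        for name in ("chlorpyrifos", "thiram", "parathion-methyl", "captan",
                     "isocarbophos", "blank"):
            assert analyte_height > group_mean(others, name)


def _fast_pipeline_config(**overrides):
    generator = small_config(replicates=4, n_points=250)
    defaults = dict(
        generator=generator,
        methods=("lasso",),
        max_components=6,
        cv_folds=5,
        selector_options={"lasso": {"n_lambdas": 30}},
        evaluate_recovery=False,
        seed=5,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


class TestPipeline:
    def test_no_methods_gives_full_spectrum_baseline_only(self):
        result = run_pipeline(_fast_pipeline_config(methods=()))
        assert [r.method for r in result.reports] == ["full-pls"]
        assert result.reports[0].n_selected == 250

    def test_same_config_and_seed_reproduce_reports_exactly(self):
        a = run_pipeline(_fast_pipeline_config())
        b = run_pipeline(_fast_pipeline_config())
        ra, rb = a.reports[0], b.reports[0]
        assert (ra.rmsep, ra.r_p, ra.rpd) == (rb.rmsep, rb.r_p, rb.rpd)
        assert np.array_equal(a.bundles["lasso"].pls.coef, b.bundles["lasso"].pls.coef)

    def test_perturbing_prediction_rows_leaves_fitted_model_unchanged(self):
        config = _fast_pipeline_config()
        base = run_pipeline(config)
        bundle = base.bundles["lasso"]

        from sersquant.evaluation import _stage_seeds

        data = generate_dataset(
            config.generator, seed=_stage_seeds(config.seed, config.methods)["dataset"]
        )
        perturbed = data.intensities.copy()
        perturbed[bundle.split.prediction] += 123.0
        tampered = data.with_intensities(perturbed)

        redo = run_pipeline(config, data=tampered)
        redo_bundle = redo.bundles["lasso"]
        assert np.array_equal(redo_bundle.msc.reference, bundle.msc.reference)
        assert np.array_equal(redo_bundle.selection.selected, bundle.selection.selected)
        assert redo_bundle.n_components == bundle.n_components
        assert np.array_equal(redo_bundle.pls.coef, bundle.pls.coef)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown selection method"):
            PipelineConfig(methods=("pca",))
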