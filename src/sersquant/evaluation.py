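"""Model metrics, spike-recovery statistics and the end-to-end pipeline.

Figures of merit follow standard multivariate-calibration practice:

* RMSEC / RMSEP — root-mean-square error on the calibration / prediction set;
* R_C / R_P — Pearson correlation between reference and predicted
  concentrations on those sets;
* RPD — ratio of the prediction-set reference standard deviation (n−1
  denominator) to RMSEP; RPD > 2 is conventionally usable and RPD > 3 marks
  a good quantitative model;
* spike recovery — 100 · predicted/added per fortified sample, with
  per-level RSD and relative errors.

``run_pipeline`` chains the full analysis: simulate (or load) spectra →
rank-stratified 2:1 split → MSC fitted on the calibration rows only →
per-method wavelength selection on the calibration block → PLS1 with a
CV-chosen component count → prediction-set evaluation → optional
spiked-sample recovery with the BOSS model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    PLSModel,
    SplitResult,
    cross_validate,
    pls_fit,
    pls_predict,
    rank_stratified_split,
)
from .preprocessing import MSCModel, msc_correct, msc_fit
from .selection import (
    BossConfig,
    GaConfig,
    IvissaConfig,
    LassoConfig,
    SelectionResult,
    boss_select,
    cluster_representatives,
    ga_select,
    ivissa_select,
    lasso_select,
)
from .spectra import ConfigurationError, SpectraSet
from .synthetic import GeneratorConfig, generate_dataset, generate_spiked_set

__all__ = [
    "ModelReport",
    "RecoveryReport",
    "ModelBundle",
    "PipelineConfig",
    "PipelineResult",
    "rmse",
    "pearson_r",
    "rpd",
    "recovery_stats",
    "peak_intensity",
    "run_pipeline",
]

logger = logging.getLogger("sersquant")

_SELECTORS = {
    "boss": (boss_select, BossConfig),
    "ga": (ga_select, GaConfig),
    "lasso": (lasso_select, LassoConfig),
    "ivissa": (ivissa_select, IvissaConfig),
}


@dataclass
class ModelReport:
    """One comparison-table row for a fitted calibration model."""

    method: str
    n_components: int
    n_selected: int
    selected_wavelengths: np.ndarray
    r_c: float
    rmsec: float
    r_p: float
    rmsep: float
    rpd: float


@dataclass
class RecoveryReport:
    """Per-spike-level standard-addition statistics."""

    level: float
    mean: float
    sd: float
    recovery_range: tuple[float, float] | None
    rsd: float
    relative_errors: np.ndarray


@dataclass
class ModelBundle:
    """Everything needed to reproduce or apply one fitted pipeline branch."""

    method: str
    split: SplitResult
    msc: MSCModel
    selection: SelectionResult | None
    pls: PLSModel
    n_components: int

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        corrected = msc_correct(self.msc, spectra)
        cols = (
            self.selection.selected
            if self.selection is not None
            else np.arange(spectra.n_points)
        )
        return pls_predict(self.pls, corrected.intensities[:, cols])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error, in the units of y (mg/L)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ConfigurationError("rmse of empty vectors is undefined")
    if y_true.size != y_pred.size:
        raise ConfigurationError("rmse requires equal-length vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson product-moment correlation between two non-constant vectors."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ConfigurationError("pearson_r requires two equal-length vectors, n >= 2")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("pearson_r is undefined for a zero-variance vector")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def rpd(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Ratio of the reference standard deviation (n−1) to the RMSEP.

    Models with RPD above 2 are conventionally considered usable for
    quantitative prediction.  A perfect prediction (RMSEP = 0) is reported
    as +inf with a warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    if np.ptp(y_true) == 0:
        raise ValueError("RPD is undefined for constant reference values")
    sd = float(np.std(y_true, ddof=1))
    err = rmse(y_true, y_pred)
    if err == 0.0:
        warnings.warn("RMSEP is zero; RPD reported as +inf", RuntimeWarning, stacklevel=2)
        return float("inf")
    return sd / err


def recovery_stats(
    added: np.ndarray, predicted: np.ndarray
) -> list[RecoveryReport]:
    """Standard-addition statistics, one report per spike level.

    recovery(%) = 100 · predicted/added per sample; RSD(%) = 100 · sd/mean
    of the replicate predictions at a level; relative error(%) =
    100 · (predicted − added)/added.  A zero-added level is reported
    descriptively (mean ± sd only): recovery is undefined there.
    """
    added = np.asarray(added, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if added.size != predicted.size or added.size == 0:
        raise ConfigurationError("recovery_stats requires equal nonempty vectors")
    reports = []
    for level in np.unique(added):
        preds = predicted[added == level]
        if preds.size < 2:
            raise ConfigurationError(
                f"level {level}: at least 2 replicates are required for an RSD"
            )
        mean = float(preds.mean())
        sd = float(preds.std(ddof=1))
        rsd = 100.0 * sd / abs(mean) if mean != 0 else float("nan")
        if level == 0:
            rec_range = None
            rel = np.full(preds.size, np.nan)
        else:
            recov = 100.0 * preds / level
            rec_range = (float(recov.min()), float(recov.max()))
            rel = 100.0 * (preds - level) / level
        reports.append(
            RecoveryReport(
                level=float(level),
                mean=mean,
                sd=sd,
                recovery_range=rec_range,
                rsd=rsd,
                relative_errors=rel,
            )
        )
    return reports


def peak_intensity(
    spectrum: np.ndarray,
    wavenumbers: np.ndarray,
    center: float,
    window: float = 15.0,
) -> float:
    """Baseline-corrected band intensity around a marker wavenumber.

    The maximum intensity within ``[center − window, center + window]``
    minus the straight line interpolated between the window endpoints —
    a local linear background subtraction.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    step = float(np.diff(wavenumbers).min())
    if window < step:
        raise ConfigurationError(f"window ({window}) must be >= one grid step ({step:g})")
    lo, hi = center - window, center + window
    if lo < wavenumbers[0] or hi > wavenumbers[-1]:
        raise ConfigurationError(
            f"window [{lo}, {hi}] cm^-1 extends outside the grid "
            f"[{wavenumbers[0]}, {wavenumbers[-1]}]"
        )
    inside = (wavenumbers >= lo) & (wavenumbers <= hi)
    y_lo = float(np.interp(lo, wavenumbers, spectrum))
    y_hi = float(np.interp(hi, wavenumbers, spectrum))
    baseline = y_lo + (wavenumbers[inside] - lo) * (y_hi - y_lo) / (hi - lo)
    return float((spectrum[inside] - baseline).max())


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run.

    ``generator`` describes the simulated dataset (ignored when ``data`` is
    passed to :func:`run_pipeline` or ``input_path`` is set); ``methods``
    lists the selectors to run (empty → full-spectrum PLS baseline only).
    The spiked-sample recovery study runs when ``evaluate_recovery`` is on
    and a BOSS model is available.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_path: str | None = None
    methods: tuple[str, ...] = ("ga", "ivissa", "lasso", "boss")
    max_components: int = 15
    cv_folds: int = 10
    selector_options: Mapping[str, Mapping] = field(default_factory=dict)
    evaluate_recovery: bool = True
    spike_levels: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0)
    spike_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in _SELECTORS:
                raise ConfigurationError(
                    f"unknown selection method {m!r}; choose from {sorted(_SELECTORS)}"
                )


@dataclass
class PipelineResult:
    reports: list[ModelReport]
    recovery: list[RecoveryReport]
    bundles: dict[str, ModelBundle]
    seed: int


def _stage_seeds(seed: int, methods: Sequence[str]) -> dict[str, int]:
    """Independent per-stage substreams derived from the run seed.

    Keyed by stage name (not list position), so e.g. the BOSS stream is the
    same whether one or four selectors are configured.
    """
    import zlib

    names = ["dataset", "split", "cv", "spiked"] + [f"select:{m}" for m in methods]
    return {
        name: int(
            np.random.SeedSequence([seed, zlib.crc32(name.encode())])
            .generate_state(1)[0]
            % (2**31)
        )
        for name in names
    }


def _evaluate(
    method: str,
    bundle: ModelBundle,
    corrected_cal: np.ndarray,
    corrected_pred: np.ndarray,
    y_cal: np.ndarray,
    y_pred_ref: np.ndarray,
    wavenumbers: np.ndarray,
) -> ModelReport:
    cols = (
        bundle.selection.selected
        if bundle.selection is not None
        else np.arange(corrected_cal.shape[1])
    )
    fitted = pls_predict(bundle.pls, corrected_cal[:, cols])
    predicted = pls_predict(bundle.pls, corrected_pred[:, cols])
    coef_on_grid = np.zeros(corrected_cal.shape[1])
    coef_on_grid[cols] = bundle.pls.coef
    reps = cluster_representatives(cols, wavenumbers, values=coef_on_grid)
    return ModelReport(
        method=method,
        n_components=bundle.n_components,
        n_selected=cols.size,
        selected_wavelengths=reps,
        r_c=pearson_r(y_cal, fitted),
        rmsec=rmse(y_cal, fitted),
        r_p=pearson_r(y_pred_ref, predicted),
        rmsep=rmse(y_pred_ref, predicted),
        rpd=rpd(y_pred_ref, predicted),
    )


def run_pipeline(
    config: PipelineConfig, data: SpectraSet | None = None
) -> PipelineResult:
    """Execute the full calibration/selection/evaluation pipeline.

    Fully seeded: the run seed is split into independent substreams for
    data generation, splitting, cross-validation, each selector and the
    spiked set, so two runs with the same configuration are identical.
    All fitted quantities (MSC reference, selected variables, component
    counts, PLS coefficients) derive from calibration rows only.
    """
    seeds = _stage_seeds(config.seed, config.methods)

    if data is None:
        if config.input_path is not None:
            from .io import read_spectra

            logger.info("stage=load path=%s", config.input_path)
            data = read_spectra(config.input_path)
        else:
            logger.info("stage=simulate config=%s", config.generator)
            data = generate_dataset(config.generator, seed=seeds["dataset"])

    logger.info("stage=split n=%d seed=%d", data.n_samples, seeds["split"])
    split = rank_stratified_split(data.y, seed=seeds["split"])
    cal = data.subset(split.calibration)
    pred = data.subset(split.prediction)

    logger.info("stage=msc n_cal=%d", cal.n_samples)
    msc = msc_fit(cal)
    corrected_cal = msc_correct(msc, cal).intensities
    corrected_pred = msc_correct(msc, pred).intensities

    bundles: dict[str, ModelBundle] = {}
    reports: list[ModelReport] = []

    def build(method: str, selection: SelectionResult | None) -> ModelBundle:
        cols = (
            selection.selected if selection is not None else np.arange(data.n_points)
        )
        Xsel = corrected_cal[:, cols]
        cv = cross_validate(
            Xsel,
            cal.y,
            max_components=min(config.max_components, cols.size, cal.n_samples - 1),
            folds=config.cv_folds,
            seed=seeds["cv"],
        )
        logger.info(
            "stage=train method=%s n_vars=%d k=%d", method, cols.size, cv.n_components
        )
        pls = pls_fit(Xsel, cal.y, cv.n_components)
        return ModelBundle(
            method=method,
            split=split,
            msc=msc,
            selection=selection,
            pls=pls,
            n_components=cv.n_components,
        )

    if not config.methods:
        bundle = build("full-pls", None)
        bundles["full-pls"] = bundle
        reports.append(
            _evaluate(
                "full-pls", bundle, corrected_cal, corrected_pred,
                cal.y, pred.y, data.wavenumbers,
            )
        )

    for method in config.methods:
        select, config_cls = _SELECTORS[method]
        options = dict(config.selector_options.get(method, {}))
        options.setdefault("seed", seeds[f"select:{method}"])
        sel_config = config_cls(**options)
        logger.info("stage=select method=%s config=%s", method, sel_config)
        selection = select(corrected_cal, cal.y, sel_config)
        bundle = build(method, selection)
        bundles[method] = bundle
        reports.append(
            _evaluate(
                method, bundle, corrected_cal, corrected_pred,
                cal.y, pred.y, data.wavenumbers,
            )
        )

    recovery: list[RecoveryReport] = []
    if config.evaluate_recovery and "boss" in bundles and config.spike_replicates > 1:
        logger.info(
            "stage=recovery levels=%s replicates=%d",
            config.spike_levels, config.spike_replicates,
        )
        spiked = generate_spiked_set(
            config.generator,
            spike_levels=config.spike_levels,
            n_replicates=config.spike_replicates,
            seed=seeds["spiked"],
        )
        predicted = bundles["boss"].predict(spiked)
        recovery = recovery_stats(spiked.y, predicted)

    return PipelineResult(
        reports=reports, recovery=recovery, bundles=bundles, seed=config.seed
    )
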