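"""Multiplicative scatter correction (MSC).

Each spectrum ``x`` is regressed on a reference spectrum ``m`` (the mean
calibration spectrum) over the full wavenumber axis, ``x ~ a + b m``, and
corrected to ``x' = (x - a) / b``.  This separates the physical scatter
contribution (per-sample gain and offset) from the chemical signal, under
the assumption that the reference shape dominates every spectrum.

The reference is always fitted on the calibration set only; prediction-set
and spiked-sample spectra are corrected with the calibration reference so no
information leaks across the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import ConfigurationError, SpectraSet

__all__ = ["MSCModel", "msc_fit", "msc_correct"]

#: Fitted gains with magnitude below this are refused (degenerate samples).
B_MIN = 1e-12


@dataclass
class MSCModel:
    """Reference spectrum plus per-sample fit diagnostics from the last
    correction (offsets ``a`` and gains ``b``)."""

    reference: np.ndarray
    offsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    gains: np.ndarray = field(default_factory=lambda: np.empty(0))


def msc_fit(calibration: SpectraSet) -> MSCModel:
    """Fit the MSC reference: the column-wise mean calibration spectrum.

    At least two calibration spectra are required; with a single spectrum
    the reference would equal that spectrum and the correction degenerates.
    """
    if calibration.n_samples < 2:
        raise ConfigurationError("MSC requires at least 2 calibration spectra")
    return MSCModel(reference=calibration.intensities.mean(axis=0))


def msc_correct(model: MSCModel, X: SpectraSet) -> SpectraSet:
    """Correct every spectrum against the reference.

    For each row the two-parameter least-squares fit ``x ~ a + b m`` is
    solved in closed form and the row is replaced by ``(x - a) / b``.
    Rows whose fitted gain has magnitude below ``B_MIN`` are flagged with a
    warning and returned uncorrected (their diagnostics record ``b`` as
    fitted).  Correcting the reference itself returns the reference.
    """
    m = np.asarray(model.reference, dtype=float)
    if X.n_points != m.size:
        raise ConfigurationError(
            f"grid length {X.n_points} does not match reference length {m.size}"
        )
    Xmat = X.intensities
    m_mean = m.mean()
    m_dev = m - m_mean
    denom = float(m_dev @ m_dev)
    if denom == 0.0:
        raise ConfigurationError("MSC reference is constant; gain is undefined")
    row_means = Xmat.mean(axis=1)
    b = (Xmat - row_means[:, None]) @ m_dev / denom
    a = row_means - b * m_mean

    bad = np.abs(b) < B_MIN
    if np.any(bad):
        warnings.warn(
            f"MSC: refusing correction for {int(bad.sum())} sample(s) with "
            f"|gain| < {B_MIN:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_b = np.where(bad, 1.0, b)
    corrected = (Xmat - a[:, None]) / safe_b[:, None]
    corrected[bad] = Xmat[bad]

    model.offsets = a
    model.gains = b
    return X.with_intensities(corrected)
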