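"""Core in-memory container for spectra tables.

A :class:`SpectraSet` holds an intensity matrix (samples x wavenumbers), the
shared wavenumber axis, per-sample reference concentrations and sample
labels.  It is the object every pipeline stage consumes and produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Invalid generator / model / selection configuration."""


class SpectraParseError(ValueError):
    """Malformed spectra or report file; message names the offending line."""


@dataclass
class SpectraSet:
    """Samples-by-wavenumbers intensity table with reference concentrations.

    Parameters
    ----------
    wavenumbers:
        Strictly increasing axis in cm^-1, length ``n_points``.
    intensities:
        ``(n_samples, n_points)`` array of intensities (arbitrary counts).
    y:
        Reference concentrations in mg/L, one per sample.  ``nan`` marks an
        unknown (unlabelled) sample.
    sample_ids:
        One label per sample.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.wavenumbers.ndim != 1:
            raise ConfigurationError("wavenumbers must be a 1-D vector")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ConfigurationError("wavenumbers must be strictly increasing")
        n, p = self.intensities.shape
        if p != self.wavenumbers.size:
            raise ConfigurationError(
                f"intensity columns ({p}) != wavenumber count ({self.wavenumbers.size})"
            )
        if self.y.size != n:
            raise ConfigurationError(f"y length ({self.y.size}) != sample count ({n})")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ConfigurationError(
                f"sample_ids length ({len(self.sample_ids)}) != sample count ({n})"
            )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def subset(self, rows: np.ndarray) -> "SpectraSet":
        """Row-subset view (copies) preserving axis and labels."""
        rows = np.asarray(rows)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[rows].copy(),
            y=self.y[rows].copy(),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(rows)],
        )

    def with_intensities(self, intensities: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=np.asarray(intensities, dtype=float),
            y=self.y.copy(),
            sample_ids=list(self.sample_ids),
        )
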