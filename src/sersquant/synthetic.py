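"""Seeded synthetic SERS spectrum generation.

The study design this package targets — seven carbendazim levels (0.1, 0.5,
1, 5, 10, 20, 50 mg/L) with 36 replicate spectra each on a 1416-point grid
from 400 to 2500 cm^-1 — is emulated here so every downstream stage (MSC,
splitting, PLS, wavelength selection, recovery statistics) is testable
without access to an instrument.

A spectrum is assembled as::

    x = gain * (response(c) * signature + baseline) + offset + noise

where ``signature`` is a sum of Lorentzian bands at the eight carbendazim
SERS wavenumbers, ``baseline`` is a large common fluorescence-like
polynomial with small per-sample perturbations, ``gain ~ N(1, sigma_b)`` and
``offset ~ N(0, sigma_a)`` model multiplicative/additive scatter, and
``noise`` is iid Gaussian shot-like noise.  The dominant smooth background
is deliberate: raw SERS counts on silver substrates are fluorescence-
dominated, and it is that common background that makes multiplicative
scatter correction against a mean reference well-posed.

Everything is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .spectra import ConfigurationError, SpectraSet

__all__ = [
    "PeakSpec",
    "GeneratorConfig",
    "CARBENDAZIM_PEAKS",
    "DEFAULT_INTERFERENT_LIBRARIES",
    "peak_profile",
    "generate_dataset",
    "generate_interferents",
    "generate_spiked_set",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band: center (cm^-1), HWHM width (cm^-1), relative
    amplitude (> 0) and a free-text vibrational assignment."""

    center: float
    width: float
    rel_amplitude: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError(f"peak width must be > 0, got {self.width}")
        if self.rel_amplitude <= 0:
            raise ConfigurationError(
                f"peak rel_amplitude must be > 0, got {self.rel_amplitude}"
            )


#: Carbendazim SERS band library: the eight major bands with their
#: vibrational assignments.  Widths (HWHM 6 cm^-1) and relative amplitudes
#: are generator choices made only to keep the bands distinguishable.
CARBENDAZIM_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(629.0, 6.0, 1.0, "ring stretching / C-C bending"),
    PeakSpec(736.0, 6.0, 0.8, "C-H bending in benzene ring"),
    PeakSpec(770.0, 6.0, 0.6, "C-H wagging"),
    PeakSpec(1007.0, 6.0, 0.9, "C-N bending / C-C stretch / C-O-CH3 stretching"),
    PeakSpec(1227.0, 6.0, 1.0, "C-C stretch / C-H bending / N-H bending"),
    PeakSpec(1271.0, 6.0, 0.7, "C-H bending / N-H bending"),
    PeakSpec(1462.0, 6.0, 0.6, "N-H bending / C-H bending"),
    PeakSpec(1521.0, 6.0, 0.9, "N-H bending / C-N stretch"),
)

#: Synthetic interferent band libraries (chlorpyrifos, thiram,
#: parathion-methyl, captan, isocarbophos).  The positions are plausible
#: mid-infrared/Raman-range placeholders constructed for the specificity
#: simulation — none lies within the exclusion window around the 1225 cm^-1
#: carbendazim marker band, mirroring the selectivity of the substrate.
DEFAULT_INTERFERENT_LIBRARIES: dict[str, tuple[PeakSpec, ...]] = {
    "chlorpyrifos": (
        PeakSpec(634.0, 7.0, 1.0),
        PeakSpec(678.0, 7.0, 0.7),
        PeakSpec(977.0, 8.0, 0.8),
        PeakSpec(1090.0, 8.0, 0.6),
        PeakSpec(1575.0, 8.0, 0.5),
    ),
    "thiram": (
        PeakSpec(560.0, 7.0, 0.9),
        PeakSpec(1146.0, 8.0, 0.8),
        PeakSpec(1386.0, 8.0, 1.0),
        PeakSpec(1512.0, 7.0, 0.6),
    ),
    "parathion-methyl": (
        PeakSpec(858.0, 8.0, 0.9),
        PeakSpec(1110.0, 8.0, 0.7),
        PeakSpec(1346.0, 8.0, 1.0),
        PeakSpec(1593.0, 8.0, 0.8),
    ),
    "captan": (
        PeakSpec(738.0, 7.0, 0.8),
        PeakSpec(1120.0, 8.0, 0.6),
        PeakSpec(1302.0, 8.0, 0.9),
        PeakSpec(1577.0, 8.0, 0.5),
    ),
    "isocarbophos": (
        PeakSpec(652.0, 7.0, 0.7),
        PeakSpec(920.0, 8.0, 0.8),
        PeakSpec(1155.0, 8.0, 0.6),
        PeakSpec(1440.0, 8.0, 0.9),
    ),
}


@dataclass
class GeneratorConfig:
    """Full description of a synthetic calibration experiment.

    Defaults reproduce the study design: 7 levels x 36 replicates = 252
    spectra, 1416 points over 400-2500 cm^-1, the eight-band carbendazim
    signature, a linear intensity-concentration response, a dominant smooth
    background with per-sample perturbation, multiplicative/additive
    scatter and additive noise.  Noise magnitudes are the documented
    defaults that place the default pipeline in the published performance
    regime (prediction-set correlation >= 0.98).
    """

    grid_min: float = 400.0
    grid_max: float = 2500.0
    n_points: int = 1416
    concentrations: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0, 20.0, 50.0)
    replicates: int = 36
    peaks: tuple[PeakSpec, ...] = CARBENDAZIM_PEAKS
    response: str = "linear"  # "linear" | "langmuir"
    c_sat: float = 100.0  # Langmuir saturation constant, mg/L
    baseline_degree: int = 2
    # The default curved fluorescence background is chosen with (numerically)
    # zero covariance against the eight-band analyte signature, so the MSC
    # gain fit does not fold the signature into the corrected background.
    baseline_mean: tuple[float, ...] = (50000.0, -12725.0, 42635.0)
    baseline_scale: float = 0.0  # per-sample polynomial jitter (texture is the default randomness)
    background_sd: float = 0.003  # smooth background-texture sd
    background_corr_length: float = 25.0  # texture correlation length, grid steps
    sigma_b: float = 0.08  # per-spectrum gain sd
    sigma_a: float = 2.0  # per-spectrum offset sd
    noise_sd: float = 0.005  # additive channel noise sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ConfigurationError("n_points must be >= 2")
        if self.grid_max <= self.grid_min:
            raise ConfigurationError("grid_max must exceed grid_min")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc <= 0):
            raise ConfigurationError("concentrations must be strictly positive")
        if np.unique(conc).size != conc.size:
            raise ConfigurationError("concentrations must be distinct")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not (0 <= self.sigma_b < 1):
            raise ConfigurationError("sigma_b must lie in [0, 1) so gains stay positive")
        if self.response not in ("linear", "langmuir"):
            raise ConfigurationError(f"unknown response model {self.response!r}")
        if self.response == "langmuir" and self.c_sat <= 0:
            raise ConfigurationError("c_sat must be > 0")
        if self.baseline_degree < 0:
            raise ConfigurationError("baseline_degree must be >= 0")
        mean = tuple(float(c) for c in self.baseline_mean)
        if len(mean) < self.baseline_degree + 1:
            mean = mean + (0.0,) * (self.baseline_degree + 1 - len(mean))
        self.baseline_mean = mean[: self.baseline_degree + 1]
        self.peaks = tuple(
            p if isinstance(p, PeakSpec) else PeakSpec(**p) for p in self.peaks
        )

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_points)

    def response_value(self, c: np.ndarray | float) -> np.ndarray | float:
        """Band intensity per unit relative amplitude at concentration c."""
        c = np.asarray(c, dtype=float)
        if self.response == "langmuir":
            return c / (1.0 + c / self.c_sat)
        return c

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peaks"] = [asdict(p) for p in self.peaks]
        d["concentrations"] = list(self.concentrations)
        d["baseline_mean"] = list(self.baseline_mean)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "peaks" in d:
            d["peaks"] = tuple(
                p if isinstance(p, PeakSpec) else PeakSpec(**p) for p in d["peaks"]
            )
        for key in ("concentrations", "baseline_mean"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def peak_profile(peaks: Sequence[PeakSpec], wavenumbers: np.ndarray) -> np.ndarray:
    """Noise-free unit-concentration signature: a sum of Lorentzians.

    Each band contributes ``A * w^2 / ((nu - c)^2 + w^2)`` so its value at
    its own center equals its amplitude (neighbouring bands only add).
    An empty peak list yields the zero vector.  A band center outside the
    grid range is a configuration error.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if wavenumbers.ndim != 1 or np.any(np.diff(wavenumbers) <= 0):
        raise ConfigurationError("wavenumbers must be a strictly increasing vector")
    profile = np.zeros_like(wavenumbers)
    lo, hi = wavenumbers[0], wavenumbers[-1]
    for peak in peaks:
        if not (lo <= peak.center <= hi):
            raise ConfigurationError(
                f"peak center {peak.center} cm^-1 outside grid [{lo}, {hi}]"
            )
        w2 = peak.width**2
        profile += peak.rel_amplitude * w2 / ((wavenumbers - peak.center) ** 2 + w2)
    return profile


def _chebyshev_axis(wavenumbers: np.ndarray) -> np.ndarray:
    lo, hi = wavenumbers[0], wavenumbers[-1]
    return 2.0 * (wavenumbers - lo) / (hi - lo) - 1.0


def _baselines(
    config: GeneratorConfig, u: np.ndarray, rng: np.random.Generator, n: int
) -> np.ndarray:
    """n random low-order polynomial baselines: common mean + perturbation."""
    coeffs = np.asarray(config.baseline_mean) + rng.normal(
        0.0, config.baseline_scale, size=(n, config.baseline_degree + 1)
    )
    powers = u[None, :] ** np.arange(config.baseline_degree + 1)[:, None]
    return coeffs @ powers


def _background_texture(
    config: GeneratorConfig, rng: np.random.Generator, n: int, p: int
) -> np.ndarray:
    """Smooth per-sample background fluctuations.

    White noise convolved with a Gaussian kernel of the configured
    correlation length (grid steps) and rescaled to ``background_sd`` per
    channel.  This models the many-degree-of-freedom sample-to-sample
    texture of real fluorescence backgrounds — the feature that makes
    off-band channels uninformative for the analyte.
    """
    if config.background_sd == 0.0 or n == 0:
        return np.zeros((n, p))
    ell = max(config.background_corr_length, 1e-6)
    half = int(np.ceil(4 * ell))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / ell) ** 2)
    kernel /= kernel.sum()
    white = rng.normal(0.0, 1.0, size=(n, p))
    from scipy.ndimage import convolve1d

    smooth = convolve1d(white, kernel, axis=1, mode="reflect")
    return (config.background_sd / np.sqrt(kernel @ kernel)) * smooth


def _assemble(
    config: GeneratorConfig,
    concentrations_per_row: np.ndarray,
    rng: np.random.Generator,
    signature: np.ndarray | None = None,
    extra_background: np.ndarray | None = None,
) -> np.ndarray:
    """Draws, in fixed order, gains / offsets / baselines / noise and builds
    the intensity matrix for one row-block."""
    wn = config.wavenumbers
    if signature is None:
        signature = peak_profile(config.peaks, wn)
    n = concentrations_per_row.size
    u = _chebyshev_axis(wn)
    gains = rng.normal(1.0, config.sigma_b, size=n)
    offsets = rng.normal(0.0, config.sigma_a, size=n)
    baselines = _baselines(config, u, rng, n)
    texture = _background_texture(config, rng, n, wn.size)
    noise = rng.normal(0.0, config.noise_sd, size=(n, wn.size))
    resp = np.asarray(config.response_value(concentrations_per_row))
    clean = resp[:, None] * signature[None, :] + baselines + texture
    if extra_background is not None:
        clean = clean + extra_background
    return gains[:, None] * clean + offsets[:, None] + noise


def generate_dataset(config: GeneratorConfig, seed: int | None = None) -> SpectraSet:
    """Generate the full calibration experiment.

    Returns ``replicates * len(concentrations)`` spectra ordered
    level-major (all replicates of the lowest level first).  Bit-identical
    for a given configuration and seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    conc = np.repeat(np.asarray(config.concentrations, dtype=float), config.replicates)
    intensities = _assemble(config, conc, rng)
    ids = [
        f"c{c:g}_r{r:02d}"
        for c in config.concentrations
        for r in range(config.replicates)
    ]
    return SpectraSet(config.wavenumbers, intensities, conc, ids)


def generate_interferents(
    config: GeneratorConfig,
    names: Sequence[str] | None = None,
    shift_scheme: Mapping[str, float] | None = None,
    libraries: Mapping[str, Sequence[PeakSpec]] | None = None,
    concentration: float = 10.0,
    amplitude_scale: float = 0.1,
    exclusion_center: float = 1225.0,
    exclusion_halfwidth: float = 15.0,
    seed: int | None = None,
) -> SpectraSet:
    """Spectra of non-analyte pesticides plus a blank, for specificity tests.

    Each interferent carries its own band library, optionally rigidly
    shifted via ``shift_scheme``.  A library with any band center inside the
    exclusion window around the analyte marker band (default 1225 +/- 15
    cm^-1) is rejected.  ``amplitude_scale`` (< 1) models the weak hotspot
    affinity of non-target molecules — the physical basis of the substrate's
    selectivity.  The reference concentration ``y`` is 0 for every row (no
    analyte present); group membership is encoded in the sample ids.
    """
    if names is None:
        names = list(DEFAULT_INTERFERENT_LIBRARIES)
    libraries = dict(libraries or DEFAULT_INTERFERENT_LIBRARIES)
    shift_scheme = dict(shift_scheme or {})
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wn = config.wavenumbers

    blocks: list[np.ndarray] = []
    ids: list[str] = []
    for name in list(names) + ["blank"]:
        if name == "blank":
            peaks: tuple[PeakSpec, ...] = ()
        else:
            if name not in libraries:
                raise ConfigurationError(f"no band library for interferent {name!r}")
            shift = shift_scheme.get(name, 0.0)
            peaks = tuple(
                PeakSpec(p.center + shift, p.width, p.rel_amplitude, p.assignment)
                for p in libraries[name]
            )
            for p in peaks:
                if abs(p.center - exclusion_center) <= exclusion_halfwidth:
                    raise ConfigurationError(
                        f"{name}: band at {p.center} cm^-1 violates the "
                        f"{exclusion_center} +/- {exclusion_halfwidth} cm^-1 "
                        "exclusion window"
                    )
        signature = amplitude_scale * peak_profile(peaks, wn)
        conc = np.full(config.replicates, concentration if peaks else 0.0)
        blocks.append(_assemble(config, conc, rng, signature=signature))
        ids.extend(f"{name}_r{r:02d}" for r in range(config.replicates))
    intensities = np.vstack(blocks)
    return SpectraSet(wn, intensities, np.zeros(intensities.shape[0]), ids)


#: Spiked-sample matrix background: an elevated smooth baseline plus weak
#: broad co-extractive bands.  Band amplitudes are small relative to the
#: analyte signature because non-adsorbed matrix compounds see none of the
#: plasmonic enhancement.
MATRIX_ELEVATION_MEAN = 0.01  # fluorescence elevation, fraction of the mean baseline
MATRIX_ELEVATION_SD = 0.005
MATRIX_BANDS: tuple[tuple[float, float, float], ...] = (
    (880.0, 70.0, 0.005),
    (1330.0, 90.0, 0.004),
    (1650.0, 80.0, 0.005),
)
MATRIX_BAND_JITTER = 0.002


def generate_spiked_set(
    config: GeneratorConfig,
    spike_levels: Sequence[float] = (0.1, 0.5, 1.0, 5.0, 10.0),
    n_replicates: int = 10,
    matrix_background: bool = True,
    seed: int | None = None,
) -> SpectraSet:
    """Fortified-sample spectra for standard-addition recovery evaluation.

    Each spike level receives ``n_replicates`` spectra built like the
    calibration spectra but with an added matrix-background component
    (elevated baseline plus weak broad bands) distinct from the calibration
    background.  ``y`` is set to the spike level.  With the matrix
    background disabled and all randomness zeroed a spiked spectrum equals
    the calibration signature at the same concentration.
    """
    levels = np.asarray(spike_levels, dtype=float)
    lo, hi = min(config.concentrations), max(config.concentrations)
    if np.any((levels < lo) | (levels > hi)):
        raise ConfigurationError(
            f"spike levels must lie within the calibrated range [{lo}, {hi}] mg/L"
        )
    if n_replicates < 0:
        raise ConfigurationError("n_replicates must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wn = config.wavenumbers
    n = n_replicates * levels.size
    conc = np.repeat(levels, n_replicates)

    extra = None
    if matrix_background and n > 0:
        u = _chebyshev_axis(wn)
        # fruit-extract fluorescence: a gain-like elevation of the common
        # baseline shape, plus weak broad co-extractive bands (non-adsorbed
        # matrix compounds see no plasmonic enhancement)
        scales = rng.normal(MATRIX_ELEVATION_MEAN, MATRIX_ELEVATION_SD, size=n)
        powers = u[None, :] ** np.arange(len(config.baseline_mean))[:, None]
        shape = np.asarray(config.baseline_mean) @ powers
        extra = scales[:, None] * shape[None, :]
        for center, width, amp in MATRIX_BANDS:
            amps = amp + rng.normal(0.0, MATRIX_BAND_JITTER, size=n)
            band = width**2 / ((wn - center) ** 2 + width**2)
            extra += amps[:, None] * band[None, :]

    intensities = (
        _assemble(config, conc, rng, extra_background=extra)
        if n > 0
        else np.empty((0, wn.size))
    )
    ids = [f"spike{c:g}_r{r:02d}" for c in levels for r in range(n_replicates)]
    return SpectraSet(wn, intensities, conc, ids)
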