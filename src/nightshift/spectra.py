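"""Synthetic photometry of outdoor lighting spectra.

Everything downstream of a lamp — camera band signals, B/G and G/R color
ratios, and biologically weighted indices such as the melatonin suppression
index (MSI) — reduces to integrals of a spectral power distribution (SPD)
against a sensitivity or action curve.  This module holds those primitives.

Conventions
-----------
* Wavelengths in nanometres, sampled on monotonically increasing grids.
* SPD power is spectral radiance per nm in relative units; absolute scale
  carries no meaning for ratios or indices (both are scale-invariant).
* Sensitivity and action curves are peak-normalized to 1.
* A curve is treated as zero outside its sampled support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "DEFAULT_WAVELENGTH_GRID",
    "SpectralPowerDistribution",
    "Band",
    "CameraResponse",
    "ActionSpectrum",
    "ColorRatios",
    "band_signal",
    "color_ratios",
    "spectral_index",
    "mix_spds",
    "gaussian_curve",
    "melatonin_suppression_action",
    "photopic_response",
    "scotopic_starlight_action",
    "phototaxis_action",
    "d65_like_reference",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

#: 380-780 nm at 1 nm: fine enough to resolve gas-discharge emission lines.
DEFAULT_WAVELENGTH_GRID = np.arange(380.0, 781.0, 1.0)


def _validate_curve(wavelength_nm: np.ndarray, values: np.ndarray, what: str) -> None:
    if wavelength_nm.ndim != 1 or values.ndim != 1:
        raise ValueError(f"{what}: wavelength and values must be 1-D")
    if wavelength_nm.shape != values.shape:
        raise ValueError(f"{what}: wavelength and values must have equal length")
    if wavelength_nm.size < 2:
        raise ValueError(f"{what}: need at least 2 samples")
    if not np.all(np.diff(wavelength_nm) > 0):
        raise ValueError(f"{what}: wavelength grid must be strictly increasing")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: values must be finite")
    if np.any(values < 0):
        raise ValueError(f"{what}: values must be nonnegative")


class SpectralPowerDistribution:
    """Wavelength-sampled emission spectrum of a lamp or lamp mixture."""

    __slots__ = ("wavelength_nm", "power", "name")

    def __init__(self, wavelength_nm, power, name: str = ""):
        w = np.ascontiguousarray(wavelength_nm, dtype=float)
        p = np.ascontiguousarray(power, dtype=float)
        _validate_curve(w, p, "SpectralPowerDistribution")
        self.wavelength_nm = w
        self.power = p
        self.name = name

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"SpectralPowerDistribution({self.name!r}, "
            f"{self.wavelength_nm[0]:g}-{self.wavelength_nm[-1]:g} nm, "
            f"n={self.wavelength_nm.size})"
        )

    def resample(self, grid: np.ndarray) -> "SpectralPowerDistribution":
        """Linear resample onto *grid*; zero outside the original support."""
        grid = np.asarray(grid, dtype=float)
        p = np.interp(grid, self.wavelength_nm, self.power, left=0.0, right=0.0)
        return SpectralPowerDistribution(grid, p, self.name)

    def total_power(self) -> float:
        """Bolometric (band-unlimited) integral of the sampled spectrum."""
        return float(np.trapezoid(self.power, self.wavelength_nm))

    def scaled(self, k: float) -> "SpectralPowerDistribution":
        if k < 0:
            raise ValueError("scale factor must be nonnegative")
        return SpectralPowerDistribution(self.wavelength_nm, self.power * k, self.name)

    def normalized(self) -> "SpectralPowerDistribution":
        """Rescale to unit total power."""
        tot = self.total_power()
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return self.scaled(1.0 / tot)


def mix_spds(
    spds: list[SpectralPowerDistribution],
    weights,
    grid: np.ndarray | None = None,
    name: str = "mixture",
) -> SpectralPowerDistribution:
    """Nonnegative linear combination of spectra on a common grid."""
    weights = np.asarray(weights, dtype=float)
    if len(spds) != weights.size:
        raise ValueError("one weight per spectrum required")
    if np.any(weights < 0):
        raise ValueError("mixture weights must be nonnegative")
    if grid is None:
        grid = DEFAULT_WAVELENGTH_GRID
    power = np.zeros_like(grid, dtype=float)
    for spd, w in zip(spds, weights):
        power += w * spd.resample(grid).power
    return SpectralPowerDistribution(grid, power, name)


@dataclass(frozen=True)
class Band:
    """One sensor channel: a named, peak-normalized sensitivity curve."""

    name: str
    wavelength_nm: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self):
        w = np.ascontiguousarray(self.wavelength_nm, dtype=float)
        s = np.ascontiguousarray(self.sensitivity, dtype=float)
        _validate_curve(w, s, f"Band {self.name!r}")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "sensitivity", s)

    @property
    def peak_wavelength(self) -> float:
        return float(self.wavelength_nm[int(np.argmax(self.sensitivity))])


def gaussian_curve(
    mean_nm: float,
    sigma_nm: float,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-normalized Gaussian on *grid* (default 380-780 nm)."""
    if grid is None:
        grid = DEFAULT_WAVELENGTH_GRID
    g = np.exp(-0.5 * ((grid - mean_nm) / sigma_nm) ** 2)
    return np.asarray(grid, dtype=float), g


class CameraResponse:
    """Three-channel (R, G, B) camera sensitivity model.

    Channel curves are peak-normalized on construction and must peak in
    wavelength order blue < green < red.  The defaults are Gaussian
    approximations of a DSLR's Bayer filters (B 460/30 nm, G 530/30 nm,
    R 600/40 nm); measured curves can be loaded from CSV and substituted —
    all the ratio-based math downstream is curve-agnostic.
    """

    def __init__(self, wavelength_nm, red, green, blue, name: str = "gaussian-dslr"):
        w = np.ascontiguousarray(wavelength_nm, dtype=float)
        bands = {}
        for ch, values in (("red", red), ("green", green), ("blue", blue)):
            v = np.ascontiguousarray(values, dtype=float)
            _validate_curve(w, v, f"CameraResponse {ch}")
            peak = v.max()
            if peak <= 0:
                raise ValueError(f"CameraResponse {ch}: all-zero sensitivity")
            bands[ch] = Band(ch, w, v / peak)
        peaks = [bands[c].peak_wavelength for c in ("blue", "green", "red")]
        if not (peaks[0] < peaks[1] < peaks[2]):
            raise ValueError(
                f"channel peaks must be ordered blue < green < red, got {peaks}"
            )
        self.wavelength_nm = w
        self._bands = bands
        self.name = name

    @classmethod
    def default(cls) -> "CameraResponse":
        grid = DEFAULT_WAVELENGTH_GRID
        _, b = gaussian_curve(460.0, 30.0, grid)
        _, g = gaussian_curve(530.0, 30.0, grid)
        _, r = gaussian_curve(600.0, 40.0, grid)
        return cls(grid, r, g, b)

    @classmethod
    def from_csv(cls, red_path, green_path, blue_path, name="csv-camera"):
        wr, r = read_spectrum_csv(red_path)
        wg, g = read_spectrum_csv(green_path)
        wb, b = read_spectrum_csv(blue_path)
        grid = np.union1d(np.union1d(wr, wg), wb)
        interp = lambda w, v: np.interp(grid, w, v, left=0.0, right=0.0)
        return cls(grid, interp(wr, r), interp(wg, g), interp(wb, b), name=name)

    def band(self, channel: str) -> Band:
        key = {"r": "red", "g": "green", "b": "blue"}.get(channel.lower(), channel.lower())
        if key not in self._bands:
            raise KeyError(f"unknown channel {channel!r}")
        return self._bands[key]

    @property
    def bands(self) -> tuple[Band, Band, Band]:
        """(red, green, blue) in that order, matching raster band order."""
        return (self._bands["red"], self._bands["green"], self._bands["blue"])


@dataclass(frozen=True)
class ActionSpectrum:
    """Biological/perceptual weighting curve, peak-normalized.

    ``name`` identifies the response: melatonin_suppression, photopic,
    scotopic_starlight, or phototaxis.
    """

    name: str
    wavelength_nm: np.ndarray
    weight: np.ndarray

    KNOWN = ("melatonin_suppression", "photopic", "scotopic_starlight", "phototaxis")

    def __post_init__(self):
        w = np.ascontiguousarray(self.wavelength_nm, dtype=float)
        v = np.ascontiguousarray(self.weight, dtype=float)
        _validate_curve(w, v, f"ActionSpectrum {self.name!r}")
        if w[0] < 300.0 or w[-1] > 800.0:
            raise ValueError("action spectrum support must lie within 300-800 nm")
        peak = v.max()
        if peak <= 0:
            raise ValueError("action spectrum cannot be all zero")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "weight", v / peak)

    @classmethod
    def from_csv(cls, path, name: str) -> "ActionSpectrum":
        w, v = read_spectrum_csv(path)
        return cls(name, w, v)


def melatonin_suppression_action() -> ActionSpectrum:
    """Melatonin-suppression action spectrum (analytic approximation).

    Gaussian at 460/40 nm approximating the published human nocturnal
    melatonin suppression curve, which peaks in the blue.
    """
    w, v = gaussian_curve(460.0, 40.0)
    return ActionSpectrum("melatonin_suppression", w, v)


def photopic_response() -> ActionSpectrum:
    """Photopic luminous efficiency (Gaussian 555/45 nm approximation)."""
    w, v = gaussian_curve(555.0, 45.0)
    return ActionSpectrum("photopic", w, v)


def scotopic_starlight_action() -> ActionSpectrum:
    """Blue-weighted scotopic curve used for the star light index (SLI).

    Gaussian 507/45 nm approximating the scotopic response; short
    wavelengths scatter more in the atmosphere, so blue-rich sources
    degrade star visibility disproportionately.
    """
    w, v = gaussian_curve(507.0, 45.0)
    return ActionSpectrum("scotopic_starlight", w, v)


def phototaxis_action() -> ActionSpectrum:
    """Insect (moth) phototaxis curve: strongly short-wavelength weighted."""
    w, v = gaussian_curve(400.0, 60.0)
    return ActionSpectrum("phototaxis", w, v)


def d65_like_reference(grid: np.ndarray | None = None) -> SpectralPowerDistribution:
    """Broad daylight-like reference illuminant (6500 K Planckian).

    Used to anchor spectral indices so that index(reference) == 1.
    """
    if grid is None:
        grid = DEFAULT_WAVELENGTH_GRID
    lam_m = np.asarray(grid, dtype=float) * 1e-9
    h, c, kb, temp = 6.62607015e-34, 2.99792458e8, 1.380649e-23, 6500.0
    planck = (2 * h * c**2 / lam_m**5) / np.expm1(h * c / (lam_m * kb * temp))
    planck /= planck.max()
    return SpectralPowerDistribution(grid, planck, "d65-like")


class ColorRatios(NamedTuple):
    b_over_g: float
    g_over_r: float
    r_over_g: float


def _overlap_grid(w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    lo = max(w1[0], w2[0])
    hi = min(w1[-1], w2[-1])
    if lo >= hi:
        raise ValueError(
            f"wavelength supports do not overlap: [{w1[0]:g},{w1[-1]:g}] vs "
            f"[{w2[0]:g},{w2[-1]:g}] nm"
        )
    merged = np.union1d(w1, w2)
    return merged[(merged >= lo) & (merged <= hi)]


def band_signal(spd: SpectralPowerDistribution, band: Band | ActionSpectrum) -> float:
    """Trapezoidal integral of spd power x band sensitivity over the overlap.

    Raises ``ValueError`` when the wavelength supports are disjoint.
    """
    if isinstance(band, ActionSpectrum):
        bw, bs = band.wavelength_nm, band.weight
    else:
        bw, bs = band.wavelength_nm, band.sensitivity
    grid = _overlap_grid(spd.wavelength_nm, bw)
    p = np.interp(grid, spd.wavelength_nm, spd.power, left=0.0, right=0.0)
    s = np.interp(grid, bw, bs, left=0.0, right=0.0)
    return float(np.trapezoid(p * s, grid))


def color_ratios(spd: SpectralPowerDistribution, camera: CameraResponse) -> ColorRatios:
    """B/G, G/R and R/G band-signal ratios of a spectrum.

    Zero-signal denominators yield NaN, which propagates as a masked value
    downstream.
    """
    r = band_signal(spd, camera.band("red"))
    g = band_signal(spd, camera.band("green"))
    b = band_signal(spd, camera.band("blue"))
    if not all(np.isfinite([r, g, b])):
        raise ValueError("non-finite band signal")
    b_over_g = b / g if g > 0 else float("nan")
    g_over_r = g / r if r > 0 else float("nan")
    r_over_g = r / g if g > 0 else float("nan")
    return ColorRatios(b_over_g, g_over_r, r_over_g)


def spectral_index(
    spd: SpectralPowerDistribution,
    action: ActionSpectrum,
    reference: SpectralPowerDistribution | None = None,
    photopic: ActionSpectrum | None = None,
) -> float:
    """Photopically normalized action-weighted index, anchored to a reference.

    index = (int spd*action / int spd*photopic)
          / (int ref*action / int ref*photopic)

    so that index(reference) == 1 by construction.  A spectrum with zero
    photopic content has an undefined index (NaN).
    """
    if reference is None:
        reference = d65_like_reference()
    if photopic is None:
        photopic = photopic_response()
    num = band_signal(spd, action)
    den = band_signal(spd, photopic)
    ref_num = band_signal(reference, action)
    ref_den = band_signal(reference, photopic)
    if ref_den <= 0 or ref_num <= 0:
        raise ValueError("reference illuminant has no overlap with the action/photopic curves")
    if den <= 0:
        return float("nan")
    return (num / den) / (ref_num / ref_den)


def read_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 2-column (wavelength_nm, value) CSV with a header line."""
    arr = np.genfromtxt(path, delimiter=",", skip_header=1, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: expected a 2-column CSV with header")
    return arr[:, 0], arr[:, 1]


def write_spectrum_csv(path, wavelength_nm, values, header="wavelength_nm,value"):
    arr = np.column_stack([np.asarray(wavelength_nm), np.asarray(values)])
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
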