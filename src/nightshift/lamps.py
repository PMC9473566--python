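"""Modeled street-lamp spectrum library and VIIRS-band photometry.

The library covers the technologies that dominate(d) European street
lighting: low/high-pressure sodium, mercury vapor, metal halide,
triphosphor fluorescent, and white LEDs at 3000/4000 K.  Class spectra are
parametric (line lists plus Gaussian continua, parameters in
``data/lamp_library.json``) and normalized to unit total power, so a
pixel's bolometric emission scale multiplies a convex mixture of classes.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .spectra import (
    DEFAULT_WAVELENGTH_GRID,
    Band,
    CameraResponse,
    SpectralPowerDistribution,
    band_signal,
    mix_spds,
)

__all__ = [
    "LAMP_CLASSES",
    "load_lamp_library",
    "viirs_band",
    "viirs_signal",
    "lamp_band_matrix",
    "lamp_viirs_vector",
    "mixture_library",
]

#: Canonical class order used by mixture-weight rasters everywhere.
LAMP_CLASSES = (
    "lps",
    "hps",
    "mercury",
    "metal_halide",
    "fluorescent",
    "led_3000k",
    "led_4000k",
)

#: Classes counted as "sodium" for the epoch-shift conversion.
SODIUM_CLASSES = ("lps", "hps")


def _build_class_spd(params: dict, grid: np.ndarray, name: str) -> SpectralPowerDistribution:
    power = np.zeros_like(grid)
    for center, amp, sigma in params.get("lines", []) + params.get("continua", []):
        power += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return SpectralPowerDistribution(grid, power, name).normalized()


def load_lamp_library(grid: np.ndarray | None = None) -> dict[str, SpectralPowerDistribution]:
    """Lamp class name -> unit-total-power SPD on *grid*."""
    if grid is None:
        grid = DEFAULT_WAVELENGTH_GRID
    raw = json.loads(
        resources.files("nightshift.data").joinpath("lamp_library.json").read_text()
    )
    return {name: _build_class_spd(p, grid, name) for name, p in raw["classes"].items()}


def viirs_band(grid: np.ndarray | None = None) -> Band:
    """Panchromatic day/night-band sensitivity: 480-920 nm boxcar.

    The satellite band is blind below 480 nm, which is exactly why blue-rich
    LED emissions are under-measured by it.
    """
    if grid is None:
        grid = np.arange(380.0, 921.0, 1.0)
    sens = ((grid >= 480.0) & (grid <= 920.0)).astype(float)
    return Band("viirs_dnb", np.asarray(grid, dtype=float), sens)


def viirs_signal(spd: SpectralPowerDistribution) -> float:
    """In-band (480-920 nm) power of a spectrum."""
    return band_signal(spd, viirs_band())


def lamp_band_matrix(
    camera: CameraResponse,
    classes: tuple[str, ...] = LAMP_CLASSES,
    library: dict[str, SpectralPowerDistribution] | None = None,
) -> np.ndarray:
    """(3, n_classes) matrix of per-unit-power band signals, rows R, G, B.

    Rendering a scene then reduces to a tensor contraction of this matrix
    with the per-pixel mixture weights.
    """
    if library is None:
        library = load_lamp_library()
    out = np.empty((3, len(classes)))
    for j, cls in enumerate(classes):
        spd = library[cls]
        for i, ch in enumerate(("red", "green", "blue")):
            out[i, j] = band_signal(spd, camera.band(ch))
    return out


def lamp_viirs_vector(
    classes: tuple[str, ...] = LAMP_CLASSES,
    library: dict[str, SpectralPowerDistribution] | None = None,
) -> np.ndarray:
    """(n_classes,) in-band VIIRS fraction per unit total power."""
    if library is None:
        library = load_lamp_library()
    return np.array([viirs_signal(library[cls]) for cls in classes])


def mixture_library(
    n_random: int = 0,
    seed: int = 0,
    library: dict[str, SpectralPowerDistribution] | None = None,
) -> list[SpectralPowerDistribution]:
    """Pure classes plus all pairwise 50/50 mixtures (plus optional random
    mixtures) — the sample over which ratio-index relationships are fitted.

    With the 7 shipped classes this yields 7 + 21 = 28 spectra.
    """
    if library is None:
        library = load_lamp_library()
    spds = [library[c] for c in LAMP_CLASSES]
    out = list(spds)
    for i in range(len(spds)):
        for j in range(i + 1, len(spds)):
            out.append(
                mix_spds(
                    [spds[i], spds[j]],
                    [0.5, 0.5],
                    name=f"{LAMP_CLASSES[i]}+{LAMP_CLASSES[j]}",
                )
            )
    if n_random > 0:
        rng = np.random.default_rng(seed)
        for k in range(n_random):
            w = rng.dirichlet(np.ones(len(spds)))
            out.append(mix_spds(spds, w, name=f"random_{k}"))
    return out
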