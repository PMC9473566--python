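"""Color-ratio grids and the outlier / satellite-threshold masks.

B/G and G/R ratios are the per-pixel spectral proxies the whole analysis
runs on.  Low signal-to-noise pixels are removed by the ratio-diagram
outlier rule (B/G > 1.2 or G/R > 1.2 or R/G > 6) and by masking pixels
below 0.5 nW cm^-2 sr^-1 in the panchromatic satellite composite, where
natural skyglow dominates.  Masking never alters surviving ratio values,
only the per-pixel reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .mosaic import MosaicGrid
from .raster import GridGeometry, Raster

__all__ = ["MaskReason", "RatioGrid", "compute_ratios", "filter_outliers", "apply_viirs_mask"]


class MaskReason(IntEnum):
    VALID = 0
    UNLIT = 1
    OUTLIER = 2
    BELOW_VIIRS_THRESHOLD = 3
    CLOUD = 4
    OFF_SCENE = 5


@dataclass
class RatioGrid:
    """Per-pixel B/G, G/R, R/G ratios with reason-coded validity."""

    b_over_g: np.ndarray
    g_over_r: np.ndarray
    r_over_g: np.ndarray
    reason: np.ndarray  # uint8 MaskReason codes
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return self.reason == MaskReason.VALID

    def copy(self) -> "RatioGrid":
        return replace(
            self,
            b_over_g=self.b_over_g.copy(),
            g_over_r=self.g_over_r.copy(),
            r_over_g=self.r_over_g.copy(),
            reason=self.reason.copy(),
            meta=dict(self.meta),
        )

    def to_raster(self) -> Raster:
        return Raster(
            np.stack([self.b_over_g, self.g_over_r, self.r_over_g, self.reason.astype(float)]),
            self.geometry,
            band_names=("b_over_g", "g_over_r", "r_over_g", "mask_reason"),
            meta=self.meta,
        )

    @classmethod
    def from_raster(cls, raster: Raster) -> "RatioGrid":
        return cls(
            b_over_g=raster.band("b_over_g"),
            g_over_r=raster.band("g_over_r"),
            r_over_g=raster.band("r_over_g"),
            reason=np.round(raster.band("mask_reason")).astype(np.uint8),
            geometry=raster.geometry,
            meta=dict(raster.meta),
        )


def compute_ratios(mosaic: MosaicGrid) -> RatioGrid:
    """Band ratios of a calibrated mosaic.

    Pixels outside every frame footprint are OFF_SCENE; pixels with any
    non-positive band radiance carry no spectral information and are
    UNLIT.  Surviving pixels have all three ratios finite and positive,
    with R/G the exact reciprocal of G/R.
    """
    r, g, b = mosaic.data[0], mosaic.data[1], mosaic.data[2]
    reason = np.full(mosaic.provenance.shape, MaskReason.OFF_SCENE, dtype=np.uint8)
    on = mosaic.valid
    reason[on] = MaskReason.UNLIT
    lit = on & np.isfinite(r) & np.isfinite(g) & np.isfinite(b) & (r > 0) & (g > 0) & (b > 0)
    reason[lit] = MaskReason.VALID
    with np.errstate(divide="ignore", invalid="ignore"):
        b_over_g = np.where(lit, b / g, np.nan)
        g_over_r = np.where(lit, g / r, np.nan)
        r_over_g = np.where(lit, r / g, np.nan)
    return RatioGrid(
        b_over_g=b_over_g,
        g_over_r=g_over_r,
        r_over_g=r_over_g,
        reason=reason,
        geometry=mosaic.geometry,
        meta={"source": "mosaic", **mosaic.meta},
    )


def filter_outliers(
    rg: RatioGrid,
    bg_max: float = 1.2,
    gr_max: float = 1.2,
    rg_max: float = 6.0,
    conjunctive: bool = False,
) -> RatioGrid:
    """Mask ratio-diagram outliers.

    A pixel is an outlier when B/G or G/R *exceeds* 1.2 or R/G exceeds 6
    (strict inequalities: boundary values are retained).  ``conjunctive``
    switches to the stricter reading that requires the R/G condition in
    addition to a ratio condition.
    """
    out = rg.copy()
    v = out.valid
    over_bg = v & (out.b_over_g > bg_max)
    over_gr = v & (out.g_over_r > gr_max)
    over_rg = v & (out.r_over_g > rg_max)
    if conjunctive:
        bad = (over_bg | over_gr) & over_rg
    else:
        bad = over_bg | over_gr | over_rg
    out.reason[bad] = MaskReason.OUTLIER
    out.meta["n_outliers_masked"] = int(bad.sum())
    return out


def apply_viirs_mask(rg: RatioGrid, viirs: Raster, threshold: float = 0.5) -> RatioGrid:
    """Mask pixels dimmer than *threshold* (nW cm^-2 sr^-1) in the
    panchromatic satellite composite; strictly-below is masked, the
    boundary value is retained."""
    if viirs.geometry != rg.geometry:
        raise ValueError("VIIRS raster is not co-registered with the ratio grid")
    out = rg.copy()
    dim = out.valid & (viirs.data[0] < threshold)
    out.reason[dim] = MaskReason.BELOW_VIIRS_THRESHOLD
    out.meta["n_below_viirs_masked"] = int(dim.sum())
    return out
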