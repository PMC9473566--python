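"""Per-frame correction chain: counts to calibrated band radiances.

Order is fixed and mirrors how the physical corruptions compose:

    decode -> linearity -> flat-field -> spectral (crosstalk) ->
    photometric calibration (reference sources) -> radiometric
    (settings) correction -> atmospheric correction -> cloud mask

:func:`calibrate_frame` drives the whole chain.  All operations return new
frames; validity masks only ever shrink, and no valid pixel acquires a
negative radiance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .raster import GridGeometry, Raster
from .scene import AcquisitionGeometry, DistortionConfig, RawFrame

__all__ = [
    "CalibrationError",
    "CalibrationModel",
    "Frame",
    "decode",
    "correct_linearity",
    "correct_flatfield",
    "spectral_characterize",
    "photometric_calibrate",
    "estimate_constants",
    "radiometric_correct",
    "atmospheric_correct",
    "mask_clouds",
    "calibrate_frame",
]


class CalibrationError(RuntimeError):
    """A frame cannot be calibrated (e.g. too few usable reference sources)."""


@dataclass
class CalibrationModel:
    """Everything needed to undo the acquisition chain.

    The linearity curve is parameterized by (knee, full_well) of the
    rational roll-off model; ``instrumental_constants`` convert counts to
    radiance at reference settings and are normally estimated per frame by
    :func:`photometric_calibrate`.
    """

    full_well: float = 65535.0
    knee_frac: float = 0.8
    vignette_a2: float = 0.35
    vignette_a4: float = 0.15
    flatfield: np.ndarray | None = None  # overrides the radial polynomial
    crosstalk: np.ndarray = field(default_factory=lambda: np.eye(3))
    t_atm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    airmass_cap: float = 5.0
    iso_ref: float = 800.0
    lens_transmittance: float = 1.0
    instrumental_constants: np.ndarray | None = None
    cloud_dark_fraction: float = 0.2

    def __post_init__(self):
        self.crosstalk = np.asarray(self.crosstalk, dtype=float)
        if self.crosstalk.shape != (3, 3) or np.any(self.crosstalk < 0):
            raise ValueError("crosstalk must be a nonnegative 3x3 matrix")
        if not 0 < self.knee_frac:
            raise ValueError("knee must be positive")
        if any(not 0 < t <= 1 for t in self.t_atm):
            raise ValueError("transmittances must be in (0, 1]")
        if self.instrumental_constants is not None:
            self.instrumental_constants = np.asarray(self.instrumental_constants, float)
            if np.any(self.instrumental_constants <= 0):
                raise ValueError("instrumental constants must be positive")

    @property
    def knee(self) -> float:
        return self.knee_frac * self.full_well

    @classmethod
    def from_distortions(cls, d: DistortionConfig, known_constants: bool = False):
        """Synthetic-mode truth model (constants still estimated from stars
        unless ``known_constants``)."""
        return cls(
            full_well=d.full_well,
            knee_frac=d.knee_frac,
            vignette_a2=d.vignette_a2,
            vignette_a4=d.vignette_a4,
            crosstalk=np.asarray(d.crosstalk, dtype=float).copy(),
            t_atm=tuple(d.t_atm),
            airmass_cap=d.airmass_cap,
            iso_ref=d.iso_ref,
            lens_transmittance=d.lens_transmittance,
            instrumental_constants=(
                np.asarray(d.instrumental_constants, float) if known_constants else None
            ),
        )

    def vignette(self, shape: tuple[int, int]) -> np.ndarray:
        if self.flatfield is not None:
            if self.flatfield.shape != shape:
                raise ValueError("flat-field shape does not match frame")
            return self.flatfield
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        r = np.hypot(rows - cr, cols - cc)
        rmax = np.hypot(cr + 0.5, cc + 0.5)
        u = r / rmax
        return 1.0 - self.vignette_a2 * u**2 - self.vignette_a4 * u**4

    def to_json(self, path=None) -> str:
        doc = {
            "full_well": self.full_well,
            "knee_frac": self.knee_frac,
            "vignette_a2": self.vignette_a2,
            "vignette_a4": self.vignette_a4,
            "crosstalk": self.crosstalk.tolist(),
            "t_atm": list(self.t_atm),
            "airmass_cap": self.airmass_cap,
            "iso_ref": self.iso_ref,
            "lens_transmittance": self.lens_transmittance,
            "instrumental_constants": (
                None
                if self.instrumental_constants is None
                else self.instrumental_constants.tolist()
            ),
            "cloud_dark_fraction": self.cloud_dark_fraction,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            doc = json.load(fh)
        kc = doc.pop("instrumental_constants", None)
        doc["crosstalk"] = np.asarray(doc["crosstalk"])
        doc["t_atm"] = tuple(doc["t_atm"])
        model = cls(**doc)
        if kc is not None:
            model.instrumental_constants = np.asarray(kc, float)
        return model


#: Validity-loss reason codes shared with the ratio grids.
REASON_OK = 0
REASON_SATURATED = 1
REASON_CLOUD = 2
REASON_NEGATIVE = 3


@dataclass
class Frame:
    """Working frame: per-channel values, validity, and provenance.

    ``units`` is "counts" until radiometric correction, then "radiance"
    (nW cm^-2 sr^-1).  Invalid pixels carry NaN once in radiance units.
    """

    values: np.ndarray  # (3, h, w), bands R, G, B
    valid: np.ndarray  # (h, w) bool
    reasons: np.ndarray  # (h, w) uint8
    geometry: AcquisitionGeometry
    window: tuple[int, int]
    grid: GridGeometry
    control_points: np.ndarray
    units: str = "counts"
    log: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def invalidate(self, mask: np.ndarray, reason: int) -> None:
        newly = mask & self.valid
        self.valid[newly] = False
        self.reasons[newly] = reason

    def copy(self) -> "Frame":
        return replace(
            self,
            values=self.values.copy(),
            valid=self.valid.copy(),
            reasons=self.reasons.copy(),
            log=dict(self.log),
        )


def decode(raw: RawFrame) -> Frame:
    """Raw acquisition -> working frame.

    Synthetic frames are already linear 3-band rasters, so decodification
    is a container change (the real-data analog is raw-file conversion and
    channel separation).
    """
    h, w = raw.counts.shape[1:]
    return Frame(
        values=raw.counts.astype(float).copy(),
        valid=np.ones((h, w), dtype=bool),
        reasons=np.zeros((h, w), dtype=np.uint8),
        geometry=raw.geometry,
        window=raw.window,
        grid=raw.grid,
        control_points=raw.control_points.copy(),
        units="counts",
        log={"frame_id": raw.geometry.frame_id},
    )


def correct_linearity(frame: Frame, model: CalibrationModel) -> Frame:
    """Invert the sensor's high-count roll-off; flag saturated pixels.

    Counts at or below the knee are unchanged.  Observed counts whose
    linear equivalent exceeds the full well (i.e. beyond the midpoint of
    the roll-off) are untrustworthy and flagged saturated.
    """
    out = frame.copy()
    knee = model.knee
    w_roll = model.full_well - knee
    v = out.values
    above = v > knee
    if w_roll > 0 and np.any(above):
        u = (v[above] - knee) / w_roll
        u = np.minimum(u, 1.0 - 1e-9)  # noise can push counts past the asymptote
        v[above] = knee + w_roll * u / (1.0 - u)
        sat = np.any(v > model.full_well, axis=0)
        out.invalidate(sat, REASON_SATURATED)
        out.log["n_saturated"] = int(sat.sum())
    return out


def correct_flatfield(frame: Frame, model: CalibrationModel) -> Frame:
    """Divide out lens vignetting / nonuniform sensor illumination."""
    ff = model.vignette(frame.shape)
    if np.any(ff <= 0):
        raise ValueError("flat-field must be strictly positive everywhere")
    out = frame.copy()
    out.values = out.values / ff[None]
    return out


def spectral_characterize(frame: Frame, model: CalibrationModel) -> Frame:
    """Undo inter-channel spectral crosstalk with the inverse 3x3 matrix."""
    try:
        inv = np.linalg.inv(model.crosstalk)
    except np.linalg.LinAlgError as exc:
        raise ValueError("crosstalk matrix is singular") from exc
    out = frame.copy()
    out.values = np.einsum("ij,jhw->ihw", inv, out.values)
    neg = out.values < 0
    out.log["n_negative_clipped"] = int(np.any(neg, axis=0).sum())
    out.values[neg] = 0.0
    return out


def photometric_calibrate(
    frame: Frame,
    sources: list[tuple[int, int, np.ndarray]],
    aperture_radius: float = 3.0,
    annulus: tuple[float, float] = (5.0, 8.0),
) -> np.ndarray:
    """Estimate per-channel instrumental constants from reference sources.

    Each source is (row, col, known at-sensor band radiance (3,)).  The
    constant is the robust (median over sources) ratio of known radiance to
    background-subtracted aperture counts, normalized to reference
    exposure/ISO settings.  Sources with saturated/invalid aperture pixels
    are excluded; fewer than 3 usable sources aborts with
    :class:`CalibrationError`.
    """
    h, w = frame.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    geom = frame.geometry
    settings = geom.exposure_s * (geom.iso / _iso_ref(frame)) * _lens_t(frame)
    estimates = []
    n_excluded = 0
    for sr, sc, flux in sources:
        dist = np.hypot(rows - sr, cols - sc)
        ap = dist <= aperture_radius
        ann = (dist >= annulus[0]) & (dist <= annulus[1])
        if not np.all(frame.valid[ap]) or ann.sum() < 8:
            n_excluded += 1
            continue
        flux = np.asarray(flux, dtype=float)
        ks = []
        for b in range(3):
            bg = np.median(frame.values[b][ann])
            net = float(frame.values[b][ap].sum() - bg * ap.sum())
            if net <= 0:
                break
            ks.append(flux[b] * settings / net)
        if len(ks) == 3:
            estimates.append(ks)
        else:
            n_excluded += 1
    if len(estimates) < 3:
        raise CalibrationError(
            f"frame {geom.frame_id!r}: only {len(estimates)} usable reference "
            f"sources ({n_excluded} excluded); need >= 3"
        )
    constants = np.median(np.asarray(estimates), axis=0)
    frame.log["n_sources_used"] = len(estimates)
    frame.log["n_sources_excluded"] = n_excluded
    return constants


def _iso_ref(frame: Frame) -> float:
    return frame.log.get("iso_ref", 800.0)


def _lens_t(frame: Frame) -> float:
    return frame.log.get("lens_transmittance", 1.0)


def radiometric_correct(
    frame: Frame, constants: np.ndarray, model: CalibrationModel
) -> Frame:
    """Counts -> at-sensor radiance using constants and camera settings."""
    geom = frame.geometry
    for name in ("exposure_s", "iso"):
        if getattr(geom, name, None) is None:
            raise ValueError(f"missing acquisition metadata field {name!r}")
    constants = np.asarray(constants, dtype=float)
    if constants.shape != (3,) or np.any(constants <= 0):
        raise ValueError("need three positive instrumental constants")
    settings = geom.exposure_s * (geom.iso / model.iso_ref) * model.lens_transmittance
    out = frame.copy()
    out.values = out.values * constants[:, None, None] / settings
    out.values[:, ~out.valid] = np.nan
    out.units = "radiance"
    out.log["instrumental_constants"] = constants.tolist()
    return out


def atmospheric_correct(frame: Frame, model: CalibrationModel) -> Frame:
    """Undo per-band extinction along the slant path (t_band ** airmass)."""
    airmass = min(
        1.0 / np.cos(np.deg2rad(frame.geometry.angle_deg)), model.airmass_cap
    )
    t = np.asarray(model.t_atm, dtype=float) ** airmass
    out = frame.copy()
    out.values = out.values / t[:, None, None]
    out.log["airmass"] = airmass
    return out


def mask_clouds(
    frame: Frame,
    mask: np.ndarray | None = None,
    viirs: Raster | None = None,
    dark_fraction: float | None = None,
    model: CalibrationModel | None = None,
) -> Frame:
    """Mask cloud pixels, from an explicit mask or the satellite heuristic.

    The heuristic flags pixels whose G-band radiance falls below
    ``dark_fraction`` (default 0.2) of the co-located panchromatic
    satellite radiance — occluding clouds darken the camera view of lit
    areas while the multi-date satellite composite still shows them lit.
    """
    if mask is None and viirs is None:
        raise ValueError("either an explicit cloud mask or a VIIRS raster is required")
    out = frame.copy()
    if mask is not None:
        if mask.shape != frame.shape:
            raise ValueError("cloud mask shape does not match frame")
        out.invalidate(mask.astype(bool), REASON_CLOUD)
    else:
        if frame.units != "radiance":
            raise ValueError("VIIRS cloud heuristic needs a radiance frame")
        if dark_fraction is None:
            dark_fraction = model.cloud_dark_fraction if model else 0.2
        r0, c0 = frame.window
        h, w = frame.shape
        vwin = viirs.data[0, r0 : r0 + h, c0 : c0 + w]
        g = frame.values[1]
        dark = np.where(np.isfinite(g), g, np.inf) < dark_fraction * vwin
        out.invalidate(dark, REASON_CLOUD)
    out.log["n_cloud_masked"] = int((out.reasons == REASON_CLOUD).sum())
    return out


def estimate_constants(
    calibration_frame: RawFrame,
    model: CalibrationModel,
    sources: list | None = None,
) -> np.ndarray:
    """Instrumental constants from a star-field calibration acquisition.

    The calibration frame goes through the same count-domain corrections
    (linearity, flat-field, crosstalk) before aperture photometry.
    """
    frame = decode(calibration_frame)
    frame.log["iso_ref"] = model.iso_ref
    frame.log["lens_transmittance"] = model.lens_transmittance
    frame = correct_linearity(frame, model)
    frame = correct_flatfield(frame, model)
    frame = spectral_characterize(frame, model)
    if sources is None:
        sources = calibration_frame.truth.get("sources", [])
    return photometric_calibrate(frame, sources)


def calibrate_frame(
    raw: RawFrame,
    model: CalibrationModel,
    viirs: Raster | None = None,
    cloud_mask: np.ndarray | None = None,
    sources: list | None = None,
    calibration_frame: RawFrame | None = None,
) -> Frame:
    """Run the full fixed-order correction chain on one raw frame.

    Instrumental constants come from, in order of preference: the model
    (if set), a dedicated star-field ``calibration_frame``, or reference
    sources embedded in the focal frame itself (``sources``, defaulting to
    the frame's ground-truth sources).  Cloud masking uses an explicit
    mask when given, else the VIIRS heuristic, else is skipped.
    """
    frame = decode(raw)
    frame.log["iso_ref"] = model.iso_ref
    frame.log["lens_transmittance"] = model.lens_transmittance
    frame = correct_linearity(frame, model)
    frame = correct_flatfield(frame, model)
    frame = spectral_characterize(frame, model)
    if model.instrumental_constants is not None:
        constants = model.instrumental_constants
    elif calibration_frame is not None:
        constants = estimate_constants(calibration_frame, model)
    else:
        if sources is None:
            sources = raw.truth.get("sources", [])
        constants = photometric_calibrate(frame, sources)
    frame = radiometric_correct(frame, constants, model)
    frame = atmospheric_correct(frame, model)
    if cloud_mask is not None:
        frame = mask_clouds(frame, mask=cloud_mask)
    elif viirs is not None:
        frame = mask_clouds(frame, viirs=viirs, model=model)
    frame.values[:, ~frame.valid] = np.nan
    np.clip(frame.values, 0.0, None, out=frame.values)
    frame.log["n_valid"] = int(frame.valid.sum())
    return frame
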