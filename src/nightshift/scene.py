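"""Ground-truthed synthetic nighttime scenes.

Emulates the statistical structure of the real inputs the analysis was
designed for: per-pixel street-lamp mixtures that shift from
sodium-dominated (epoch 1) to white-LED-dominated (epoch 2), RGB camera
acquisitions with sensor nonlinearity, vignetting, channel crosstalk,
atmospheric extinction, cloud occlusion and ~4-px georeferencing error,
plus a panchromatic satellite-like radiance raster and region polygons.

Every corrupting effect the calibration pipeline must undo is recorded as
ground truth on the rendered frame, so round-trip accuracy is directly
testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, box
from shapely.ops import unary_union
from shapely import affinity

from .lamps import LAMP_CLASSES, SODIUM_CLASSES, lamp_band_matrix, lamp_viirs_vector
from .raster import GridGeometry, Raster, RegionSet
from .spectra import CameraResponse, band_signal, d65_like_reference

__all__ = [
    "LampMixMap",
    "AcquisitionGeometry",
    "DistortionConfig",
    "RawFrame",
    "make_lamp_maps",
    "render_frame",
    "render_viirs",
    "render_calibration_field",
    "make_regions",
    "default_frame_geometries",
]


@dataclass
class LampMixMap:
    """Georeferenced ground-truth map of per-pixel lamp mixtures.

    ``weights`` is (n_classes, rows, cols) with values in [0, 1] summing to
    1 on lit pixels and 0 on unlit ones; ``scale`` is the bolometric
    emission in nW cm^-2 sr^-1-equivalent units.
    """

    weights: np.ndarray
    scale: np.ndarray
    epoch: str
    geometry: GridGeometry
    classes: tuple[str, ...] = LAMP_CLASSES

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.weights.shape[0] != len(self.classes):
            raise ValueError("one weight plane per lamp class required")
        if self.weights.shape[1:] != tuple(self.geometry.shape):
            raise ValueError("weights do not match grid shape")
        if np.any(self.weights < 0) or np.any(self.weights > 1 + 1e-9):
            raise ValueError("mixture weights must lie in [0, 1]")
        wsum = self.weights.sum(axis=0)
        if np.any(wsum > 1 + 1e-6):
            raise ValueError("mixture weights must sum to <= 1 per pixel")
        if np.any(self.scale[wsum <= 0] != 0):
            raise ValueError("unlit pixels must have zero emission scale")

    @property
    def lit_mask(self) -> np.ndarray:
        return self.scale > 0

    def band_radiance(self, camera: CameraResponse) -> np.ndarray:
        """(3, rows, cols) true R, G, B band radiances of the scene."""
        m = lamp_band_matrix(camera, self.classes)
        return np.tensordot(m, self.weights, axes=1) * self.scale


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Metadata of one camera acquisition."""

    angle_deg: float  # observation angle from nadir
    focal_mm: float
    center_rowcol: tuple[int, int]  # frame center on the analysis grid
    timestamp: float  # decimal year
    exposure_s: float
    iso: float
    frame_shape: tuple[int, int] = (120, 120)
    frame_id: str = "frame"

    def __post_init__(self):
        if not 0.0 <= self.angle_deg <= 70.0:
            raise ValueError("observation angle must be in [0, 70] degrees")
        if self.exposure_s <= 0:
            raise ValueError("exposure must be positive")
        if self.iso <= 0:
            raise ValueError("ISO must be positive")
        if self.focal_mm <= 0:
            raise ValueError("focal length must be positive")


@dataclass
class DistortionConfig:
    """Forward-model parameters of every corruption the pipeline corrects.

    Defaults are the study conditions; :meth:`none` disables everything for
    construction-style tests.
    """

    # lens vignetting V(r) = 1 - a2*(r/rmax)^2 - a4*(r/rmax)^4
    vignette_a2: float = 0.35
    vignette_a4: float = 0.15
    # sensor nonlinearity: linear below knee, rational roll-off above
    full_well: float = 65535.0
    knee_frac: float = 0.8
    # channel crosstalk matrix (rows = measured, cols = true; R, G, B order)
    crosstalk: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.94, 0.05, 0.01], [0.04, 0.92, 0.04], [0.01, 0.06, 0.93]]
        )
    )
    # per-band atmospheric transmittance at nadir (R, G, B)
    t_atm: tuple[float, float, float] = (0.93, 0.88, 0.82)
    airmass_cap: float = 5.0
    # radiometry: counts = L * exposure * (iso/iso_ref) * lens_t * V / K
    instrumental_constants: tuple[float, float, float] = (5.2e-5, 5.0e-5, 5.5e-5)
    iso_ref: float = 800.0
    lens_transmittance: float = 0.95
    # noise: sd = sqrt(read^2 + shot_var_per_count * counts)
    read_noise: float = 15.0
    shot_var_per_count: float = 2.0
    # clouds: occluding smoothed-noise field with a faint diffuse glow
    cloud_fraction: float = 0.12
    cloud_attenuation: float = 0.05
    cloud_glow_radiance: float = 0.3
    cloud_smooth_px: float = 8.0
    # georeferencing: control-point jitter, RMSE target ~4 px
    cp_jitter_px: float = 4.0
    n_control_points: int = 100
    # reference point sources for photometric calibration
    n_sources: int = 8
    source_flux_range: tuple[float, float] = (6.0, 14.0)
    source_psf_sigma: float = 1.0

    @classmethod
    def none(cls) -> "DistortionConfig":
        """All distortions off: identity optics, no noise, no clouds."""
        return cls(
            vignette_a2=0.0,
            vignette_a4=0.0,
            knee_frac=1e9,  # knee far above any count: purely linear
            crosstalk=np.eye(3),
            t_atm=(1.0, 1.0, 1.0),
            lens_transmittance=1.0,
            read_noise=0.0,
            shot_var_per_count=0.0,
            cloud_fraction=0.0,
            cp_jitter_px=0.0,
        )

    @property
    def knee(self) -> float:
        return self.knee_frac * self.full_well

    def vignette(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        r = np.hypot(rows - cr, cols - cc)
        rmax = np.hypot(cr + 0.5, cc + 0.5)
        u = r / rmax
        return 1.0 - self.vignette_a2 * u**2 - self.vignette_a4 * u**4

    def apply_nonlinearity(self, counts: np.ndarray) -> np.ndarray:
        """Linear below the knee; saturating rational roll-off above it."""
        knee = self.knee
        w = self.full_well - knee
        out = np.array(counts, dtype=float)
        above = out > knee
        if np.any(above) and w > 0:
            u = (out[above] - knee) / w
            out[above] = knee + w * u / (1.0 + u)
        return out

    def glow_band_radiance(self, camera: CameraResponse) -> np.ndarray:
        """Per-band radiance of the diffuse cloud glow (broad white)."""
        glow = d65_like_reference().normalized().scaled(self.cloud_glow_radiance)
        return np.array([band_signal(glow, b) for b in camera.bands])


@dataclass
class RawFrame:
    """One rendered acquisition: counts, metadata, and ground truth."""

    counts: np.ndarray  # (3, h, w) R, G, B
    geometry: AcquisitionGeometry
    window: tuple[int, int]  # (row0, col0) of the frame on the grid
    control_points: np.ndarray  # (n, 4): frame_row, frame_col, map_x, map_y
    grid: GridGeometry
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[0] != 3:
            raise ValueError("counts must be (3, h, w)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


def make_lamp_maps(
    n_cities: int,
    grid_shape: tuple[int, int] = (300, 300),
    epoch_shift: float = 0.5,
    seed: int = 0,
    geometry: GridGeometry | None = None,
    lit_floor: float = 2.0,
) -> tuple[LampMixMap, LampMixMap]:
    """Generate matched epoch-1 / epoch-2 lamp-mixture maps.

    Epoch 1 is sodium-dominated (HPS with minority LPS, mercury,
    fluorescent, metal halide); epoch 2 is identical except that a seeded
    Bernoulli(epoch_shift) subset of lit pixels has its sodium weight
    reassigned to white LED.  Cities are Gaussian-decay emission blobs;
    pixels below ``lit_floor`` are unlit.
    """
    if not 0.0 <= epoch_shift <= 1.0:
        raise ValueError("epoch_shift must be in [0, 1]")
    h, w = grid_shape
    if n_cities < 1:
        raise ValueError("need at least one city")
    if h * w < 64 * n_cities or min(h, w) < 16:
        raise ValueError(f"grid {grid_shape} too small for {n_cities} cities")
    if geometry is None:
        geometry = GridGeometry.study_grid(shape=grid_shape)

    rng = np.random.default_rng(seed)
    n_cls = len(LAMP_CLASSES)
    idx = {c: i for i, c in enumerate(LAMP_CLASSES)}

    scale = np.zeros(grid_shape)
    wsum = np.zeros((n_cls, h, w))
    margin = min(h, w) // 15
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(n_cities):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        sigma = rng.uniform(12.0, 20.0)
        amp = float(np.exp(rng.normal(np.log(8.0), 0.4)))
        blob = amp * np.exp(-0.5 * ((rows - cy) ** 2 + (cols - cx) ** 2) / sigma**2)
        # epoch-1 technology mix of this city: sodium-dominated
        mix = np.zeros(n_cls)
        mix[idx["hps"]] = rng.uniform(0.55, 0.75)
        mix[idx["lps"]] = rng.uniform(0.0, 0.15)
        rest = 1.0 - mix.sum()
        other = rng.dirichlet(np.ones(3)) * rest
        mix[idx["mercury"]], mix[idx["fluorescent"]], mix[idx["metal_halide"]] = other
        scale += blob
        wsum += mix[:, None, None] * blob

    lit = scale >= lit_floor
    weights1 = np.zeros_like(wsum)
    weights1[:, lit] = wsum[:, lit] / scale[lit]
    scale1 = np.where(lit, scale, 0.0)

    map1 = LampMixMap(weights1, scale1, epoch="pre", geometry=geometry)

    # epoch 2: per-pixel sodium -> LED conversion
    weights2 = weights1.copy()
    if epoch_shift > 0:
        convert = lit & (rng.random(grid_shape) < epoch_shift)
        led = np.where(rng.random(grid_shape) < 0.3, idx["led_3000k"], idx["led_4000k"])
        sodium = sum(weights2[idx[c]] for c in SODIUM_CLASSES)
        for c in SODIUM_CLASSES:
            weights2[idx[c]][convert] = 0.0
        for led_i in (idx["led_3000k"], idx["led_4000k"]):
            sel = convert & (led == led_i)
            weights2[led_i][sel] += sodium[sel]
    map2 = LampMixMap(weights2, scale1.copy(), epoch="post", geometry=geometry)
    return map1, map2


def render_viirs(mix_map: LampMixMap) -> Raster:
    """Panchromatic satellite-like radiance of the scene (480-920 nm band).

    Per-pixel in-band integral of the mixture spectrum, in the same
    nW cm^-2 sr^-1-equivalent units as the emission scale.  Blind to
    emissions below 480 nm, like the real day/night band.
    """
    v = lamp_viirs_vector(mix_map.classes)
    data = np.tensordot(v, mix_map.weights, axes=1) * mix_map.scale
    return Raster(
        data,
        mix_map.geometry,
        band_names=("viirs",),
        meta={"epoch": mix_map.epoch, "units": "nW cm-2 sr-1"},
    )


def _source_positions(rng, scale_w, n_sources, margin=9, min_sep=18):
    """Reference-source positions on the darkest available sky.

    Candidates are ranked by the brightest scene pixel within the
    photometric annulus footprint (so both aperture and background ring
    sit on dark sky where possible) and chosen greedily with a minimum
    mutual separation, so no source contaminates another's photometry.
    """
    from scipy.ndimage import maximum_filter

    h, w = scale_w.shape
    local_max = maximum_filter(scale_w, size=2 * margin + 1)
    rs, cs = np.mgrid[margin : h - margin, margin : w - margin]
    rs, cs = rs.ravel(), cs.ravel()
    score = local_max[rs, cs] + rng.uniform(0, 1e-6, rs.size)  # random tie-break
    order = np.argsort(score, kind="stable")
    used = np.zeros(rs.size, dtype=bool)
    sel_r, sel_c = [], []
    for sep in (min_sep, min_sep // 2, 2):
        for i in order:
            if len(sel_r) >= n_sources:
                break
            if used[i]:
                continue
            if all(np.hypot(rs[i] - a, cs[i] - b) >= sep for a, b in zip(sel_r, sel_c)):
                used[i] = True
                sel_r.append(rs[i])
                sel_c.append(cs[i])
        if len(sel_r) >= n_sources:
            break
    return np.asarray(sel_r), np.asarray(sel_c)


def render_frame(
    mix_map: LampMixMap,
    camera: CameraResponse,
    geom: AcquisitionGeometry,
    distortions: DistortionConfig | None = None,
    seed: int = 0,
    noise_seed: int | None = None,
) -> RawFrame:
    """Forward-render one camera acquisition from a ground-truth map.

    Chain per band: scene radiance -> cloud occlusion -> atmospheric
    extinction (t^airmass) -> vignette, exposure/ISO/lens scaling and
    count conversion -> reference point sources -> channel crosstalk ->
    sensor nonlinearity -> noise.  Deterministic for a fixed seed.
    ``noise_seed`` separates the sensor-noise stream from the structural
    randomness (clouds, sources, control-point jitter), so matched
    re-acquisitions of the same scene can share everything but the noise.
    """
    if distortions is None:
        distortions = DistortionConfig()
    d = distortions
    rng = np.random.default_rng(seed)
    noise_rng = rng if noise_seed is None else np.random.default_rng(noise_seed)
    H, W = mix_map.geometry.shape
    fh, fw = geom.frame_shape
    if fh > H or fw > W:
        raise ValueError("frame larger than analysis grid")
    row0 = int(np.clip(geom.center_rowcol[0] - fh // 2, 0, H - fh))
    col0 = int(np.clip(geom.center_rowcol[1] - fw // 2, 0, W - fw))

    weights = mix_map.weights[:, row0 : row0 + fh, col0 : col0 + fw]
    scale = mix_map.scale[row0 : row0 + fh, col0 : col0 + fw]
    bandmat = lamp_band_matrix(camera, mix_map.classes)
    radiance = np.tensordot(bandmat, weights, axes=1) * scale  # ground truth

    # clouds occlude and add a faint diffuse glow
    cloud_mask = np.zeros((fh, fw), dtype=bool)
    observed = radiance.copy()
    if d.cloud_fraction > 0:
        noise_field = gaussian_filter(rng.standard_normal((fh, fw)), d.cloud_smooth_px)
        thresh = np.quantile(noise_field, 1.0 - d.cloud_fraction)
        cloud_mask = noise_field > thresh
        glow = d.glow_band_radiance(camera)
        observed[:, cloud_mask] = (
            observed[:, cloud_mask] * d.cloud_attenuation + glow[:, None]
        )

    airmass = min(1.0 / np.cos(np.deg2rad(geom.angle_deg)), d.airmass_cap)
    t = np.asarray(d.t_atm, dtype=float) ** airmass
    observed = observed * t[:, None, None]

    vign = d.vignette((fh, fw))
    gain = geom.iso / d.iso_ref
    k = np.asarray(d.instrumental_constants, dtype=float)
    settings = geom.exposure_s * gain * d.lens_transmittance
    counts = observed * vign[None] * settings / k[:, None, None]

    # reference point sources (known at-sensor band radiance) on dark sky
    sources = []
    if d.n_sources > 0:
        srows, scols = _source_positions(rng, scale, d.n_sources)
        flux = rng.uniform(*d.source_flux_range, size=srows.size)
        rr, cc = np.mgrid[0:fh, 0:fw].astype(float)
        for sr, sc, f in zip(srows, scols, flux):
            psf = np.exp(
                -0.5 * ((rr - sr) ** 2 + (cc - sc) ** 2) / d.source_psf_sigma**2
            )
            psf /= psf.sum()
            fb = np.full(3, float(f))  # flat white reference spectrum
            src_counts = fb[:, None, None] * psf[None] * vign[sr, sc] * settings / k[
                :, None, None
            ]
            counts = counts + src_counts
            sources.append((int(sr), int(sc), fb))

    counts = np.einsum("ij,jhw->ihw", np.asarray(d.crosstalk, dtype=float), counts)
    counts_linear = counts.copy()
    counts = d.apply_nonlinearity(counts)
    if d.read_noise > 0 or d.shot_var_per_count > 0:
        sd = np.sqrt(d.read_noise**2 + d.shot_var_per_count * counts)
        counts = counts + noise_rng.normal(0.0, 1.0, counts.shape) * sd
    counts = np.maximum(counts, 0.0)

    # control points: regular grid of frame pixels whose true map position
    # is known; the reported map coordinate carries the georeferencing error
    n_side = max(2, int(round(np.sqrt(d.n_control_points))))
    cp_r = np.linspace(2, fh - 3, n_side)
    cp_c = np.linspace(2, fw - 3, n_side)
    cpr, cpc = [a.ravel() for a in np.meshgrid(cp_r, cp_c)]
    map_x, map_y = mix_map.geometry.transform.xy(row0 + cpr, col0 + cpc, center=True)
    res = mix_map.geometry.resolution
    if d.cp_jitter_px > 0:
        map_x = map_x + rng.normal(0.0, d.cp_jitter_px * res, map_x.shape)
        map_y = map_y + rng.normal(0.0, d.cp_jitter_px * res, map_y.shape)
    control_points = np.column_stack([cpr, cpc, map_x, map_y])

    truth = {
        "radiance": radiance,
        "cloud_mask": cloud_mask,
        "vignette": vign,
        "counts_linear": counts_linear,
        "saturated": counts_linear > d.full_well,
        "sources": sources,
        "distortions": d,
    }
    return RawFrame(
        counts=counts,
        geometry=geom,
        window=(row0, col0),
        control_points=control_points,
        grid=mix_map.geometry,
        truth=truth,
    )


def render_calibration_field(
    camera: CameraResponse,
    geom: AcquisitionGeometry,
    distortions: DistortionConfig | None = None,
    seed: int = 0,
) -> RawFrame:
    """Render a dedicated dark calibration field: reference sources only.

    Photometric calibration against point sources of known flux is done on
    separate star-field acquisitions (clear dark sky), not on the bright
    focal frames; this renders such a field with the same camera settings
    and optical distortions as the focal acquisition.
    """
    d = replace(distortions or DistortionConfig(), cloud_fraction=0.0)
    fh, fw = geom.frame_shape
    grid = GridGeometry.study_grid(shape=(fh, fw))
    dark = LampMixMap(
        np.zeros((len(LAMP_CLASSES), fh, fw)),
        np.zeros((fh, fw)),
        epoch="calibration",
        geometry=grid,
    )
    cal_geom = replace(geom, center_rowcol=(fh // 2, fw // 2), frame_id=geom.frame_id + "_cal")
    return render_frame(dark, camera, cal_geom, d, seed=seed)


def default_frame_geometries(
    grid_shape: tuple[int, int],
    n_frames: int = 12,
    epoch: str = "pre",
    frame_shape: tuple[int, int] = (120, 120),
    seed: int = 0,
) -> list[AcquisitionGeometry]:
    """Tile the grid with overlapping acquisitions of varied metadata."""
    rng = np.random.default_rng(seed)
    h, w = grid_shape
    fh, fw = frame_shape
    n_cols = int(np.ceil(np.sqrt(n_frames)))
    n_rows = int(np.ceil(n_frames / n_cols))
    centers_r = np.linspace(fh // 2, h - fh // 2, n_rows)
    centers_c = np.linspace(fw // 2, w - fw // 2, n_cols)
    years = (2012.0, 2013.9) if epoch == "pre" else (2014.0, 2020.9)
    geoms = []
    i = 0
    for cr in centers_r:
        for cc in centers_c:
            if i >= n_frames:
                break
            geoms.append(
                AcquisitionGeometry(
                    angle_deg=float(rng.uniform(5.0, 45.0)),
                    focal_mm=float(rng.choice([28.0, 50.0, 85.0, 180.0, 400.0])),
                    center_rowcol=(int(cr), int(cc)),
                    timestamp=float(rng.uniform(*years)),
                    exposure_s=float(rng.choice([0.2, 0.25, 1 / 3])),
                    iso=float(rng.choice([800.0, 1600.0, 3200.0])),
                    frame_shape=frame_shape,
                    frame_id=f"{epoch}_{i:03d}",
                )
            )
            i += 1
    return geoms


def _label_polygons(labels: np.ndarray, geometry: GridGeometry, region_ids):
    """Exact polygon per label from row-run rectangles of grid pixels."""
    tr = geometry.transform
    polys = {}
    for rid in region_ids:
        rects = []
        for r in range(labels.shape[0]):
            row = labels[r]
            c = 0
            while c < row.size:
                if row[c] == rid:
                    c1 = c
                    while c1 < row.size and row[c1] == rid:
                        c1 += 1
                    x0, y0 = tr.xy(r, c, center=False)
                    x1, y1 = tr.xy(r + 1, c1, center=False)
                    rects.append(box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1)))
                    c = c1
                else:
                    c += 1
        polys[rid] = unary_union(rects) if rects else None
    return polys


def make_regions(
    n_regions: int,
    geometry: GridGeometry,
    seed: int = 0,
    mode: str = "partition",
) -> RegionSet:
    """Synthetic region polygons on the analysis grid.

    ``partition``: nearest-seed (Voronoi-by-pixel) tessellation — disjoint
    polygons that exactly cover the grid.  ``ranges``: randomly placed,
    possibly overlapping ellipses emulating species ranges.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    rng = np.random.default_rng(seed)
    h, w = geometry.shape
    if mode == "partition":
        if n_regions == 1:
            x0, y0 = geometry.transform.xy(0, 0, center=False)
            x1, y1 = geometry.transform.xy(h, w, center=False)
            poly = box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))
            return RegionSet(["region_000"], [poly], crs=geometry.crs)
        seeds_r = rng.uniform(0, h, n_regions)
        seeds_c = rng.uniform(0, w, n_regions)
        rows, cols = np.mgrid[0:h, 0:w]
        d2 = (
            (rows[None] - seeds_r[:, None, None] + 0.5) ** 2
            + (cols[None] - seeds_c[:, None, None] + 0.5) ** 2
        )
        labels = np.argmin(d2, axis=0)
        polys = _label_polygons(labels, geometry, range(n_regions))
        names, geoms = [], []
        for rid in range(n_regions):
            if polys[rid] is not None:
                names.append(f"region_{rid:03d}")
                geoms.append(polys[rid])
        return RegionSet(names, geoms, crs=geometry.crs, kind="partition")
    if mode == "ranges":
        res = geometry.resolution
        names, geoms = [], []
        for i in range(n_regions):
            cy = rng.uniform(0.15 * h, 0.85 * h)
            cx = rng.uniform(0.15 * w, 0.85 * w)
            x, y = geometry.transform.xy(cy, cx, center=True)
            rx = rng.uniform(0.08, 0.35) * w * res
            ry = rng.uniform(0.08, 0.35) * h * res
            circ = Point(x, y).buffer(1.0, quad_segs=32)
            ell = affinity.scale(circ, rx, ry)
            ell = affinity.rotate(ell, rng.uniform(0, 180))
            names.append(f"species_{i:03d}")
            geoms.append(ell)
        return RegionSet(names, geoms, crs=geometry.crs, kind="ranges")
    raise ValueError(f"unknown mode {mode!r}")
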