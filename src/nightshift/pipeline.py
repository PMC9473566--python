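"""End-to-end pipeline driver: simulate -> calibrate -> mosaic -> ratios ->
indices -> epoch comparison, with a reproducibility manifest.

A single :class:`PipelineConfig` drives every stage; all randomness
descends from its seed via spawned child generators, so a rerun with the
same config is bit-identical.  Outputs embed the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import CalibrationModel, calibrate_frame
from .change import GridView, compare_epochs, distribution_report, grid_values, report_to_csv, zonal_summary
from .indices import estimate_intensity, index_grid
from .lamps import mixture_library
from .mosaic import composite, georeference
from .raster import GridGeometry, Raster, write_raster, write_regions
from .ratiofit import fit_ratio_index_curve
from .ratios import apply_viirs_mask, compute_ratios, filter_outliers
from .scene import (
    DistortionConfig,
    default_frame_geometries,
    make_lamp_maps,
    make_regions,
    render_calibration_field,
    render_frame,
    render_viirs,
)
from .spectra import CameraResponse

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run."""

    grid_shape: tuple[int, int] = (300, 300)
    resolution_m: float = 500.0
    n_cities: int = 10
    epoch_shift: float = 0.5
    n_frames: int = 12
    frame_shape: tuple[int, int] = (120, 120)
    seed: int = 0
    # masking thresholds: B/G, G/R, R/G outlier rule and the VIIRS floor
    bg_max: float = 1.2
    gr_max: float = 1.2
    rg_max: float = 6.0
    viirs_threshold: float = 0.5
    georef_method: str = "affine"
    n_regions: int = 8
    n_species_ranges: int = 38
    # paired_epochs: identical acquisition conditions (geometries, clouds,
    # control-point jitter) in both epochs, independent sensor noise only —
    # the matched-conditions null used to check the pipeline injects no
    # spurious epoch shift
    paired_epochs: bool = False
    distortions: DistortionConfig = field(default_factory=DistortionConfig)
    out_dir: str | None = None
    write_outputs: bool = True

    def __post_init__(self):
        if self.resolution_m <= 0:
            raise ValueError("resolution must be positive")
        for name in ("bg_max", "gr_max", "rg_max", "viirs_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


#: Quantities compared between epochs, in report order.
REPORT_QUANTITIES = (
    "b_over_g",
    "g_over_r",
    "g_intensity",
    "b_intensity",
    "p_intensity",
    "msi_bg",
    "msi_gr",
    "sli_bg",
    "phototaxis_gr",
)


@dataclass
class PipelineResult:
    config: PipelineConfig
    mosaics: dict
    ratio_grids: dict
    intensity_grids: dict
    index_grids: dict
    comparisons: list
    report: dict
    zonal_tables: dict
    manifest: dict
    truth_maps: dict
    viirs: dict


def _ints(ss: np.random.SeedSequence, n: int) -> list[int]:
    return [int(x % 2**31) for x in ss.generate_state(n)]


def _epoch_products(
    epoch, mix_map, viirs, camera, cfg,
    geom_seed, frame_seeds, noise_seeds,
    index_models, intensity_models,
):
    """Calibrate, mosaic and mask one epoch; return per-epoch grids."""
    geoms = default_frame_geometries(
        cfg.grid_shape, cfg.n_frames, epoch, cfg.frame_shape, seed=geom_seed
    )
    model = CalibrationModel.from_distortions(cfg.distortions)
    frames = []
    for geom, fs, ns in zip(geoms, frame_seeds, noise_seeds):
        raw = render_frame(
            mix_map, camera, geom, cfg.distortions, seed=fs, noise_seed=ns
        )
        star_field = render_calibration_field(
            camera, geom, cfg.distortions, seed=fs + 1
        )
        cal = calibrate_frame(raw, model, viirs=viirs, calibration_frame=star_field)
        frames.append(georeference(cal, method=cfg.georef_method))
    mosaic = composite(frames, epoch_policy=epoch)
    rg = compute_ratios(mosaic)
    rg = filter_outliers(rg, cfg.bg_max, cfg.gr_max, cfg.rg_max)
    rg = apply_viirs_mask(rg, viirs, cfg.viirs_threshold)
    intensities = {
        which: estimate_intensity(viirs, rg, which, model=intensity_models[which])
        for which in ("G", "B", "P")
    }
    idx = {name: index_grid(rg, m) for name, m in index_models.items()}
    return mosaic, rg, intensities, idx


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full synthetic two-epoch analysis.

    Returns every intermediate product plus the epoch-comparison report;
    writes rasters, tables and a manifest under ``config.out_dir`` when
    ``write_outputs`` is set and a directory is given.
    """
    cfg = config or PipelineConfig()
    root_ss = np.random.SeedSequence(cfg.seed)
    ss_scene, ss_pre, ss_post, ss_regions = root_ss.spawn(4)
    camera = CameraResponse.default()
    geometry = GridGeometry.study_grid(cfg.grid_shape, cfg.resolution_m)

    map_pre, map_post = make_lamp_maps(
        cfg.n_cities,
        cfg.grid_shape,
        cfg.epoch_shift,
        seed=int(ss_scene.generate_state(1)[0] % 2**31),
        geometry=geometry,
    )
    viirs = {"pre": render_viirs(map_pre), "post": render_viirs(map_post)}

    # ratio -> index and ratio -> intensity relationships refitted over the
    # lamp library by synthetic photometry (seeded bootstrap)
    library = mixture_library()
    fit_seed = cfg.seed
    index_models = {
        "msi_bg": fit_ratio_index_curve(library, "b_over_g", "msi", camera=camera, seed=fit_seed),
        "msi_gr": fit_ratio_index_curve(library, "g_over_r", "msi", camera=camera, seed=fit_seed),
        "sli_bg": fit_ratio_index_curve(library, "b_over_g", "sli", camera=camera, seed=fit_seed),
        "phototaxis_gr": fit_ratio_index_curve(
            library, "g_over_r", "phototaxis", camera=camera, seed=fit_seed
        ),
    }
    intensity_models = {
        "G": fit_ratio_index_curve(library, "g_over_r", "g_over_viirs", camera=camera, seed=fit_seed),
        "B": fit_ratio_index_curve(library, "b_over_g", "b_over_viirs", camera=camera, seed=fit_seed),
        "P": fit_ratio_index_curve(library, "g_over_r", "p_over_viirs", camera=camera, seed=fit_seed),
    }

    # acquisition randomness: shared between epochs in paired mode, with
    # only the sensor-noise streams independent
    acq = {"pre": ss_pre, "post": ss_pre if cfg.paired_epochs else ss_post}
    noise = {e: root_ss.spawn(1)[0] for e in ("pre", "post")}
    mosaics, ratio_grids, intensity_grids, index_grids = {}, {}, {}, {}
    for epoch, mix_map in (("pre", map_pre), ("post", map_post)):
        seeds = _ints(acq[epoch], cfg.n_frames + 1)
        mosaic, rg, intens, idx = _epoch_products(
            epoch, mix_map, viirs[epoch], camera, cfg,
            geom_seed=seeds[0],
            frame_seeds=seeds[1:],
            noise_seeds=_ints(noise[epoch], cfg.n_frames),
            index_models=index_models,
            intensity_models=intensity_models,
        )
        mosaics[epoch] = mosaic
        ratio_grids[epoch] = rg
        intensity_grids[epoch] = intens
        index_grids[epoch] = idx

    # epoch comparisons
    def views(epoch):
        rg = ratio_grids[epoch]
        out = {
            "b_over_g": GridView(rg.b_over_g, rg.valid, rg.geometry),
            "g_over_r": GridView(rg.g_over_r, rg.valid, rg.geometry),
        }
        for which, label in (("G", "g_intensity"), ("B", "b_intensity"), ("P", "p_intensity")):
            ig = intensity_grids[epoch][which]
            out[label] = GridView(ig.values, ig.valid, ig.geometry)
        for name, ig in index_grids[epoch].items():
            out[name] = GridView(ig.values, ig.valid, ig.geometry)
        return out

    v_pre, v_post = views("pre"), views("post")
    comparisons, samples = [], {}
    for q in REPORT_QUANTITIES:
        pre = grid_values(v_pre[q].values, v_pre[q].valid)
        post = grid_values(v_post[q].values, v_post[q].valid)
        comparisons.append(compare_epochs(pre, post, quantity=q))
        samples[q] = (pre, post)
    report = distribution_report(comparisons, samples)

    # zonal summaries: a partition of "countries" and overlapping "ranges"
    region_seed = int(ss_regions.generate_state(1)[0] % 2**31)
    countries = make_regions(cfg.n_regions, geometry, seed=region_seed, mode="partition")
    ranges = make_regions(cfg.n_species_ranges, geometry, seed=region_seed + 1, mode="ranges")
    zonal_tables = {}
    for q in ("b_over_g", "g_over_r"):
        zonal_tables[f"{q}_countries"] = zonal_summary(v_pre[q], v_post[q], countries, "median")
        zonal_tables[f"{q}_ranges"] = zonal_summary(v_pre[q], v_post[q], ranges, "mean")

    manifest = {
        "software": f"nightshift {__version__}",
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_frames": {"pre": cfg.n_frames, "post": cfg.n_frames},
        "stages": {
            epoch: {
                "n_valid_ratio_pixels": int(ratio_grids[epoch].valid.sum()),
                "mask_counts": {
                    str(code): int((ratio_grids[epoch].reason == code).sum())
                    for code in np.unique(ratio_grids[epoch].reason)
                },
            }
            for epoch in ("pre", "post")
        },
    }

    result = PipelineResult(
        config=cfg,
        mosaics=mosaics,
        ratio_grids=ratio_grids,
        intensity_grids=intensity_grids,
        index_grids=index_grids,
        comparisons=comparisons,
        report=report,
        zonal_tables=zonal_tables,
        manifest=manifest,
        truth_maps={"pre": map_pre, "post": map_post},
        viirs=viirs,
    )
    if cfg.write_outputs and cfg.out_dir:
        _write_outputs(result, countries, ranges)
    return result


def _stamp(raster: Raster, cfg: PipelineConfig) -> Raster:
    raster.meta = {**raster.meta, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    return raster


def _write_outputs(result: PipelineResult, countries, ranges) -> None:
    cfg = result.config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for epoch in ("pre", "post"):
        write_raster(_stamp(result.mosaics[epoch].to_raster(), cfg), out / f"mosaic_{epoch}.tif")
        write_raster(_stamp(result.ratio_grids[epoch].to_raster(), cfg), out / f"ratios_{epoch}.tif")
        write_raster(_stamp(result.viirs[epoch], cfg), out / f"viirs_{epoch}.tif")
        for which, ig in result.intensity_grids[epoch].items():
            write_raster(_stamp(ig.to_raster(), cfg), out / f"intensity_{which}_{epoch}.tif")
        for name, ig in result.index_grids[epoch].items():
            write_raster(_stamp(ig.to_raster(), cfg), out / f"index_{name}_{epoch}.tif")
    write_regions(countries, out / "regions_countries.geojson")
    write_regions(ranges, out / "regions_ranges.geojson")
    report_to_csv(result.report, out / "epoch_comparison.csv")
    for name, table in result.zonal_tables.items():
        table.to_csv(out / f"zonal_{name}.csv", index=False, float_format="%.10g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
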