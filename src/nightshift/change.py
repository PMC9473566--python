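"""Europe-wide epoch comparison: medians, IQRs, rank tests, zonal change.

Change is analyzed distributionally — per-epoch medians and interquartile
ranges of all valid pixels, compared with a two-group Kruskal-Wallis rank
test — rather than pixel-by-pixel, because co-registration between epochs
is only good to a few pixels.  Pixels are treated as independent samples;
spatial autocorrelation makes the reported p-values anti-conservative,
which every report footer states.

Quantiles use linear interpolation (type 7), the numpy default; IQR
values depend on this choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely import contains_xy

from .raster import RegionSet

__all__ = [
    "EpochComparison",
    "compare_epochs",
    "percent_change_of_medians",
    "zonal_summary",
    "distribution_report",
    "grid_values",
]

_FOOTER = (
    "Note: pixels are treated as independent samples; spatial autocorrelation "
    "is not corrected for, so test statistics are anti-conservative."
)


@dataclass(frozen=True)
class EpochComparison:
    """Distributional two-epoch summary of one quantity."""

    quantity: str
    n_pre: int
    n_post: int
    median_pre: float
    median_post: float
    iqr_pre: float
    iqr_post: float
    kruskal_h: float
    df: int
    p_value: float
    percent_change: float


def percent_change_of_medians(median_pre: float, median_post: float) -> float:
    """(post - pre) / pre * 100; NaN when the pre-epoch median is zero."""
    if median_pre == 0:
        return float("nan")
    return (median_post - median_pre) / median_pre * 100.0


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25.0, 75.0])
    return float(q3 - q1)


def compare_epochs(values_pre, values_post, quantity: str = "quantity") -> EpochComparison:
    """Median/IQR/Kruskal-Wallis comparison of two pixel samples.

    Both samples must be nonempty with finite values.  An all-identical
    pooled sample is degenerate: H = 0, p = 1, with a warning.
    """
    pre = np.asarray(values_pre, dtype=float).ravel()
    post = np.asarray(values_post, dtype=float).ravel()
    if pre.size == 0 or post.size == 0:
        raise ValueError(f"{quantity}: empty epoch sample")
    if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
        raise ValueError(f"{quantity}: samples must contain only finite values")
    med_pre, med_post = float(np.median(pre)), float(np.median(post))
    if np.ptp(np.concatenate([pre, post])) == 0:
        warnings.warn(f"{quantity}: degenerate all-identical samples", stacklevel=2)
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(pre, post)
    return EpochComparison(
        quantity=quantity,
        n_pre=pre.size,
        n_post=post.size,
        median_pre=med_pre,
        median_post=med_post,
        iqr_pre=_iqr(pre),
        iqr_post=_iqr(post),
        kruskal_h=float(h),
        df=1,
        p_value=float(p),
        percent_change=percent_change_of_medians(med_pre, med_post),
    )


def grid_values(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Valid finite pixel values of a grid, as a flat sample."""
    v = values[valid]
    return v[np.isfinite(v)]


def zonal_summary(
    grid_pre,
    grid_post,
    regions: RegionSet,
    statistic: str = "median",
) -> pd.DataFrame:
    """Per-region epoch statistics and change of one quantity.

    ``grid_pre`` / ``grid_post`` are objects with ``values``, ``valid`` and
    ``geometry`` attributes (ratio bands can be wrapped with
    :class:`GridView`).  Pixel membership is by pixel-center point in
    polygon.  Regions with no valid pixels are flagged empty, never
    silently dropped.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    geom = grid_pre.geometry
    if grid_post.geometry != geom:
        raise ValueError("epoch grids are not co-registered")
    if regions.crs != geom.crs:
        raise ValueError(f"regions CRS {regions.crs!r} != grid CRS {geom.crs!r}")
    stat = np.median if statistic == "median" else np.mean
    x, y = geom.pixel_centers()
    rows = []
    for name, poly in regions:
        inside = contains_xy(poly, x, y)
        row = {"region": name, "n_pixels": int(inside.sum())}
        for label, g in (("pre", grid_pre), ("post", grid_post)):
            vals = g.values[inside & g.valid]
            vals = vals[np.isfinite(vals)]
            row[f"n_valid_{label}"] = int(vals.size)
            row[f"{statistic}_{label}"] = float(stat(vals)) if vals.size else float("nan")
        row["empty"] = row["n_valid_pre"] == 0 or row["n_valid_post"] == 0
        row["change"] = row[f"{statistic}_post"] - row[f"{statistic}_pre"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GridView:
    """Adapter pairing a value plane with a validity mask and geometry."""

    values: np.ndarray
    valid: np.ndarray
    geometry: object


def distribution_report(
    comparisons: list[EpochComparison],
    samples: dict | None = None,
    n_bins: int = 40,
) -> dict:
    """Summary table plus fixed-bin histogram data for both epochs.

    ``samples`` optionally maps quantity -> (pre_values, post_values) to
    produce histogram counts on shared bin edges.  Deterministic: the same
    inputs yield byte-identical CSV/Markdown output.
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    table = pd.DataFrame([c.__dict__ for c in comparisons])
    histograms = {}
    if samples:
        for name, (pre, post) in samples.items():
            pre = np.asarray(pre, dtype=float)
            post = np.asarray(post, dtype=float)
            pooled = np.concatenate([pre, post])
            edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
            histograms[name] = {
                "bin_edges": edges,
                "counts_pre": np.histogram(pre, bins=edges)[0],
                "counts_post": np.histogram(post, bins=edges)[0],
            }
    return {"table": table, "histograms": histograms, "footer": _FOOTER}


def report_to_csv(report: dict, path) -> None:
    report["table"].to_csv(path, index=False, float_format="%.10g")


def report_to_markdown(report: dict) -> str:
    lines = [report["table"].to_markdown(index=False, floatfmt=".4g"), "", report["footer"]]
    return "\n".join(lines)


def plot_epoch_histograms(report: dict, path) -> None:
    """Paired per-epoch histograms of every quantity in a report (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hists = report.get("histograms", {})
    if not hists:
        raise ValueError("report carries no histogram data")
    n = len(hists)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.4 * n), squeeze=False)
    for ax, (name, h) in zip(axes[:, 0], hists.items()):
        centers = 0.5 * (h["bin_edges"][:-1] + h["bin_edges"][1:])
        width = np.diff(h["bin_edges"])
        ax.bar(centers, h["counts_pre"], width=width, alpha=0.5, label="pre")
        ax.bar(centers, h["counts_post"], width=width, alpha=0.5, label="post")
        ax.set_ylabel("pixels")
        ax.set_title(name, fontsize=9)
        ax.legend(fontsize=8)
    axes[-1, 0].set_xlabel("value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
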