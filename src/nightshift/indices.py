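"""Satellite-corrected intensities and biological risk-index grids.

The panchromatic satellite band is blind to blue, so camera-band
intensities are estimated by multiplying the satellite radiance by a
ratio-dependent correction factor:

    G = VIIRS * gv(G/R),   gv(x) = a * b**x           (exponential)
    B = VIIRS * bv(B/G),   bv(x) = c0 + c1*x + c2*x^2 (quadratic)
    P = VIIRS * pv(G/R),   pv(x) = p0 * p1**x         (phototaxis)

The shipped coefficient defaults are the published point estimates with
bootstrap 95% CIs: a=0.21 (+0.21/-0.06), b=1.5 (+0.09/-0.30);
c0=-0.03 (+0.03/-0.04), c1=0.6 (+/-0.20), c2=1.3 (+0.20/-0.30);
p0=0.23 (+0.05/-0.03), p1=0.21 (+0.06/-0.21).  Coefficient uncertainty is
propagated by evaluating the model at every CI corner.  Biological index
grids (MSI, SLI, relative phototaxis) come from fitted ratio-index models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .raster import GridGeometry, Raster
from .ratiofit import RatioIndexModel
from .ratios import MaskReason, RatioGrid

__all__ = [
    "RegressionCoefficients",
    "IntensityGrid",
    "IndexGrid",
    "g_over_viirs",
    "b_over_viirs",
    "p_over_viirs",
    "estimate_intensity",
    "propagate_ci",
    "index_grid",
]


@dataclass(frozen=True)
class RegressionCoefficients:
    """Named coefficients with point values and 95% CIs (low, point, high)."""

    name: str
    params: dict  # param -> (low, point, high)

    def __post_init__(self):
        for key, (lo, pt, hi) in self.params.items():
            if not lo <= pt <= hi:
                raise ValueError(f"{self.name}.{key}: CI must bracket the point value")

    def point(self, key: str) -> float:
        return self.params[key][1]

    def interval(self, key: str) -> tuple[float, float]:
        lo, _, hi = self.params[key]
        return lo, hi

    @classmethod
    def g_over_viirs_default(cls) -> "RegressionCoefficients":
        return cls("G_over_VIIRS", {"a": (0.15, 0.21, 0.42), "b": (1.2, 1.5, 1.59)})

    @classmethod
    def b_over_viirs_default(cls) -> "RegressionCoefficients":
        return cls(
            "B_over_VIIRS",
            {"c0": (-0.07, -0.03, 0.0), "c1": (0.4, 0.6, 0.8), "c2": (1.0, 1.3, 1.5)},
        )

    @classmethod
    def p_over_viirs_default(cls) -> "RegressionCoefficients":
        return cls("P_over_VIIRS", {"p0": (0.20, 0.23, 0.28), "p1": (0.0, 0.21, 0.27)})

    def to_json(self, path=None) -> str:
        text = json.dumps({"name": self.name, "params": self.params}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RegressionCoefficients":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(doc["name"], {k: tuple(v) for k, v in doc["params"].items()})


def _check_nonnegative(x):
    x = np.asarray(x, dtype=float)
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("ratio input must be nonnegative")
    return x


def g_over_viirs(g_over_r, coeffs: RegressionCoefficients | None = None):
    """Exponential G-band correction factor a * b**(G/R)."""
    if coeffs is None:
        coeffs = RegressionCoefficients.g_over_viirs_default()
    x = _check_nonnegative(g_over_r)
    return coeffs.point("a") * np.power(coeffs.point("b"), x)


def b_over_viirs(b_over_g, coeffs: RegressionCoefficients | None = None):
    """Quadratic B-band correction factor c0 + c1*x + c2*x**2 (pre-clamp).

    Negative outputs (the quadratic dips to -0.03 at x = 0) are clamped to
    zero only when building intensity grids, never here.
    """
    if coeffs is None:
        coeffs = RegressionCoefficients.b_over_viirs_default()
    x = np.asarray(b_over_g, dtype=float)
    return coeffs.point("c0") + coeffs.point("c1") * x + coeffs.point("c2") * x**2


def p_over_viirs(g_over_r, coeffs: RegressionCoefficients | None = None):
    """Phototaxis correction factor p0 * p1**(G/R): decreasing in G/R,
    since redder light draws a smaller phototaxic response."""
    if coeffs is None:
        coeffs = RegressionCoefficients.p_over_viirs_default()
    x = _check_nonnegative(g_over_r)
    return coeffs.point("p0") * np.power(coeffs.point("p1"), x)


_MODEL_FUNCS = {
    "G": ("g_over_r", g_over_viirs, RegressionCoefficients.g_over_viirs_default),
    "B": ("b_over_g", b_over_viirs, RegressionCoefficients.b_over_viirs_default),
    "P": ("g_over_r", p_over_viirs, RegressionCoefficients.p_over_viirs_default),
}


@dataclass
class IntensityGrid:
    """Estimated band intensity (nW cm^-2 sr^-1) with inherited masks."""

    values: np.ndarray
    reason: np.ndarray
    which: str  # G, B or P
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return self.reason == MaskReason.VALID

    def to_raster(self) -> Raster:
        return Raster(
            np.stack([self.values, self.reason.astype(float)]),
            self.geometry,
            band_names=(f"{self.which}_intensity", "mask_reason"),
            meta=self.meta,
        )


def estimate_intensity(
    viirs: Raster,
    rg: RatioGrid,
    which: str = "G",
    coeffs: RegressionCoefficients | None = None,
    model: RatioIndexModel | None = None,
) -> IntensityGrid:
    """Per-pixel VIIRS radiance times the ratio-model correction factor.

    ``model`` (a refitted ratio relationship) overrides ``coeffs`` (the
    published closed-form defaults).  The mask is the union of the ratio
    grid's mask and non-finite satellite pixels; negative estimates are
    clamped to zero with a counter recorded.
    """
    if which not in _MODEL_FUNCS:
        raise ValueError("which must be G, B or P")
    if viirs.geometry != rg.geometry:
        raise ValueError("VIIRS raster is not co-registered with the ratio grid")
    pred_name, func, default = _MODEL_FUNCS[which]
    ratio = getattr(rg, pred_name)
    v = viirs.data[0]
    valid = rg.valid & np.isfinite(v)
    if model is not None:
        factor = model.predict(np.where(valid, ratio, 0.0), clamp=False)
    else:
        factor = func(np.where(valid, ratio, 0.0), coeffs or default())
    values = np.where(valid, v * factor, np.nan)
    n_clamped = int(np.sum(values[valid] < 0))
    values = np.where(valid, np.maximum(values, 0.0), np.nan)
    reason = rg.reason.copy()
    reason[rg.valid & ~valid] = MaskReason.OFF_SCENE
    return IntensityGrid(
        values=values,
        reason=reason,
        which=which,
        geometry=rg.geometry,
        meta={"n_negative_clamped": n_clamped, "model": "refit" if model else "published"},
    )


def propagate_ci(which: str, x, coeffs: RegressionCoefficients | None = None):
    """(low, point, high) model outputs from CI-corner evaluation.

    Evaluates the correction factor at every corner of the coefficient
    CI box (plus the point estimate) and takes the envelope; guarantees
    low <= point <= high everywhere.
    """
    if which not in _MODEL_FUNCS:
        raise ValueError("which must be G, B or P")
    _, _, default = _MODEL_FUNCS[which]
    coeffs = coeffs or default()
    x = np.asarray(x, dtype=float)
    keys = list(coeffs.params)

    def evaluate(values: dict):
        c = RegressionCoefficients(coeffs.name, {k: (v, v, v) for k, v in values.items()})
        if which == "G":
            return g_over_viirs(x, c)
        if which == "B":
            return b_over_viirs(x, c)
        return p_over_viirs(x, c)

    point = evaluate({k: coeffs.point(k) for k in keys})
    lo = point.copy()
    hi = point.copy()
    for bits in range(2 ** len(keys)):
        corner = {
            k: coeffs.interval(k)[(bits >> i) & 1] for i, k in enumerate(keys)
        }
        y = evaluate(corner)
        lo = np.minimum(lo, y)
        hi = np.maximum(hi, y)
    return lo, point, hi


@dataclass
class IndexGrid:
    """Dimensionless biological index per pixel (MSI, SLI or phototaxis)."""

    values: np.ndarray
    reason: np.ndarray
    index_name: str
    predictor: str
    extrapolated: np.ndarray
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return self.reason == MaskReason.VALID

    def to_raster(self) -> Raster:
        return Raster(
            np.stack(
                [self.values, self.reason.astype(float), self.extrapolated.astype(float)]
            ),
            self.geometry,
            band_names=(self.index_name, "mask_reason", "extrapolated"),
            meta=self.meta,
        )


def index_grid(rg: RatioGrid, model: RatioIndexModel) -> IndexGrid:
    """Map a ratio band through a fitted ratio-index relationship.

    Values are clamped to the index's physical range; pixels whose ratio
    lies outside the model's fitted domain are still computed but flagged
    extrapolated.
    """
    if model.predictor not in ("b_over_g", "g_over_r"):
        raise ValueError(f"model predictor {model.predictor!r} has no ratio band")
    ratio = getattr(rg, model.predictor)
    valid = rg.valid
    values = np.where(valid, model.predict(np.where(valid, ratio, 0.0)), np.nan)
    extrap = valid & model.extrapolated(np.where(valid, ratio, model.domain[0]))
    return IndexGrid(
        values=values,
        reason=rg.reason.copy(),
        index_name=model.response,
        predictor=model.predictor,
        extrapolated=extrap,
        geometry=rg.geometry,
        meta={"family": model.family, "rmse": model.rmse},
    )
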