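"""Fitting "established relationships" between color ratios and indices.

A camera's B/G or G/R ratio is a one-number proxy for a lamp spectrum; the
biological indices (MSI, SLI, relative phototaxis) and the satellite-band
correction factors (G/VIIRS, B/VIIRS, P/VIIRS) are smooth functions of it
over the space of real lighting spectra.  This module fits those functions
over a lamp library by least squares, in two families:

* ``quadratic``  : y = c0 + c1*x + c2*x**2   (used with B/G predictors)
* ``exponential``: y = a * b**x              (used with G/R predictors)

Coefficient uncertainty comes from a seeded nonparametric bootstrap
(leverage-adjusted residual resampling, expanded percentile 95% intervals,
1000 replicates by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .lamps import mixture_library, viirs_signal
from .spectra import (
    CameraResponse,
    SpectralPowerDistribution,
    band_signal,
    color_ratios,
    melatonin_suppression_action,
    phototaxis_action,
    scotopic_starlight_action,
    spectral_index,
)

__all__ = ["RatioIndexModel", "RatioIndexRegression", "fit_ratio_index_curve", "library_ratio_index_samples"]

_FAMILIES = ("quadratic", "exponential")
#: Responses whose physical range is [0, 1]-like and should be clamped low.
_CLAMPED_RESPONSES = ("msi", "sli")


def _eval_family(family: str, coef: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if family == "quadratic":
        return coef[0] + coef[1] * x + coef[2] * x**2
    if family == "exponential":
        return coef[0] * np.power(coef[1], x)
    raise ValueError(f"unknown family {family!r}")


def _fit_family(family: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n_par = 3 if family == "quadratic" else 2
    if x.size < n_par:
        raise ValueError(f"need at least {n_par} samples to fit a {family} model")
    if family == "quadratic":
        vander = np.column_stack([np.ones_like(x), x, x**2])
        if np.linalg.matrix_rank(vander) < 3:
            raise np.linalg.LinAlgError(
                "rank-deficient design: predictor values do not span a quadratic"
            )
        coef, *_ = np.linalg.lstsq(vander, y, rcond=None)
        return coef
    # exponential: seed with a log-linear fit on the positive responses
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError(
            "rank-deficient design: constant predictor cannot identify an exponential"
        )
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(np.exp(slope)))
    else:
        p0 = (max(float(np.mean(y)), 1e-6), 1.0)
    coef, _ = curve_fit(
        lambda xx, a, b: a * np.power(b, xx),
        x,
        y,
        p0=p0,
        bounds=([0.0, 1e-9], [np.inf, np.inf]),
        maxfev=10000,
    )
    return np.asarray(coef)


@dataclass
class RatioIndexModel:
    """Fitted ratio -> index (or ratio -> band/VIIRS) relationship."""

    predictor: str  # "b_over_g" or "g_over_r"
    response: str  # e.g. "msi", "sli", "phototaxis", "g_over_viirs"
    family: str
    coefficients: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    rmse: float
    domain: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.ci_low = np.asarray(self.ci_low, dtype=float)
        self.ci_high = np.asarray(self.ci_high, dtype=float)
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (
            np.all(self.ci_low <= self.coefficients + 1e-12)
            and np.all(self.coefficients <= self.ci_high + 1e-12)
        ):
            raise ValueError("CI bounds must bracket the point estimates")

    def predict(self, x, clamp: bool = True) -> np.ndarray:
        """Model prediction; MSI/SLI responses are clamped into [0, 1]."""
        y = _eval_family(self.family, self.coefficients, x)
        if clamp and self.response in _CLAMPED_RESPONSES:
            y = np.clip(y, 0.0, 1.0)
        elif clamp:
            y = np.maximum(y, 0.0)
        return y

    def extrapolated(self, x) -> np.ndarray:
        """Boolean mask of predictor values outside the fitted domain."""
        x = np.asarray(x, dtype=float)
        return (x < self.domain[0]) | (x > self.domain[1])

    def to_json(self, path=None) -> str:
        doc = {
            "predictor": self.predictor,
            "response": self.response,
            "family": self.family,
            "coefficients": self.coefficients.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "rmse": self.rmse,
            "domain": list(self.domain),
            "meta": self.meta,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RatioIndexModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            predictor=doc["predictor"],
            response=doc["response"],
            family=doc["family"],
            coefficients=np.asarray(doc["coefficients"]),
            ci_low=np.asarray(doc["ci_low"]),
            ci_high=np.asarray(doc["ci_high"]),
            rmse=doc["rmse"],
            domain=tuple(doc["domain"]),
            meta=doc.get("meta", {}),
        )


class RatioIndexRegression:
    """Estimator-style wrapper: ``fit(x, y)`` then ``predict(x)``.

    Thin object API over the same least-squares + bootstrap machinery used
    by :func:`fit_ratio_index_curve`.
    """

    def __init__(
        self,
        family: str = "quadratic",
        predictor: str = "b_over_g",
        response: str = "msi",
        n_boot: int = 1000,
        seed: int = 0,
    ):
        if family not in _FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.predictor = predictor
        self.response = response
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, x, y) -> "RatioIndexRegression":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        coef = _fit_family(self.family, x, y)
        resid = y - _eval_family(self.family, coef, x)
        rmse = float(np.sqrt(np.mean(resid**2)))
        lo, hi = self._bootstrap(x, y, coef)
        self.model_ = RatioIndexModel(
            predictor=self.predictor,
            response=self.response,
            family=self.family,
            coefficients=coef,
            ci_low=lo,
            ci_high=hi,
            rmse=rmse,
            domain=(float(x.min()), float(x.max())),
            meta={"n": int(x.size), "n_boot": self.n_boot, "seed": self.seed},
        )
        return self

    def _bootstrap(self, x, y, coef):
        """Leverage-adjusted residual bootstrap with expanded percentile
        levels.

        The library design is fixed (the same spectra enter every fit), so
        residual resampling is the appropriate scheme; raw case resampling
        underestimates coefficient variability at this sample size and its
        percentile intervals undercover the intercept.  Residuals are
        inflated by 1/sqrt(1-h_ii) (h from the linearized design) and the
        percentile levels widened by the small-sample t adjustment, which
        restores near-nominal 95% coverage.
        """
        from scipy import stats as _stats

        rng = np.random.default_rng(self.seed)
        n = x.size
        fitted = _eval_family(self.family, coef, x)
        resid = y - fitted
        if self.family == "quadratic":
            design = np.column_stack([np.ones(n), x, x**2])
        else:  # local linearization of a * b**x at the fitted coefficients
            a, b = coef
            design = np.column_stack([np.power(b, x), a * x * np.power(b, np.maximum(x - 1, 0))])
        n_par = design.shape[1]
        try:
            hat = design @ np.linalg.pinv(design.T @ design) @ design.T
            lev = np.clip(np.diag(hat), 0.0, 1.0 - 1e-6)
        except np.linalg.LinAlgError:
            lev = np.zeros(n)
        adj = resid / np.sqrt(1.0 - lev)
        adj = adj - adj.mean()
        draws = []
        for _ in range(self.n_boot):
            yb = fitted + rng.choice(adj, size=n, replace=True)
            try:
                draws.append(_fit_family(self.family, x, yb))
            except (np.linalg.LinAlgError, RuntimeError):
                continue
        if len(draws) < max(10, self.n_boot // 10):
            # Too few successful refits to estimate spread; fall back to
            # zero-width intervals at the point estimate.
            return coef.copy(), coef.copy()
        draws = np.asarray(draws)
        dof = max(n - n_par, 1)
        t_adj = _stats.t.ppf(0.975, dof) * np.sqrt(n / dof)
        level = float(_stats.norm.cdf(-t_adj) * 100.0)
        lo = np.percentile(draws, level, axis=0)
        hi = np.percentile(draws, 100.0 - level, axis=0)
        # the envelope must bracket the full-sample fit
        return np.minimum(lo, coef), np.maximum(hi, coef)

    def predict(self, x, clamp: bool = True) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit() must be called before predict()")
        return self.model_.predict(x, clamp=clamp)


def library_ratio_index_samples(
    spds: list[SpectralPowerDistribution],
    predictor: str,
    response: str,
    camera: CameraResponse | None = None,
    reference: SpectralPowerDistribution | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute (ratio, response) pairs over a spectrum library.

    Responses: ``msi``, ``sli``, ``phototaxis`` (photopically normalized
    indices) or ``g_over_viirs`` / ``b_over_viirs`` / ``p_over_viirs``
    (band-to-satellite intensity ratios).
    """
    if camera is None:
        camera = CameraResponse.default()
    actions = {
        "msi": melatonin_suppression_action(),
        "sli": scotopic_starlight_action(),
        "phototaxis": phototaxis_action(),
    }
    xs, ys = [], []
    for spd in spds:
        cr = color_ratios(spd, camera)
        x = {"b_over_g": cr.b_over_g, "g_over_r": cr.g_over_r}[predictor]
        if response in actions:
            y = spectral_index(spd, actions[response], reference=reference)
        elif response in ("g_over_viirs", "b_over_viirs", "p_over_viirs"):
            v = viirs_signal(spd)
            if v <= 0:
                y = float("nan")
            elif response == "g_over_viirs":
                y = band_signal(spd, camera.band("green")) / v
            elif response == "b_over_viirs":
                y = band_signal(spd, camera.band("blue")) / v
            else:
                y = band_signal(spd, phototaxis_action()) / v
        else:
            raise ValueError(f"unknown response {response!r}")
        xs.append(x)
        ys.append(y)
    return np.asarray(xs), np.asarray(ys)


def fit_ratio_index_curve(
    spds: list[SpectralPowerDistribution] | None = None,
    predictor: str = "b_over_g",
    response: str = "msi",
    family: str | None = None,
    camera: CameraResponse | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> RatioIndexModel:
    """Fit a ratio -> index relationship over a lamp-spectrum library.

    ``spds`` defaults to the shipped library (pure classes + pairwise
    mixtures).  ``family`` defaults by predictor: quadratic for B/G,
    exponential for G/R, mirroring the functional forms used for the
    satellite-band corrections.
    """
    if spds is None:
        spds = mixture_library()
    if family is None:
        family = "quadratic" if predictor == "b_over_g" else "exponential"
    x, y = library_ratio_index_samples(spds, predictor, response, camera=camera)
    reg = RatioIndexRegression(
        family=family, predictor=predictor, response=response, n_boot=n_boot, seed=seed
    ).fit(x, y)
    return reg.model_
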