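"""Vegetation indices, empirical yield-transfer regression and validation.

Three normalized-difference indices are computed from the sensor bands
nearest the nominal wavelengths: NDVI (NIR 832 / red 663 nm), GNDVI
(NIR / green 560 nm) and NDRE (NIR / red-edge 722 nm).  Biomass and
grain yield (t/ha) are then estimated from retrieved LAI or an index by
simple two-coefficient regressions (linear, exponential, power or
logarithmic), the best growth stage is selected from a per-date R-squared
time series, and held-out predictions are scored with R-squared
(squared Pearson correlation), RMSE and MAE.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .bands import BandSpectrum, nearest_band

__all__ = [
    "VIDefinition",
    "NDVI",
    "GNDVI",
    "NDRE",
    "VI_DEFINITIONS",
    "compute_vi",
    "RegressionModel",
    "fit_model",
    "predict",
    "stage_r2_series",
    "EvalMetrics",
    "evaluate",
    "FAMILIES",
    "DEFAULT_FAMILY_BY_PREDICTOR",
]

FAMILIES = ("linear", "exponential", "power", "logarithmic")

#: Regression family used per predictor unless the caller asks for
#: automatic best-family selection: indices built on saturating bands
#: stay linear, NDVI needs the exponential to counter its saturation.
DEFAULT_FAMILY_BY_PREDICTOR = {
    "lai": "linear",
    "ndvi": "exponential",
    "gndvi": "linear",
    "ndre": "linear",
}


@dataclass(frozen=True)
class VIDefinition:
    """A normalized-difference index (b1 - b2) / (b1 + b2).

    ``numerator_nm`` is the band whose reflectance enters positively
    (the NIR for all three standard indices); ``denominator_nm`` the
    contrasting band (red, green or red-edge).
    """

    name: str
    numerator_nm: float
    denominator_nm: float


NDVI = VIDefinition("ndvi", 832.0, 663.0)
GNDVI = VIDefinition("gndvi", 832.0, 560.0)
NDRE = VIDefinition("ndre", 832.0, 722.0)
VI_DEFINITIONS = (NDVI, GNDVI, NDRE)


def compute_vi(spec: BandSpectrum, vi: VIDefinition) -> float:
    """Normalized difference from the nearest active bands to the nominals."""
    i1 = nearest_band(spec.band_set, vi.numerator_nm)
    i2 = nearest_band(spec.band_set, vi.denominator_nm)
    if i1 == i2:
        raise ValueError(
            f"{vi.name}: both nominal wavelengths resolve to the same band "
            f"({spec.band_set.active_centers[i1]:g} nm)"
        )
    b1, b2 = spec.values[i1], spec.values[i2]
    denom = b1 + b2
    if denom == 0:
        raise ValueError(f"{vi.name}: zero denominator (both bands reflect 0)")
    return float((b1 - b2) / denom)


@dataclass(frozen=True)
class RegressionModel:
    """Two-coefficient empirical transfer model y = f(x; a, b).

    linear: a*x + b;  exponential: a*exp(b*x);  power: a*x**b;
    logarithmic: a + b*ln(x).  ``r2`` is the coefficient of
    determination (1 - SS_res/SS_tot) on the fitting data.
    """

    family: str
    a: float
    b: float
    r2: float
    predictor: str = "x"
    response: str = "y"

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: "str | Path") -> "RegressionModel":
        return cls(**json.loads(Path(path).read_text()))


def _check_domain(x: np.ndarray, family: str) -> None:
    if family in ("power", "logarithmic") and np.any(x <= 0):
        raise ValueError(f"{family} regression requires strictly positive predictors")


def predict(model: RegressionModel, x: "float | np.ndarray") -> "float | np.ndarray":
    """Evaluate the family formula at x (t/ha for yield models)."""
    xa = np.asarray(x, dtype=float)
    _check_domain(np.atleast_1d(xa), model.family)
    if model.family == "linear":
        out = model.a * xa + model.b
    elif model.family == "exponential":
        out = model.a * np.exp(model.b * xa)
    elif model.family == "power":
        out = model.a * xa**model.b
    elif model.family == "logarithmic":
        out = model.a + model.b * np.log(xa)
    else:
        raise ValueError(f"unknown family {model.family!r}")
    return float(out) if np.ndim(x) == 0 else out


def fit_model(
    x: np.ndarray,
    y: np.ndarray,
    family: str = "linear",
    predictor: str = "x",
    response: str = "y",
) -> RegressionModel:
    """Least-squares fit of one family on the original response scale.

    Exponential and power fits are solved iteratively (Levenberg-
    Marquardt) starting from the log-linearised closed form, so the
    reported coefficients minimise squared error in y, not in log y.
    Constant responses are degenerate: R2 is defined as 0 and the linear
    fit returns (a=0, b=mean(y)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points to fit a transfer model")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    _check_domain(x, family)

    ss_tot = float(((y - y.mean()) ** 2).sum())
    if family == "linear":
        if ss_tot == 0:
            return RegressionModel("linear", 0.0, float(y.mean()), 0.0, predictor, response)
        a, b = np.polyfit(x, y, 1)
    elif family == "logarithmic":
        b, a = np.polyfit(np.log(x), y, 1)
    else:
        # log-linearised start, then iterative least squares in y
        pos = y > 0
        if pos.sum() >= 2:
            if family == "exponential":
                b0, loga = np.polyfit(x[pos], np.log(y[pos]), 1)
            else:
                b0, loga = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
            p0 = (math.exp(loga), b0)
        else:
            p0 = (1.0, 0.1)
        fn = (
            (lambda xx, aa, bb: aa * np.exp(bb * xx))
            if family == "exponential"
            else (lambda xx, aa, bb: aa * xx**bb)
        )
        try:
            (a, b), _ = curve_fit(fn, x, y, p0=p0, maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(
                f"{family} fit did not converge (start a={p0[0]:.4g}, b={p0[1]:.4g}): {err}"
            ) from None

    model = RegressionModel(family, float(a), float(b), 0.0, predictor, response)
    if ss_tot == 0:
        return model
    resid = y - predict(model, x)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return RegressionModel(family, float(a), float(b), r2, predictor, response)


def stage_r2_series(
    records: "dict[int, tuple[np.ndarray, np.ndarray]]",
    family: str = "linear",
):
    """Per-date fit quality and the best date for yield estimation.

    ``records`` maps each acquisition date (days after sowing) to the
    paired (predictor, response) arrays of the calibration points.
    ``family`` is one of the regression families or ``"auto"`` to pick
    the best-fitting family per date.  Dates with fewer than 3 pairs are
    skipped with a warning.  Returns (series, best_das): ``series`` is a
    list of (das, r2, family) sorted by date; ``best_das`` maximises R2,
    ties resolved toward the earliest date.
    """
    series: "list[tuple[int, float, str]]" = []
    for das in sorted(records):
        x, y = records[das]
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3:
            warnings.warn(f"date {das} DAS has {x.size} < 3 points; skipped", stacklevel=2)
            continue
        if family == "auto":
            best = None
            for fam in FAMILIES:
                try:
                    m = fit_model(x, y, fam)
                except (ValueError, RuntimeError):
                    continue
                if best is None or m.r2 > best.r2:
                    best = m
            if best is None:
                warnings.warn(f"date {das} DAS: no family fit; skipped", stacklevel=2)
                continue
            series.append((das, best.r2, best.family))
        else:
            m = fit_model(x, y, family)
            series.append((das, m.r2, family))
    if not series:
        raise ValueError("no date had enough points to fit")
    best_das = max(series, key=lambda rec: (rec[1], -rec[0]))[0]
    return series, best_das


@dataclass(frozen=True)
class EvalMetrics:
    """Cross-validation scores: squared Pearson r2, RMSE and MAE (t/ha)."""

    r2: float
    rmse: float
    mae: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(pred: np.ndarray, obs: np.ndarray) -> EvalMetrics:
    """Score predictions against ground observations.

    r2 is the squared Pearson correlation of the predicted-vs-observed
    scatter (insensitive to bias); RMSE and MAE carry the units of the
    response.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D arrays of equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 observations to evaluate")
    if np.all(obs == obs[0]):
        raise ValueError("observations have zero variance; r2 undefined")
    err = pred - obs
    if np.all(pred == pred[0]):
        r2 = 0.0  # degenerate constant prediction: no linear association
    else:
        r2 = float(pearsonr(pred, obs).statistic ** 2)
    return EvalMetrics(
        r2=r2,
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        n=pred.size,
    )
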