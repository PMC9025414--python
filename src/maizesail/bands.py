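"""Sensor band grid, band exclusions and Gaussian spectral resampling.

The airborne sensor view of the world used throughout this package is a
uniform grid of Gaussian bands (constant FWHM) spanning 400-850 nm.  Fine
1-nm spectra produced by the radiative-transfer forward models are reduced
to that grid by a truncated, renormalised Gaussian spectral response
function.  A handful of bands affected by oxygen absorption and sensor
noise are carried along but flagged inactive, so that band bookkeeping
(61 centres, 55 active) is explicit rather than implied by array length.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BandSet",
    "BandSpectrum",
    "make_band_grid",
    "apply_exclusions",
    "resample",
    "resample_matrix",
    "nearest_band",
    "default_band_set",
    "write_band_set",
    "read_band_set",
    "write_spectra_table",
    "read_spectra_table",
    "DEFAULT_EXCLUDED_NM",
    "FWHM_TO_SIGMA",
]

#: FWHM of a Gaussian divided by its standard deviation: 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Band centres excluded from analysis (oxygen absorption / sensor noise), nm.
DEFAULT_EXCLUDED_NM = (751.0, 759.0, 766.0, 773.0, 810.0, 818.0)

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class Spectrum:
    """A spectral quantity sampled on a uniform 1-nm wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing, uniformly spaced wavelengths in nm.
    values
        One finite value per wavelength.  When the spectrum is a
        reflectance the values must lie in [0, 1]; this is enforced by
        the radiative-transfer modules, not here, because a Spectrum may
        also hold e.g. absorption coefficients.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a Spectrum needs at least two samples")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("wavelengths must be uniformly spaced")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


@dataclass(frozen=True)
class BandSet:
    """A set of Gaussian sensor bands with a shared FWHM and an active mask."""

    centers: np.ndarray
    fwhm: float
    active_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("centers must be a non-empty 1-D array")
        if np.any(np.diff(c) <= 0):
            raise ValueError("centers must be strictly increasing")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        mask = self.active_mask
        mask = np.ones(c.size, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        if mask.shape != c.shape:
            raise ValueError("active_mask length must match centers")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "fwhm", float(self.fwhm))
        object.__setattr__(self, "active_mask", mask)

    @property
    def n_bands(self) -> int:
        return int(self.centers.size)

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    @property
    def active_centers(self) -> np.ndarray:
        return self.centers[self.active_mask]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandSet):
            return NotImplemented
        return (
            self.centers.shape == other.centers.shape
            and np.array_equal(self.centers, other.centers)
            and self.fwhm == other.fwhm
            and np.array_equal(self.active_mask, other.active_mask)
        )


@dataclass(frozen=True)
class BandSpectrum:
    """Reflectance on the active bands of a :class:`BandSet`."""

    band_set: BandSet
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.band_set.n_active:
            raise ValueError(
                f"expected {self.band_set.n_active} values (one per active band), got {v.size}"
            )
        object.__setattr__(self, "values", v)


def make_band_grid(min_nm: float, max_nm: float, step_nm: float) -> BandSet:
    """Build a uniform band grid from ``min_nm`` to ``max_nm`` inclusive.

    The FWHM of every band equals the grid step.  The range must be an
    integer multiple of the step (within 1e-9 nm).
    """
    if not min_nm < max_nm:
        raise ValueError(f"need min_nm < max_nm, got {min_nm} >= {max_nm}")
    if not step_nm > 0:
        raise ValueError("step_nm must be positive")
    span = max_nm - min_nm
    n_steps = round(span / step_nm)
    residual = abs(span - n_steps * step_nm)
    if n_steps < 1 or residual > _GRID_TOL:
        raise ValueError(
            f"range {min_nm}-{max_nm} nm is not a multiple of step {step_nm} nm "
            f"(residual {span - round(span / step_nm) * step_nm:g} nm)"
        )
    centers = min_nm + step_nm * np.arange(n_steps + 1)
    centers[-1] = max_nm  # exact endpoint despite float accumulation
    return BandSet(centers=centers, fwhm=step_nm)


def apply_exclusions(
    bands: BandSet, nominal_nm: "list[float] | tuple[float, ...]", tol_nm: float = 4.0
) -> BandSet:
    """Deactivate, for each nominal wavelength, the nearest band centre.

    Nominal wavelengths are matched to centres within ``tol_nm``; printed
    exclusion wavelengths are typically rounded so they rarely sit exactly
    on the grid.  Centres are never removed, only masked, and re-applying
    the same list is idempotent.
    """
    if not tol_nm > 0:
        raise ValueError("tol_nm must be positive")
    mask = bands.active_mask.copy()
    hit: dict[int, float] = {}
    for nom in nominal_nm:
        dist = np.abs(bands.centers - nom)
        idx = int(np.argmin(dist))
        if dist[idx] > tol_nm:
            raise ValueError(
                f"no band centre within {tol_nm} nm of nominal {nom} nm "
                f"(closest is {bands.centers[idx]:g} nm)"
            )
        if idx in hit and hit[idx] != nom:
            raise ValueError(
                f"nominal wavelengths {hit[idx]} and {nom} nm both map to "
                f"band centre {bands.centers[idx]:g} nm"
            )
        hit[idx] = nom
        mask[idx] = False
    return BandSet(centers=bands.centers, fwhm=bands.fwhm, active_mask=mask)


def default_band_set() -> BandSet:
    """The canonical 400-850 nm grid: 61 centres at 7.5 nm, 55 active."""
    return apply_exclusions(make_band_grid(400.0, 850.0, 7.5), DEFAULT_EXCLUDED_NM)


def resample_matrix(bands: BandSet, wavelengths: np.ndarray) -> np.ndarray:
    """Weight matrix W (n_active x n_fine) so that band values = W @ fine values.

    Each row is a Gaussian of sigma = FWHM/2.3548 centred on the band,
    truncated at +/- 2 FWHM and renormalised to sum to one over the fine
    grid points available (edge bands keep their truncated support).
    """
    wl = np.asarray(wavelengths, dtype=float)
    steps = np.diff(wl)
    if wl.size < 2 or np.any(steps <= 0) or not np.allclose(steps, 1.0, rtol=0, atol=1e-6):
        raise ValueError("resampling requires a uniform 1-nm wavelength grid")
    sigma = bands.fwhm / FWHM_TO_SIGMA
    half = 2.0 * bands.fwhm
    centers = bands.active_centers
    for c in centers:
        if c - half > wl[-1] or c + half < wl[0]:
            raise ValueError(f"spectrum does not cover band at {c:g} nm")
    dist = wl[None, :] - centers[:, None]
    w = np.exp(-0.5 * (dist / sigma) ** 2)
    w[np.abs(dist) > half] = 0.0
    return w / w.sum(axis=1, keepdims=True)


def resample(spec: Spectrum, bands: BandSet) -> BandSpectrum:
    """Reduce a fine-grid spectrum to sensor bands (active bands only)."""
    w = resample_matrix(bands, spec.wavelengths)
    return BandSpectrum(band_set=bands, values=w @ spec.values)


def nearest_band(bands: BandSet, nominal_nm: float) -> int:
    """Index (into the active bands) of the active centre nearest ``nominal_nm``.

    Equidistant ties are broken toward the lower wavelength.  The returned
    index addresses :attr:`BandSpectrum.values` directly.
    """
    centers = bands.active_centers
    if centers.size == 0:
        raise ValueError("band set has no active bands")
    dist = np.abs(centers - nominal_nm)
    return int(np.argmin(dist))  # argmin takes the first (lower-wavelength) tie


# ---------------------------------------------------------------------------
# text serialization

def write_band_set(bands: BandSet, path: "str | Path") -> None:
    df = pd.DataFrame(
        {
            "center_nm": bands.centers,
            "fwhm_nm": np.full(bands.n_bands, bands.fwhm),
            "active": bands.active_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_band_set(path: "str | Path") -> BandSet:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("center_nm", "fwhm_nm", "active"):
        if col not in df.columns:
            raise ValueError(f"band-set file missing column {col!r}")
    fwhm = df["fwhm_nm"].to_numpy(dtype=float)
    if not np.all(fwhm == fwhm[0]):
        raise ValueError("band-set file must have a single shared FWHM")
    return BandSet(
        centers=df["center_nm"].to_numpy(dtype=float),
        fwhm=float(fwhm[0]),
        active_mask=df["active"].to_numpy(dtype=int).astype(bool),
    )


def band_columns(bands: BandSet) -> "list[str]":
    """Column names for the active bands in a point-spectra table."""
    return [f"b{c:g}" for c in bands.active_centers]


def write_spectra_table(df: pd.DataFrame, path: "str | Path") -> None:
    """Write a point-spectra table (point_id, das, ... then band columns).

    Floats are written with 17 significant digits so the table round-trips
    bit-exactly.
    """
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_table(path: "str | Path", bands: BandSet) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in band_columns(bands) if c not in df.columns]
    if missing:
        raise ValueError(f"spectra table missing band columns: {missing[:5]} ...")
    return df


def table_band_values(df: pd.DataFrame, bands: BandSet) -> np.ndarray:
    """Extract the (n_rows, n_active) reflectance block from a spectra table."""
    return df[band_columns(bands)].to_numpy(dtype=float)
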