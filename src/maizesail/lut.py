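"""Look-up-table construction, LSE inversion and global sensitivity analysis.

The retrieval strategy is numerical inversion by table search: draw many
parameter vectors from the prior ranges, forward-simulate each canopy
reflectance with PROSPECT-4 + 4-SAIL, resample to the sensor bands, and
match an observed band spectrum against the table with a least-square-
error cost.  Averaging the parameters of the best fraction of matches
(10% by default) damps the ill-posedness of the inversion.

The default sampling design replicates the study configuration: free
parameters N, Cab, ALIA, Hot, soil brightness and the view angles drawn
i.i.d. uniform within their ranges, LAI stratified by a one-dimensional
latin hypercube over [0.5, 7], leaf water and dry matter fixed, sun
zenith fixed at 49 degrees, for 60750 simulations in total.
"""
from __future__ import annotations

import hashlib
import json
import math
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bands as bands_mod
from .bands import BandSet, BandSpectrum, Spectrum
from .foursail import CanopyParams, SoilSpectrum, ViewGeometry, canopy_brf, soil_reflectance
from .prospect4 import LeafOpticalConstants, LeafParams, leaf_rt

__all__ = [
    "ParamSpec",
    "SamplingConfig",
    "default_sampling_config",
    "sample_params",
    "forward_reflectance",
    "build_lut",
    "LUT",
    "lse_cost",
    "invert",
    "InversionResult",
    "gsa_first_order",
    "write_lut",
    "read_lut",
    "write_lut_binary",
    "read_lut_binary",
    "PARAM_NAMES",
]

#: Canonical parameter order: leaf, canopy, then geometry.
PARAM_NAMES = (
    "n",
    "cab",
    "cw",
    "cm",
    "lai",
    "alia",
    "hot",
    "alpha_soil",
    "theta_s",
    "theta_v",
    "phi_sv",
)

_SCHEMES = ("uniform", "lhs", "fixed")


@dataclass(frozen=True)
class ParamSpec:
    """Range and sampling scheme for one model parameter.

    ``fixed`` parameters carry a single value (lo == hi); free parameters
    are sampled ``uniform`` i.i.d. or by one-dimensional latin-hypercube
    (``lhs``) stratification.
    """

    lo: float
    hi: float
    scheme: str = "uniform"

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")
        if self.scheme == "fixed":
            if self.lo != self.hi:
                raise ValueError("fixed parameters need lo == hi")
        elif self.lo > self.hi:
            raise ValueError(f"inverted range: lo={self.lo} > hi={self.hi}")

    @property
    def is_fixed(self) -> bool:
        return self.scheme == "fixed"

    @classmethod
    def fixed(cls, value: float) -> "ParamSpec":
        return cls(lo=value, hi=value, scheme="fixed")


@dataclass(frozen=True)
class SamplingConfig:
    """Full sampling design: per-parameter specs, sample count and seed."""

    params: "dict[str, ParamSpec]"
    n: int = 60750
    seed: int = 20141004

    def __post_init__(self) -> None:
        missing = [p for p in PARAM_NAMES if p not in self.params]
        if missing:
            raise ValueError(f"sampling config missing parameters: {missing}")
        if self.n < 1:
            raise ValueError("sample count n must be >= 1")

    @property
    def free_names(self) -> "tuple[str, ...]":
        return tuple(p for p in PARAM_NAMES if not self.params[p].is_fixed)

    def replace(self, **kw) -> "SamplingConfig":
        d = {"params": dict(self.params), "n": self.n, "seed": self.seed}
        d.update(kw)
        return SamplingConfig(**d)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "params": {
                k: {"lo": v.lo, "hi": v.hi, "scheme": v.scheme}
                for k, v in self.params.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingConfig":
        return cls(
            params={k: ParamSpec(**v) for k, v in d["params"].items()},
            n=int(d.get("n", 60750)),
            seed=int(d.get("seed", 20141004)),
        )

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_sampling_config(n: int = 60750, seed: int = 20141004) -> SamplingConfig:
    """The study-replication design (free/fixed roles and ranges).

    N 1.2-2, Cab 30-80 ug/cm2, ALIA 35-90 deg, hot spot 0-0.28 and soil
    brightness 0-1 uniform; LAI latin-hypercube over 0.5-7; view zenith
    -24-24 deg and relative azimuth 0-180 deg uniform; Cw = 0.02 cm,
    Cm = 0.005 g/cm2 and sun zenith = 49 deg fixed.
    """
    return SamplingConfig(
        params={
            "n": ParamSpec(1.2, 2.0),
            "cab": ParamSpec(30.0, 80.0),
            "cw": ParamSpec.fixed(0.02),
            "cm": ParamSpec.fixed(0.005),
            "lai": ParamSpec(0.5, 7.0, scheme="lhs"),
            "alia": ParamSpec(35.0, 90.0),
            "hot": ParamSpec(0.0, 0.28),
            "alpha_soil": ParamSpec(0.0, 1.0),
            "theta_s": ParamSpec.fixed(49.0),
            "theta_v": ParamSpec(-24.0, 24.0),
            "phi_sv": ParamSpec(0.0, 180.0),
        },
        n=n,
        seed=seed,
    )


def sample_params(cfg: SamplingConfig, rng: "np.random.Generator | None" = None) -> pd.DataFrame:
    """Draw the parameter table of the design (one row per simulation).

    LHS parameters are stratified: exactly one sample falls in each of the
    n equal-width strata of the range, in shuffled order.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    cols = {}
    for name in PARAM_NAMES:
        spec = cfg.params[name]
        if spec.is_fixed:
            cols[name] = np.full(n, spec.lo)
        elif spec.scheme == "uniform":
            cols[name] = rng.uniform(spec.lo, spec.hi, size=n)
        else:  # lhs
            strata = rng.permutation(n)
            u = rng.uniform(size=n)
            cols[name] = spec.lo + (strata + u) / n * (spec.hi - spec.lo)
    return pd.DataFrame(cols, columns=list(PARAM_NAMES))


def forward_reflectance(
    row: "dict | pd.Series",
    constants: LeafOpticalConstants,
    soil_ref: SoilSpectrum,
    weights: np.ndarray,
) -> np.ndarray:
    """Band reflectance for one parameter vector.

    ``weights`` is the precomputed resampling matrix from
    :func:`maizesail.bands.resample_matrix` on the constants' grid.
    """
    leaf_r, leaf_t = leaf_rt(
        LeafParams(n=row["n"], cab=row["cab"], cw=row["cw"], cm=row["cm"]), constants
    )
    cp = CanopyParams(
        lai=row["lai"], alia=row["alia"], hot=row["hot"], alpha_soil=row["alpha_soil"]
    )
    g = ViewGeometry(theta_s=row["theta_s"], theta_v=row["theta_v"], phi_sv=row["phi_sv"])
    soil = soil_reflectance(cp.alpha_soil, soil_ref)
    brf = canopy_brf(leaf_r, leaf_t, cp, g, soil)
    return weights @ brf.values


@dataclass
class LUT:
    """Paired parameter and band-reflectance tables of the simulations."""

    params: pd.DataFrame
    reflectance: np.ndarray
    band_set: BandSet
    free_names: "tuple[str, ...]"
    config_hash: str = ""

    def __post_init__(self) -> None:
        if len(self.params) != self.reflectance.shape[0]:
            raise ValueError("parameter and reflectance tables must have equal length")
        if self.reflectance.shape[1] != self.band_set.n_active:
            raise ValueError("reflectance table width must equal the active band count")
        if np.any(self.reflectance < 0) or np.any(self.reflectance > 1):
            raise ValueError("LUT reflectances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.params)

    def subset_geometry(
        self,
        theta_v: "tuple[float, float] | None" = None,
        phi_sv: "tuple[float, float] | None" = None,
    ) -> "LUT":
        """Restrict the table to a view-geometry window before inversion."""
        keep = np.ones(self.n, dtype=bool)
        if theta_v is not None:
            keep &= (self.params["theta_v"] >= theta_v[0]) & (
                self.params["theta_v"] <= theta_v[1]
            )
        if phi_sv is not None:
            keep &= (self.params["phi_sv"] >= phi_sv[0]) & (
                self.params["phi_sv"] <= phi_sv[1]
            )
        if not keep.any():
            raise ValueError("geometry window leaves an empty look-up table")
        return LUT(
            params=self.params.loc[keep].reset_index(drop=True),
            reflectance=self.reflectance[keep.to_numpy()],
            band_set=self.band_set,
            free_names=self.free_names,
            config_hash=self.config_hash,
        )


def build_lut(
    cfg: SamplingConfig,
    bands: BandSet,
    constants: LeafOpticalConstants,
    soil_ref: SoilSpectrum,
) -> LUT:
    """Sample the design and forward-simulate every record to band space."""
    params = sample_params(cfg)
    weights = bands_mod.resample_matrix(bands, constants.wavelengths)
    refl = np.empty((cfg.n, bands.n_active))
    records = params.to_dict("records")  # much faster than DataFrame row access
    for i, row in enumerate(records):
        refl[i] = forward_reflectance(row, constants, soil_ref, weights)
    return LUT(
        params=params,
        reflectance=refl,
        band_set=bands,
        free_names=cfg.free_names,
        config_hash=cfg.hash(),
    )


def lse_cost(obs: BandSpectrum, sim: BandSpectrum) -> float:
    """Least-square-error cost: sum of squared differences over active bands."""
    if obs.band_set != sim.band_set:
        raise ValueError("observed and simulated spectra use different band sets")
    d = obs.values - sim.values
    return float(d @ d)


@dataclass(frozen=True)
class InversionResult:
    """Retrieved parameters from best-fraction averaging.

    ``estimates`` and ``dispersion`` map each free parameter to the mean
    and (population) standard deviation over the retained records.
    """

    estimates: "dict[str, float]"
    dispersion: "dict[str, float]"
    best_cost: float
    n_retained: int
    retained_indices: np.ndarray


def invert(
    obs: BandSpectrum,
    lut: LUT,
    fraction: float = 0.10,
    weighted: bool = False,
) -> InversionResult:
    """Invert one observed band spectrum against the look-up table.

    Costs are computed against every record; the ceil(fraction * n)
    lowest-cost records are retained (ties broken by record order) and
    each free parameter is averaged over them.  ``weighted=True`` uses
    1/cost weights instead of the plain mean.
    """
    if lut.n == 0:
        raise ValueError("look-up table is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("retained fraction must be in (0, 1]")
    if obs.band_set != lut.band_set:
        raise ValueError("observation band set does not match the look-up table")
    diff = lut.reflectance - obs.values[None, :]
    costs = np.einsum("ij,ij->i", diff, diff)
    k = math.ceil(fraction * lut.n)
    order = np.argsort(costs, kind="stable")[:k]
    retained = lut.params.iloc[order]
    if weighted:
        wts = 1.0 / (costs[order] + 1e-12)
        wts /= wts.sum()
        estimates = {p: float(retained[p].to_numpy() @ wts) for p in lut.free_names}
    else:
        estimates = {p: float(retained[p].mean()) for p in lut.free_names}
    dispersion = {p: float(retained[p].std(ddof=0)) for p in lut.free_names}
    return InversionResult(
        estimates=estimates,
        dispersion=dispersion,
        best_cost=float(costs[order[0]]),
        n_retained=k,
        retained_indices=order,
    )


def gsa_first_order(
    cfg: SamplingConfig,
    n_mc: int,
    bins: int,
    bands: BandSet,
    constants: LeafOpticalConstants,
    soil_ref: SoilSpectrum,
    seed: "int | None" = None,
) -> pd.DataFrame:
    """First-order sensitivity indices per parameter and band.

    Binning estimator from a single Monte-Carlo sample: the index of a
    parameter at a band is Var(E[reflectance | parameter bin]) divided by
    Var(reflectance), with the parameter range cut into ``bins``
    equal-width strata.  Fixed parameters have index 0 by convention, as
    do bands with degenerate (zero) reflectance variance.

    Requires n_mc >= 50 * bins so each stratum holds enough samples.
    """
    if n_mc < 50 * bins:
        raise ValueError(f"n_mc must be >= 50*bins = {50 * bins}, got {n_mc}")
    mc_cfg = cfg.replace(n=n_mc, seed=cfg.seed if seed is None else seed)
    sub = build_lut(mc_cfg, bands, constants, soil_ref)
    y = sub.reflectance
    var_y = y.var(axis=0)
    out = {}
    for name in PARAM_NAMES:
        spec = cfg.params[name]
        if spec.is_fixed:
            out[name] = np.zeros(bands.n_active)
            continue
        x = sub.params[name].to_numpy()
        edges = np.linspace(spec.lo, spec.hi, bins + 1)
        which = np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
        num = np.zeros(bands.n_active)
        grand = y.mean(axis=0)
        for b in range(bins):
            mask = which == b
            if not mask.any():
                continue
            p_b = mask.mean()
            m_b = y[mask].mean(axis=0)
            num += p_b * (m_b - grand) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(var_y > 0, num / np.where(var_y > 0, var_y, 1.0), 0.0)
        out[name] = idx
    df = pd.DataFrame(out, index=[f"{c:g}" for c in bands.active_centers]).T
    df.index.name = "parameter"
    return df


# ---------------------------------------------------------------------------
# persistence

def write_lut(lut: LUT, directory: "str | Path") -> None:
    """Write the LUT as delimited text (params.csv, reflectance.csv, ...)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lut.params.to_csv(d / "params.csv", index=False, float_format="%.17g")
    pd.DataFrame(lut.reflectance, columns=bands_mod.band_columns(lut.band_set)).to_csv(
        d / "reflectance.csv", index=False, float_format="%.17g"
    )
    bands_mod.write_band_set(lut.band_set, d / "band_set.csv")
    (d / "meta.json").write_text(
        json.dumps(
            {"free_names": list(lut.free_names), "config_hash": lut.config_hash},
            indent=1,
        )
    )


def read_lut(directory: "str | Path") -> LUT:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    band_set = bands_mod.read_band_set(d / "band_set.csv")
    params = pd.read_csv(d / "params.csv", float_precision="round_trip").astype(float)
    refl = pd.read_csv(d / "reflectance.csv", float_precision="round_trip").to_numpy(dtype=float)
    return LUT(
        params=params,
        reflectance=refl,
        band_set=band_set,
        free_names=tuple(meta["free_names"]),
        config_hash=meta.get("config_hash", ""),
    )


_MAGIC = b"MZLUT1\x00"


def write_lut_binary(lut: LUT, path: "str | Path") -> None:
    """Compact columnar binary: magic, JSON header, float64 blocks.

    Layout: 7-byte magic, uint32 header length, UTF-8 JSON header (record
    count, parameter column order, band centres/FWHM/mask, free names,
    config hash), then the parameter table and the reflectance table as
    row-major little-endian float64.  Round trips bit-exactly.
    """
    header = {
        "n": lut.n,
        "param_columns": list(lut.params.columns),
        "band_centers": lut.band_set.centers.tolist(),
        "fwhm": lut.band_set.fwhm,
        "active_mask": lut.band_set.active_mask.astype(int).tolist(),
        "free_names": list(lut.free_names),
        "config_hash": lut.config_hash,
    }
    hjson = json.dumps(header).encode()
    with open(path, "wb") as f:
        f.write(_MAGIC)
        f.write(struct.pack("<I", len(hjson)))
        f.write(hjson)
        f.write(np.ascontiguousarray(lut.params.to_numpy(dtype="<f8")).tobytes())
        f.write(np.ascontiguousarray(lut.reflectance.astype("<f8")).tobytes())


def read_lut_binary(path: "str | Path") -> LUT:
    with open(path, "rb") as f:
        magic = f.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError("not a maizesail binary LUT file")
        (hlen,) = struct.unpack("<I", f.read(4))
        header = json.loads(f.read(hlen).decode())
        n = header["n"]
        cols = header["param_columns"]
        band_set = BandSet(
            centers=np.array(header["band_centers"], dtype=float),
            fwhm=float(header["fwhm"]),
            active_mask=np.array(header["active_mask"], dtype=int).astype(bool),
        )
        params = np.frombuffer(f.read(8 * n * len(cols)), dtype="<f8").reshape(n, len(cols))
        refl = np.frombuffer(
            f.read(8 * n * band_set.n_active), dtype="<f8"
        ).reshape(n, band_set.n_active)
    return LUT(
        params=pd.DataFrame(params.copy(), columns=cols),
        reflectance=refl.copy(),
        band_set=band_set,
        free_names=tuple(header["free_names"]),
        config_hash=header.get("config_hash", ""),
    )
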