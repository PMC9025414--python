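"""Virtual maize field campaigns with the statistical structure of the study.

Two fields are emulated: F1 (26 sampling points, 12 of them carrying
ground LAI at five dates between 40 and 123 days after sowing) under
furrow irrigation — lower-yielding and spatially heterogeneous — and F2
(25 points, harvest data only) under pivot irrigation — higher-yielding
and homogeneous.  Per-point green LAI follows a logistic rise to a
plateau (field mean about 1.3 m2/m2 at 40 DAS, peaking near 4.9 at 123
DAS) followed by a senescence decline whose per-point timing is
independent of yield, which makes late-season reflectance a poor yield
predictor, as in real campaigns.  Biomass scales with the LAI plateau
and grain yield is a harvest-index fraction of biomass, keeping
biomass >= yield structurally true.

Canopy spectra are forward-simulated with PROSPECT-4 + 4-SAIL and
resampled to the sensor bands.  Nuisance parameters are drawn from
within-field distributions (:class:`FieldNuisance`) much narrower than
the literature-wide retrieval prior — a single hybrid on one date does
not span the full literature range — with leaf chlorophyll weakly
coupled to plant vigour; view geometry varies across the swath.  A
multiplicative-plus-additive noise model emulates airborne reflectance
uncertainty.  Everything is reproducible from a single seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bands as bands_mod
from .bands import BandSet
from .foursail import SoilSpectrum
from .lut import SamplingConfig, default_sampling_config, forward_reflectance
from .prospect4 import LeafOpticalConstants

__all__ = [
    "FieldDesign",
    "Campaign",
    "GrowthModel",
    "FieldNuisance",
    "NoiseModel",
    "make_design",
    "footprint_area",
    "simulate_ground",
    "simulate_spectra",
    "logistic_lai",
    "green_lai",
    "DEFAULT_GROWTH",
]


@dataclass(frozen=True)
class FieldDesign:
    """Sampling design of one field.

    ``points`` holds (id, x, y) planar coordinates in metres;
    ``calibration`` flags the points that carry ground LAI and fit the
    transfer equations.  The harvest footprint per point is
    ``rows_per_sample`` adjacent rows of ``row_length`` m at
    ``row_spacing`` m spacing.
    """

    field_id: str
    points: pd.DataFrame
    calibration: np.ndarray
    row_spacing: float = 0.8
    row_length: float = 5.0
    rows_per_sample: int = 2

    def __post_init__(self) -> None:
        if self.calibration.sum() > len(self.points):
            raise ValueError("calibration count exceeds point count")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_calibration(self) -> int:
        return int(self.calibration.sum())


@dataclass(frozen=True)
class Campaign:
    """Acquisition calendar: per-field imaging dates and LAI-measurement dates.

    ``image_das`` maps field id to the days-after-sowing of the airborne
    acquisitions; ``lai_das`` to the subset of dates with concurrent
    ground LAI.  ``stage`` labels the maize growth stage per (field, das).
    """

    image_das: "dict[str, tuple[int, ...]]"
    lai_das: "dict[str, tuple[int, ...]]"
    stage: "dict[tuple[str, int], str]" = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, das in self.image_das.items():
            if list(das) != sorted(das):
                raise ValueError(f"image dates for {fid} must be increasing")
        for fid, das in self.lai_das.items():
            missing = set(das) - set(self.image_das.get(fid, ()))
            if missing:
                raise ValueError(f"LAI dates {sorted(missing)} not in {fid} image calendar")


@dataclass(frozen=True)
class GrowthModel:
    """Logistic LAI growth with senescence, plus linear yield transfer.

    The per-point plateau is the hybrid's potential minus an
    exponentially distributed stress deficit, lmax = lmax_potential -
    Exp(stress_scale): plateau LAI is capped biologically near the
    potential while water stress drags weak spots far below it, giving
    the left-skewed within-field distribution real yield maps show.
    Green LAI(t) = lmax / (1 + exp(-rate (t - midpoint_das))) *
    1 / (1 + exp(senescence_rate (t - t_sen))), with the senescence
    onset t_sen jittered per point independently of yield.  Biomass =
    biomass_per_lmax * lmax + noise; grain yield = harvest_index *
    biomass + noise.
    """

    lmax_potential: float = 5.8  # m2/m2, hybrid potential plateau
    stress_scale: float = 1.1  # mean stress deficit, m2/m2
    rate: float = 0.055  # 1/day
    midpoint_das: float = 57.0
    senescence_das: float = 145.0
    senescence_rate: float = 0.1  # 1/day
    senescence_jitter_sd: float = 8.0  # days
    lai_noise_sd: float = 0.15
    biomass_per_lmax: float = 2.5  # t/ha per m2/m2 of plateau LAI
    biomass_noise_sd: float = 1.2
    harvest_index: float = 0.47
    yield_noise_sd: float = 0.35

    @property
    def lmax_mean(self) -> float:
        return self.lmax_potential - self.stress_scale


#: Field-specific growth defaults: the same hybrid potential, but the
#: furrow-irrigated F1 carries a much larger stress deficit scale than
#: the evenly watered pivot-irrigated F2, making F1 lower-yielding and
#: heterogeneous and F2 high-yielding and homogeneous.
DEFAULT_GROWTH = {
    "F1": GrowthModel(),
    "F2": GrowthModel(
        stress_scale=0.4,
        senescence_das=148.0,
        biomass_per_lmax=3.8,
        biomass_noise_sd=0.8,
        yield_noise_sd=0.25,
    ),
}

#: Default acquisition calendar (days after sowing per field) and the
#: dates carrying ground LAI on the F1 calibration points.
DEFAULT_IMAGE_DAS = {
    "F1": (40, 53, 67, 74, 98, 107, 123, 144, 157),
    "F2": (34, 48, 54, 67, 81, 88, 112, 121, 137, 158),
}
DEFAULT_LAI_DAS = {"F1": (40, 53, 74, 107, 123), "F2": ()}

#: Growth-stage labels for the default calendar (vegetative V, then
#: reproductive R); the late vegetative stage V16 is reached at 74 DAS
#: in F1 and 67 DAS in F2.
DEFAULT_STAGES = {
    ("F1", 40): "V7",
    ("F1", 53): "V9",
    ("F1", 67): "V14",
    ("F1", 74): "V16",
    ("F1", 98): "V18",
    ("F1", 107): "VT",
    ("F1", 123): "R2",
    ("F1", 144): "R4",
    ("F1", 157): "R6",
    ("F2", 34): "V7",
    ("F2", 48): "V8",
    ("F2", 54): "V9",
    ("F2", 67): "V16",
    ("F2", 81): "V18",
    ("F2", 88): "V18",
    ("F2", 112): "R1",
    ("F2", 121): "R2",
    ("F2", 137): "R3",
    ("F2", 158): "R6",
}


def _field_seed(seed: int, fid: str) -> "list[int]":
    # stable per-field stream (builtin hash() is salted per process)
    return [seed, sum(ord(ch) for ch in fid)]


def make_design(
    config: "dict | None" = None, seed: int = 0
) -> "tuple[dict[str, FieldDesign], Campaign]":
    """Build the two field designs and the acquisition calendar.

    ``config`` may override ``n_points``/``n_calibration`` per field and
    the calendar; the defaults replicate the study layout (26 + 25
    points, 12 calibration, five LAI dates on F1).  Point coordinates
    are drawn on a jittered grid, reproducibly from ``seed``.
    """
    cfg: dict = {
        "F1": {"n_points": 26, "n_calibration": 12},
        "F2": {"n_points": 25, "n_calibration": 0},
        "image_das": DEFAULT_IMAGE_DAS,
        "lai_das": DEFAULT_LAI_DAS,
    }
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and k in cfg and isinstance(cfg[k], dict):
                cfg[k] = {**cfg[k], **v}
            else:
                cfg[k] = v
    rng = np.random.default_rng(seed)
    designs: "dict[str, FieldDesign]" = {}
    for fid in ("F1", "F2"):
        n_pts = int(cfg[fid]["n_points"])
        n_cal = int(cfg[fid]["n_calibration"])
        if n_pts < 1:
            raise ValueError(f"{fid}: need at least one sampling point")
        if n_cal > n_pts:
            raise ValueError(f"{fid}: calibration count {n_cal} > point count {n_pts}")
        # jittered grid spread over a few hundred metres, like points in a field
        side = int(np.ceil(np.sqrt(n_pts)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        cells = np.column_stack([gx.ravel(), gy.ravel()])[:n_pts]
        coords = (cells + rng.uniform(0.15, 0.85, size=cells.shape)) * 80.0
        pts = pd.DataFrame(
            {
                "point_id": [f"{fid}-{i + 1:02d}" for i in range(n_pts)],
                "x": coords[:, 0],
                "y": coords[:, 1],
            }
        )
        cal = np.zeros(n_pts, dtype=bool)
        cal[rng.choice(n_pts, size=n_cal, replace=False)] = True
        designs[fid] = FieldDesign(field_id=fid, points=pts, calibration=cal)
    campaign = Campaign(
        image_das={k: tuple(v) for k, v in cfg["image_das"].items()},
        lai_das={k: tuple(v) for k, v in cfg["lai_das"].items()},
        stage=dict(DEFAULT_STAGES),
    )
    return designs, campaign


def footprint_area(design: FieldDesign) -> float:
    """Harvested ground area per sampling point, m2."""
    return design.rows_per_sample * design.row_length * design.row_spacing


def logistic_lai(lmax, rate, t0, das):
    """Plateauing logistic growth curve LAI(t)."""
    return lmax / (1.0 + np.exp(-rate * (np.asarray(das, dtype=float) - t0)))


def green_lai(lmax, rate, t0, sen_rate, t_sen, das):
    """Green LAI: logistic growth times a logistic senescence decline."""
    das = np.asarray(das, dtype=float)
    rise = logistic_lai(lmax, rate, t0, das)
    survive = 1.0 / (1.0 + np.exp(sen_rate * (das - t_sen)))
    return rise * survive


def _growth_trajectories(design: FieldDesign, gm: GrowthModel, rng: np.random.Generator):
    """Per-point (lmax, rate, t0, t_sen): plateau and jittered timing."""
    deficit = rng.exponential(gm.stress_scale, size=design.n_points)
    lmax = np.clip(gm.lmax_potential - deficit, 0.5, None)
    rate = gm.rate * rng.normal(1.0, 0.05, size=design.n_points)
    t0 = gm.midpoint_das + rng.normal(0.0, 2.0, size=design.n_points)
    t_sen = gm.senescence_das + rng.normal(
        0.0, gm.senescence_jitter_sd, size=design.n_points
    )
    return lmax, rate, t0, t_sen


def simulate_ground(
    designs: "dict[str, FieldDesign]",
    campaign: Campaign,
    growth: "dict[str, GrowthModel] | None" = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground records: LAI per calibration point and LAI date, plus
    biomass and grain yield per point at harvest.

    Returns a tidy table (field, point_id, das, lai, biomass,
    grain_yield) with NaN where a quantity was not observed; harvest
    rows use the last acquisition date of the field.  All draws are
    reproducible from ``seed``.
    """
    growth = dict(DEFAULT_GROWTH) if growth is None else growth
    rows = []
    for fid, design in designs.items():
        gm = growth[fid]
        rng = np.random.default_rng(_field_seed(seed, fid))
        lmax, rate, t0, t_sen = _growth_trajectories(design, gm, rng)
        for das in campaign.lai_das.get(fid, ()):
            for j in np.flatnonzero(design.calibration):
                lai = float(
                    green_lai(lmax[j], rate[j], t0[j], gm.senescence_rate, t_sen[j], das)
                )
                lai += rng.normal(0.0, gm.lai_noise_sd)
                rows.append(
                    {
                        "field": fid,
                        "point_id": design.points["point_id"].iloc[j],
                        "das": das,
                        "lai": max(lai, 0.0),
                        "biomass": np.nan,
                        "grain_yield": np.nan,
                    }
                )
        harvest_das = max(campaign.image_das[fid])
        biomass = gm.biomass_per_lmax * lmax + rng.normal(
            0.0, gm.biomass_noise_sd, size=design.n_points
        )
        biomass = np.clip(biomass, 0.1, None)
        gy = gm.harvest_index * biomass + rng.normal(
            0.0, gm.yield_noise_sd, size=design.n_points
        )
        gy = np.clip(gy, 0.0, biomass)  # grain cannot exceed total biomass
        for j in range(design.n_points):
            rows.append(
                {
                    "field": fid,
                    "point_id": design.points["point_id"].iloc[j],
                    "das": harvest_das,
                    "lai": np.nan,
                    "biomass": float(biomass[j]),
                    "grain_yield": float(gy[j]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FieldNuisance:
    """Within-field distributions of the non-LAI canopy parameters.

    A single hybrid observed on one date spans a much narrower range
    than the literature-wide retrieval prior: leaf structure, leaf
    inclination and the hot-spot parameter vary mildly between points;
    chlorophyll is weakly coupled to plant vigour (vigorous plants are
    greener); soil brightness is set per date by the field's surface
    moisture (one draw per acquisition) with a small per-point jitter;
    view zenith and relative azimuth vary across the sensor swath over
    the full acquisition ranges.  All draws are clipped to the
    retrieval prior so simulated spectra stay inside the look-up
    table's support.
    """

    n_mean: float = 1.5
    n_sd: float = 0.08
    cab_base: float = 55.0  # ug/cm2 at the mean plateau LAI
    cab_vigor_slope: float = 4.0  # ug/cm2 per m2/m2 of plateau LAI
    cab_sd: float = 3.0
    alia_mean: float = 60.0
    alia_sd: float = 5.0
    hot_mean: float = 0.15
    hot_sd: float = 0.03
    alpha_soil_lo: float = 0.3  # per-date field moisture range
    alpha_soil_hi: float = 0.7
    alpha_soil_point_sd: float = 0.05  # per-point jitter within a date


@dataclass(frozen=True)
class NoiseModel:
    """Reflectance noise: multiplicative Gaussian plus additive Gaussian.

    r_obs = clip(r (1 + eps_m) + eps_a, 0, 1) with eps_m ~ N(0, 0.02)
    and eps_a ~ N(0, 0.005) by default — typical airborne surface-
    reflectance uncertainty.
    """

    multiplicative_sd: float = 0.02
    additive_sd: float = 0.005

    def apply(self, refl: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = refl * (1.0 + rng.normal(0.0, self.multiplicative_sd, size=refl.shape))
        out = out + rng.normal(0.0, self.additive_sd, size=refl.shape)
        return np.clip(out, 0.0, 1.0)


def simulate_spectra(
    designs: "dict[str, FieldDesign]",
    campaign: Campaign,
    bands: BandSet,
    constants: LeafOpticalConstants,
    soil_ref: SoilSpectrum,
    growth: "dict[str, GrowthModel] | None" = None,
    sampling: "SamplingConfig | None" = None,
    nuisance: "FieldNuisance | None" = None,
    noise: "NoiseModel | None" = NoiseModel(),
    seed: int = 0,
    fields: "tuple[str, ...] | None" = None,
    image_das: "dict[str, tuple[int, ...]] | None" = None,
) -> pd.DataFrame:
    """Forward-simulate noisy point spectra for every point and date.

    Per point/date the true green LAI comes from the same growth
    trajectories as :func:`simulate_ground` (same seed, same draws);
    leaf structure, chlorophyll, leaf angle and hot spot are drawn once
    per point and soil brightness and view geometry per point/date from
    ``nuisance``, clipped to the free ranges of ``sampling`` (the
    study-replication prior by default); fixed parameters keep their
    configured values.  LAI below the prior's lower bound is pushed up
    to it (a bare-ish canopy still gets the nearest representable
    state); LAI above it is clipped with a warning.  Returns the
    point-spectra table: field, point_id, das, true LAI and the
    parameter draws, then one reflectance column per active band.
    ``noise=None`` disables the noise model.
    """
    growth = dict(DEFAULT_GROWTH) if growth is None else growth
    sampling = default_sampling_config() if sampling is None else sampling
    nuisance = FieldNuisance() if nuisance is None else nuisance
    weights = bands_mod.resample_matrix(bands, constants.wavelengths)

    def rng_draw_clipped(rng, mean, sd, lo, hi, size):
        return np.clip(rng.normal(mean, sd, size=size), lo, hi)

    p = sampling.params
    lai_spec = p["lai"]
    rows = []
    refls = []
    for fid, design in designs.items():
        if fields is not None and fid not in fields:
            continue
        gm = growth[fid]
        rng = np.random.default_rng(_field_seed(seed, fid))
        # identical draw order as simulate_ground so trajectories agree
        lmax, rate, t0, t_sen = _growth_trajectories(design, gm, rng)
        spec_rng = np.random.default_rng(_field_seed(seed + 1, fid))
        npts = design.n_points
        n_pt = rng_draw_clipped(spec_rng, nuisance.n_mean, nuisance.n_sd,
                                p["n"].lo, p["n"].hi, npts)
        cab_pt = rng_draw_clipped(
            spec_rng,
            nuisance.cab_base + nuisance.cab_vigor_slope * (lmax - gm.lmax_mean),
            nuisance.cab_sd,
            p["cab"].lo, p["cab"].hi, npts,
        )
        alia_pt = rng_draw_clipped(spec_rng, nuisance.alia_mean, nuisance.alia_sd,
                                   p["alia"].lo, p["alia"].hi, npts)
        hot_pt = rng_draw_clipped(spec_rng, nuisance.hot_mean, nuisance.hot_sd,
                                  p["hot"].lo, p["hot"].hi, npts)
        das_list = (image_das or campaign.image_das)[fid]
        for das in das_list:
            soil_date = spec_rng.uniform(nuisance.alpha_soil_lo, nuisance.alpha_soil_hi)
            for j in range(npts):
                true_lai = float(
                    green_lai(lmax[j], rate[j], t0[j], gm.senescence_rate, t_sen[j], das)
                )
                lai = true_lai
                if lai > lai_spec.hi:
                    warnings.warn(
                        f"{fid} point {j} at {das} DAS: LAI {lai:.2f} above prior "
                        f"range [{lai_spec.lo}, {lai_spec.hi}]; clipped",
                        stacklevel=2,
                    )
                lai = float(np.clip(lai, lai_spec.lo, lai_spec.hi))
                draw = {
                    "n": float(n_pt[j]),
                    "cab": float(cab_pt[j]),
                    "alia": float(alia_pt[j]),
                    "hot": float(hot_pt[j]),
                    "alpha_soil": float(
                        np.clip(
                            soil_date
                            + spec_rng.normal(0.0, nuisance.alpha_soil_point_sd),
                            p["alpha_soil"].lo, p["alpha_soil"].hi,
                        )
                    ),
                    "theta_v": float(spec_rng.uniform(p["theta_v"].lo, p["theta_v"].hi)),
                    "phi_sv": float(spec_rng.uniform(p["phi_sv"].lo, p["phi_sv"].hi)),
                    "cw": p["cw"].lo,
                    "cm": p["cm"].lo,
                    "theta_s": p["theta_s"].lo,
                    "lai": lai,
                }
                refl = forward_reflectance(draw, constants, soil_ref, weights)
                if noise is not None:
                    refl = noise.apply(refl, spec_rng)
                rows.append(
                    {
                        "field": fid,
                        "point_id": design.points["point_id"].iloc[j],
                        "das": das,
                        "true_lai": true_lai,
                        **{
                            k: draw[k]
                            for k in ("n", "cab", "alia", "hot", "alpha_soil",
                                      "theta_v", "phi_sv")
                        },
                    }
                )
                refls.append(refl)
    meta = pd.DataFrame(rows)
    refl_df = pd.DataFrame(np.array(refls), columns=bands_mod.band_columns(bands))
    return pd.concat([meta, refl_df], axis=1)


def write_ground_table(df: pd.DataFrame, path) -> None:
    """Write ground records (bit-exact round trip: 17 significant digits)."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_ground_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("field", "point_id", "das", "lai", "biomass", "grain_yield")
               if c not in df.columns]
    if missing:
        raise ValueError(f"ground table missing columns: {missing}")
    return df
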