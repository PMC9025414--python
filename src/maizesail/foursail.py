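"""4-SAIL canopy bidirectional reflectance.

Four-stream radiative transfer in a horizontally homogeneous canopy of
arbitrarily inclined leaves: given leaf reflectance/transmittance spectra,
leaf area index, an ellipsoidal leaf inclination distribution summarised
by its mean angle (ALIA), a hot-spot parameter, a soil lower boundary and
the sun/view geometry, the model returns the directional reflectance
factor seen by the sensor.  The implementation follows the classical
formulation: SUITS-type extinction and scattering coefficients averaged
over a 13-class leaf inclination quadrature, exact two-stream solutions
for the diffuse fluxes, and the hot-spot correction for the joint gap
probability in the sun and view directions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bands import Spectrum

__all__ = [
    "CanopyParams",
    "ViewGeometry",
    "SoilSpectrum",
    "default_soil",
    "soil_reflectance",
    "leaf_angle_distribution",
    "canopy_brf",
    "LIDF_ANGLES_DEG",
]

_RD = math.pi / 180.0

#: The standard 13-class SAIL leaf-inclination quadrature: 10-degree
#: classes up to 80 degrees, then 2-degree classes approaching vertical.
LIDF_ANGLE_BOUNDS_DEG = np.array(
    [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 82.0, 84.0, 86.0, 88.0, 90.0]
)
LIDF_ANGLES_DEG = 0.5 * (LIDF_ANGLE_BOUNDS_DEG[:-1] + LIDF_ANGLE_BOUNDS_DEG[1:])


@dataclass(frozen=True)
class CanopyParams:
    """4-SAIL canopy structure parameters.

    Attributes
    ----------
    lai : leaf area index, m2/m2.
    alia : average leaf inclination angle of the ellipsoidal
        distribution, degrees from horizontal, in (0, 90].
    hot : hot-spot parameter (leaf size / canopy height), m/m.
    alpha_soil : soil brightness multiplier in [0, 1].
    """

    lai: float = 3.0
    alia: float = 60.0
    hot: float = 0.1
    alpha_soil: float = 0.5

    def __post_init__(self) -> None:
        if self.lai < 0:
            raise ValueError("LAI must be non-negative")
        if not 0.0 < self.alia <= 90.0:
            raise ValueError("ALIA must be in (0, 90] degrees")
        if self.hot < 0:
            raise ValueError("hot-spot parameter must be non-negative")
        if not 0.0 <= self.alpha_soil <= 1.0:
            raise ValueError("soil brightness must be in [0, 1]")


@dataclass(frozen=True)
class ViewGeometry:
    """Sun and view directions.

    theta_s: sun zenith (deg, [0, 90)); theta_v: view zenith (deg,
    (-90, 90), negative values meaning the opposite azimuth half-plane);
    phi_sv: relative sun-view azimuth (deg, [0, 180]).
    """

    theta_s: float = 49.0
    theta_v: float = 0.0
    phi_sv: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_s < 90.0:
            raise ValueError("sun zenith must be in [0, 90) degrees")
        if not abs(self.theta_v) < 90.0:
            raise ValueError("view zenith must be in (-90, 90) degrees")
        if not 0.0 <= self.phi_sv <= 180.0:
            raise ValueError("relative azimuth must be in [0, 180] degrees")

    def canonical(self) -> "tuple[float, float, float]":
        """(theta_s, theta_v >= 0, phi) with a signed view zenith folded
        into the azimuth: (-tv, phi) describes the same direction as
        (tv, 180 - phi)."""
        if self.theta_v < 0:
            return self.theta_s, -self.theta_v, 180.0 - self.phi_sv
        return self.theta_s, self.theta_v, self.phi_sv


@dataclass(frozen=True)
class SoilSpectrum:
    """Reference soil reflectance on the 1-nm grid (before brightness scaling)."""

    spectrum: Spectrum

    def __post_init__(self) -> None:
        v = self.spectrum.values
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("soil reflectance must be in [0, 1]")


def default_soil(wavelengths: "np.ndarray | None" = None) -> SoilSpectrum:
    """Packaged reference soil: a smooth bright-soil ramp.

    r(lambda) = 0.12 + 0.00035 (lambda - 400), clipped to [0, 1] — a
    documented analytic stand-in for a library soil curve, rising gently
    from the blue to the NIR as bare dry soils do.
    """
    wl = np.arange(400.0, 851.0) if wavelengths is None else np.asarray(wavelengths, float)
    r = np.clip(0.12 + 0.00035 * (wl - 400.0), 0.0, 1.0)
    return SoilSpectrum(Spectrum(wl, r))


def soil_reflectance(alpha_soil: float, ref: SoilSpectrum) -> Spectrum:
    """Scale the reference soil by the brightness parameter, elementwise."""
    if not 0.0 <= alpha_soil <= 1.0:
        raise ValueError(f"soil brightness must be in [0, 1], got {alpha_soil}")
    s = ref.spectrum
    return Spectrum(s.wavelengths, alpha_soil * s.values)


def ellipsoidal_class_frequencies(excent: float, bounds_deg: np.ndarray) -> np.ndarray:
    """Leaf-inclination class frequencies of an ellipsoidal distribution.

    Leaf normals are distributed as the surface of an ellipsoid of
    revolution whose horizontal/vertical semi-axis ratio is ``excent``;
    frequencies per inclination class follow from the closed-form
    antiderivative of the surface-area density evaluated at the class
    bounds (degrees from horizontal).  Returned frequencies sum to 1.
    """
    bounds = np.asarray(bounds_deg, dtype=float) * _RD
    n_cls = bounds.size - 1
    freq = np.empty(n_cls)
    for i in range(n_cls):
        tl1, tl2 = bounds[i], bounds[i + 1]
        x1 = excent / math.sqrt(1.0 + excent**2 * math.tan(tl1) ** 2)
        x2 = excent / math.sqrt(1.0 + excent**2 * math.tan(tl2) ** 2)
        if abs(excent - 1.0) < 1e-9:
            freq[i] = abs(math.cos(tl1) - math.cos(tl2))
        else:
            alph = excent / math.sqrt(abs(1.0 - excent**2))
            alph2 = alph**2
            x12, x22 = x1**2, x2**2
            if excent > 1.0:
                alpx1 = math.sqrt(alph2 + x12)
                alpx2 = math.sqrt(alph2 + x22)
                dum = x1 * alpx1 + alph2 * math.log(x1 + alpx1)
                freq[i] = abs(dum - (x2 * alpx2 + alph2 * math.log(x2 + alpx2)))
            else:
                almx1 = math.sqrt(alph2 - x12)
                almx2 = math.sqrt(alph2 - x22)
                dum = x1 * almx1 + alph2 * math.asin(x1 / alph)
                freq[i] = abs(dum - (x2 * almx2 + alph2 * math.asin(x2 / alph)))
    return freq / freq.sum()


_CAL_BOUNDS = np.linspace(0.0, 90.0, 1801)  # 0.05-degree calibration quadrature
_CAL_MIDS = 0.5 * (_CAL_BOUNDS[:-1] + _CAL_BOUNDS[1:])
_CAL_GRID: "tuple[np.ndarray, np.ndarray] | None" = None


def _calibration_grid() -> "tuple[np.ndarray, np.ndarray]":
    # Tabulate excentricity -> continuous mean inclination once (monotone
    # decreasing: small excentricity = erectophile, large = planophile);
    # excentricity_for_mean inverts it by interpolation.
    global _CAL_GRID
    if _CAL_GRID is None:
        exc = np.logspace(-4.0, 3.0, 700)
        means = np.empty_like(exc)
        for i, e in enumerate(exc):
            f = ellipsoidal_class_frequencies(e, _CAL_BOUNDS)
            means[i] = float(f @ _CAL_MIDS)
        _CAL_GRID = (means[::-1].copy(), exc[::-1].copy())  # ascending in mean
    return _CAL_GRID


def excentricity_for_mean(alia_deg: float) -> float:
    """Excentricity whose ellipsoidal distribution has mean inclination ALIA."""
    means, exc = _calibration_grid()
    if alia_deg <= means[0]:
        return float(exc[0])
    if alia_deg >= means[-1]:
        return float(exc[-1])
    return float(np.exp(np.interp(alia_deg, means, np.log(exc))))


def leaf_angle_distribution(alia_deg: float) -> np.ndarray:
    """Discrete ellipsoidal leaf-inclination density on the 13-class quadrature.

    The excentricity is calibrated numerically so the mean of the
    underlying continuous ellipsoidal distribution equals ``alia_deg``
    to well within half a degree; the returned frequencies (summing to
    1) are the integrals of that distribution over the 13 SAIL classes.
    """
    if not 0.0 < alia_deg <= 90.0:
        raise ValueError("ALIA must be in (0, 90] degrees")
    excent = excentricity_for_mean(alia_deg)
    return ellipsoidal_class_frequencies(excent, LIDF_ANGLE_BOUNDS_DEG)


def _volscatt(tts: float, tto: float, psi: float, ttl: float):
    """SUITS geometric factors for one leaf inclination class.

    Returns (chi_s, chi_o, frho, ftau): extinction cross-sections in the
    sun and view directions and the bidirectional area scattering factors
    multiplying leaf reflectance and transmittance.
    """
    cts = math.cos(_RD * tts)
    cto = math.cos(_RD * tto)
    sts = math.sin(_RD * tts)
    sto = math.sin(_RD * tto)
    cospsi = math.cos(_RD * psi)
    psir = _RD * psi
    costl = math.cos(_RD * ttl)
    sintl = math.sin(_RD * ttl)
    cs = costl * cts
    co = costl * cto
    ss = sintl * sts
    so = sintl * sto

    cosbts = 5.0
    if abs(ss) > 1e-6:
        cosbts = -cs / ss
    cosbto = 5.0
    if abs(so) > 1e-6:
        cosbto = -co / so

    if abs(cosbts) < 1.0:
        bts = math.acos(cosbts)
        ds = ss
    else:
        bts = math.pi
        ds = cs
    chi_s = 2.0 / math.pi * ((bts - math.pi * 0.5) * cs + math.sin(bts) * ss)

    if abs(cosbto) < 1.0:
        bto = math.acos(cosbto)
        do_ = so
    else:
        if tto < 90.0:
            bto = math.pi
            do_ = co
        else:
            bto = 0.0
            do_ = -co
    chi_o = 2.0 / math.pi * ((bto - math.pi * 0.5) * co + math.sin(bto) * so)

    btran1 = abs(bts - bto)
    btran2 = math.pi - abs(bts + bto - math.pi)
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    else:
        bt1 = btran1
        if psir <= btran2:
            bt2, bt3 = psir, btran2
        else:
            bt2, bt3 = btran2, psir

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = 0.0
    if bt2 > 0.0:
        t2 = math.sin(bt2) * (2.0 * ds * do_ + ss * so * math.cos(bt1) * math.cos(bt3))
    denom = 2.0 * math.pi**2
    frho = ((math.pi - bt2) * t1 + t2) / denom
    ftau = (-bt2 * t1 + t2) / denom
    return chi_s, chi_o, max(frho, 0.0), max(ftau, 0.0)


def geometric_coefficients(lidf: np.ndarray, tts: float, tto: float, psi: float):
    """Canopy-level SUITS coefficients averaged over the inclination classes.

    Returns (ks, ko, bf, sob, sof): directional extinction coefficients
    for sun and view, the mean squared cosine of leaf inclination, and
    the bidirectional scattering weights.
    """
    cts = math.cos(_RD * tts)
    cto = math.cos(_RD * tto)
    ctscto = cts * cto
    ks = ko = bf = sob = sof = 0.0
    for i, ttl in enumerate(LIDF_ANGLES_DEG):
        chi_s, chi_o, frho, ftau = _volscatt(tts, tto, psi, ttl)
        ctl = math.cos(_RD * ttl)
        ks += chi_s / cts * lidf[i]
        ko += chi_o / cto * lidf[i]
        bf += ctl * ctl * lidf[i]
        sob += frho * math.pi / ctscto * lidf[i]
        sof += ftau * math.pi / ctscto * lidf[i]
    return ks, ko, bf, sob, sof


def _jfunc1(k: float, m: np.ndarray, t: float) -> np.ndarray:
    # J1(k, m, t) with a series expansion near the k = m singularity.
    delt = (k - m) * t
    safe = np.where(np.abs(delt) > 1e-3, k - m, 1.0)
    out = np.where(
        np.abs(delt) > 1e-3,
        (np.exp(-m * t) - np.exp(-k * t)) / safe,
        0.5 * t * (np.exp(-k * t) + np.exp(-m * t)) * (1.0 - delt**2 / 12.0),
    )
    return out


def _jfunc2(k: float, m: np.ndarray, t: float) -> np.ndarray:
    return (1.0 - np.exp(-(k + m) * t)) / (k + m)


def _hotspot_integral(lai: float, ks: float, ko: float, hot: float, dso: float):
    """Bidirectional gap-probability integral with the hot-spot correction.

    Returns (tsstoo, sumint): the joint sun-view gap transmittance and the
    path integral weighting single scattering.
    """
    alf = 1e36
    if hot > 0.0:
        alf = (dso / hot) * 2.0 / (ks + ko)
    if alf == 0.0:
        # Exact backscattering: sun and view paths coincide.
        tss = math.exp(-ks * lai)
        return tss, (1.0 - tss) / (ks * lai)
    fhot = lai * math.sqrt(ko * ks)
    # Integrate in 20 exponential steps.
    x1 = 0.0
    y1 = 0.0
    f1 = 1.0
    fint = (1.0 - math.exp(-alf)) * 0.05
    sumint = 0.0
    for istep in range(1, 21):
        if istep < 20:
            x2 = -math.log(1.0 - istep * fint) / alf
        else:
            x2 = 1.0
        y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - math.exp(-alf * x2)) / alf
        f2 = math.exp(y2)
        sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
        x1, y1, f1 = x2, y2, f2
    if not math.isfinite(sumint):
        sumint = 0.0
    return f1, sumint


def canopy_brf(
    leaf_r: Spectrum,
    leaf_t: Spectrum,
    cp: CanopyParams,
    g: ViewGeometry,
    soil: Spectrum,
    skyl: float = 0.0,
) -> Spectrum:
    """Canopy directional reflectance factor for direct-sun illumination.

    ``skyl`` is the diffuse fraction of incoming radiation (0 by default:
    imagery corrected to surface reflectance under clear sky); for
    skyl > 0 the result blends the sun-to-view and sky-to-view factors.
    An empty canopy (LAI = 0) returns the soil spectrum exactly.
    """
    if not np.array_equal(leaf_r.wavelengths, leaf_t.wavelengths) or not np.array_equal(
        leaf_r.wavelengths, soil.wavelengths
    ):
        raise ValueError("leaf and soil spectra must share the same wavelength grid")
    if not 0.0 <= skyl <= 1.0:
        raise ValueError("diffuse fraction skyl must be in [0, 1]")
    rho = leaf_r.values
    tau = leaf_t.values
    rsoil = soil.values
    lai = cp.lai
    if lai <= 0.0:
        return Spectrum(soil.wavelengths, rsoil.copy())

    tts, tto, psi = g.canonical()
    lidf = leaf_angle_distribution(cp.alia)
    ks, ko, bf, sob, sof = geometric_coefficients(lidf, tts, tto, psi)

    sdb = 0.5 * (ks + bf)
    sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf)
    dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1.0 + bf)
    ddf = 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m2 = np.maximum((att + sigb) * (att - sigb), 0.0)
    m = np.sqrt(m2)
    sb = sdb * rho + sdf * tau
    sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau
    vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    tss = math.exp(-ks * lai)
    too = math.exp(-ko * lai)
    z = _jfunc2(ks, np.asarray(ko, dtype=float), lai)
    e1 = np.exp(-m * lai)
    e2 = e1**2
    rinf = np.where(sigb > 0, (att - m) / np.where(sigb > 0, sigb, 1.0), 0.0)
    rinf2 = rinf**2
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    j1ks = _jfunc1(ks, m, lai)
    j2ks = _jfunc2(ks, m, lai)
    j1ko = _jfunc1(ko, m, lai)
    j2ko = _jfunc2(ko, m, lai)

    ps = (sf + sb * rinf) * j1ks
    qs = (sf * rinf + sb) * j2ks
    pv = (vf + vb * rinf) * j1ko
    qv = (vf * rinf + vb) * j2ko

    rdd = rinf * (1.0 - e2) / denom
    tdd = (1.0 - rinf2) * e1 / denom
    tsd = (ps - re * qs) / denom
    rsd = (qs - re * ps) / denom
    tdo = (pv - re * qv) / denom
    rdo = (qv - re * pv) / denom

    # Hot-spot single-scattering and joint gap probability.
    tants = math.tan(_RD * tts)
    tanto = math.tan(_RD * tto)
    cospsi = math.cos(_RD * psi)
    dso = math.sqrt(tants**2 + tanto**2 - 2.0 * tants * tanto * cospsi)
    tsstoo, sumint = _hotspot_integral(lai, ks, ko, cp.hot, dso)

    rsos = w * lai * sumint  # single scattering in the sun-view plane

    # Multiple-scattering contribution to the bidirectional factor.
    g1 = (z - j1ks * too) / (ko + m)
    g2 = (z - j1ko * tss) / (ks + m)
    tv1 = (vf * rinf + vb) * g1
    tv2 = (vf + vb * rinf) * g2
    t1 = tv1 * (sf + sb * rinf)
    t2 = tv2 * (sf * rinf + sb)
    t3 = (rdo * qs + tdo * ps) * rinf
    rsod = (t1 + t2 - t3) / (1.0 - rinf2)

    # Couple the canopy layer with the soil lower boundary.
    dn = 1.0 - rsoil * rdd
    rddt = rdd + tdd * rsoil * tdd / dn
    rsdt = rsd + (tsd + tss) * rsoil * tdd / dn
    rdot = rdo + tdd * rsoil * (tdo + too) / dn
    rsodt = ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn + rsod
    rsost = rsos + tsstoo * rsoil
    rsot = rsost + rsodt

    out = (1.0 - skyl) * rsot + skyl * rdot
    out = np.clip(out, 0.0, 1.0)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("4-SAIL produced non-finite reflectance")
    return Spectrum(soil.wavelengths, out)
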