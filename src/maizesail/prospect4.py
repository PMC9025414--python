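"""PROSPECT-4 leaf radiative transfer: the generalized plate model.

A leaf is represented as a stack of N compact layers separated by air
gaps.  Four parameters drive the model: the mesophyll structure index N
(number of layers, continuous), chlorophyll a+b content Cab (ug/cm2),
equivalent water thickness Cw (cm) and dry matter content Cm (g/cm2).
Per-layer absorption is k(lambda) = (Cab*k_cab + Cw*k_cw + Cm*k_cm) / N;
the transmissivity of an elementary layer follows the exponential-integral
form, interface transmittances for oblique incidence come from the leaf
refractive index n(lambda), and the N-layer stack is solved with the
Stokes system for reflectance and transmittance.

The specific absorption coefficients and refractive index are supplied as
:class:`LeafOpticalConstants`.  The package ships no measured coefficient
table; unit tests and the synthetic campaigns run on the documented
synthetic surrogate (:func:`synthetic_constants`), and a measured table in
the same four-column text schema can be dropped in via
:func:`read_constants`.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import exp1

from .bands import Spectrum

__all__ = [
    "LeafParams",
    "LeafOpticalConstants",
    "synthetic_constants",
    "leaf_rt",
    "read_constants",
    "write_constants",
    "tav",
]

#: Solid-angle half-aperture (degrees) of incident light at the top leaf
#: surface; the standard value of the plate model family.
INCIDENCE_ANGLE_DEG = 40.0


@dataclass(frozen=True)
class LeafParams:
    """PROSPECT-4 free parameters.

    Attributes
    ----------
    n : mesophyll structure index (number of elementary layers), >= 1.
    cab : chlorophyll a+b content, ug/cm2.
    cw : equivalent water thickness, cm.
    cm : dry matter content, g/cm2.
    """

    n: float = 1.5
    cab: float = 50.0
    cw: float = 0.02
    cm: float = 0.005

    def __post_init__(self) -> None:
        if not self.n >= 1.0:
            raise ValueError(f"mesophyll structure index N must be >= 1, got {self.n}")
        for name in ("cab", "cw", "cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class LeafOpticalConstants:
    """Refractive index and specific absorption coefficients on the 1-nm grid.

    Parameters are per unit of the corresponding content: k_cab per ug/cm2,
    k_cw per cm, k_cm per g/cm2.  Interface transmissivities, which depend
    only on n(lambda), are computed once and cached.
    """

    def __init__(
        self,
        wavelengths: np.ndarray,
        refractive_index: np.ndarray,
        k_cab: np.ndarray,
        k_cw: np.ndarray,
        k_cm: np.ndarray,
    ) -> None:
        wl = np.asarray(wavelengths, dtype=float)
        n = np.asarray(refractive_index, dtype=float)
        kc = np.asarray(k_cab, dtype=float)
        kw = np.asarray(k_cw, dtype=float)
        km = np.asarray(k_cm, dtype=float)
        for arr, name in ((n, "refractive_index"), (kc, "k_cab"), (kw, "k_cw"), (km, "k_cm")):
            if arr.shape != wl.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        if np.any(n < 1.0):
            raise ValueError("refractive index must be >= 1")
        if np.any(kc < 0) or np.any(kw < 0) or np.any(km < 0):
            raise ValueError("specific absorption coefficients must be non-negative")
        self.wavelengths = wl
        self.refractive_index = n
        self.k_cab = kc
        self.k_cw = kw
        self.k_cm = km
        # Interface terms depend only on n(lambda): cache for reuse across
        # the tens of thousands of look-up-table simulations.
        self._t12_alpha = tav(INCIDENCE_ANGLE_DEG, n)
        self._tav90 = tav(90.0, n)


def tav(theta_deg: float, refr: np.ndarray) -> np.ndarray:
    """Average transmissivity of a dielectric interface.

    Transmissivity of a plane dielectric surface of refractive index
    ``refr`` averaged over all directions of incidence within a cone of
    half-angle ``theta_deg``, following the classical elliptic-integral
    solution used by the plate model family.
    """
    refr = np.asarray(refr, dtype=float)
    theta = np.radians(theta_deg)
    if theta_deg < 0.1:  # normal-incidence limit; avoids catastrophic cancellation
        return 4.0 * refr / (refr + 1.0) ** 2
    refr2 = refr * refr
    ax = (refr + 1.0) ** 2 / 2.0
    bx = -((refr2 - 1.0) ** 2) / 4.0
    sin2 = np.sin(theta) ** 2
    if abs(theta_deg - 90.0) < 1e-12:
        b1 = np.zeros_like(refr)
    else:
        b1 = np.sqrt((sin2 - (refr2 + 1.0) / 2.0) ** 2 + bx)
    b2 = sin2 - (refr2 + 1.0) / 2.0
    b0 = b1 - b2
    ts = (bx**2 / (6.0 * b0**3) + bx / b0 - b0 / 2.0) - (
        bx**2 / (6.0 * ax**3) + bx / ax - ax / 2.0
    )
    tp1 = -2.0 * refr2 * (b0 - ax) / (refr2 + 1.0) ** 2
    tp2 = -2.0 * refr2 * (refr2 + 1.0) * np.log(b0 / ax) / (refr2 - 1.0) ** 2
    tp3 = refr2 * (1.0 / b0 - 1.0 / ax) / 2.0
    tp4 = (
        16.0
        * refr2**2
        * (refr2**2 + 1.0)
        * np.log(
            (2.0 * (refr2 + 1.0) * b0 - (refr2 - 1.0) ** 2)
            / (2.0 * (refr2 + 1.0) * ax - (refr2 - 1.0) ** 2)
        )
        / ((refr2 + 1.0) ** 3 * (refr2 - 1.0) ** 2)
    )
    tp5 = (
        16.0
        * refr2**3
        * (
            1.0 / (2.0 * (refr2 + 1.0) * b0 - (refr2 - 1.0) ** 2)
            - 1.0 / (2.0 * (refr2 + 1.0) * ax - (refr2 - 1.0) ** 2)
        )
        / (refr2 + 1.0) ** 3
    )
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * sin2)


def synthetic_constants() -> LeafOpticalConstants:
    """Documented synthetic leaf optical constants for the 400-850 nm grid.

    A smooth, physically plausible surrogate: refractive index falling
    linearly from 1.45 at 400 nm (1e-4 per nm); a chlorophyll specific
    absorption built from two unit-peak Gaussians, 0.06 * G(430, 30) +
    0.10 * G(662, 25) per ug/cm2; zero water absorption below 850 nm
    (water absorbs further into the infrared); and a flat dry-matter
    coefficient of 4 per g/cm2, sized so that at a typical dry-matter
    content (0.005 g/cm2) the leaf keeps the high near-infrared
    single-scattering albedo (~0.9) of real leaves — without it canopy
    NIR reflectance would not respond to leaf area at all.
    """
    wl = np.arange(400.0, 851.0)
    n = 1.45 - 1e-4 * (wl - 400.0)
    k_cab = 0.06 * np.exp(-0.5 * ((wl - 430.0) / 30.0) ** 2) + 0.10 * np.exp(
        -0.5 * ((wl - 662.0) / 25.0) ** 2
    )
    k_cw = np.zeros_like(wl)
    k_cm = np.full_like(wl, 4.0)
    return LeafOpticalConstants(wl, n, k_cab, k_cw, k_cm)


def _layer_transmissivity(k: np.ndarray) -> np.ndarray:
    # Transmissivity of an elementary absorbing layer under isotropic
    # internal illumination: (1 - k) e^{-k} + k^2 E1(k), continuous at k=0.
    theta = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    theta[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return theta


def leaf_rt(p: LeafParams, c: LeafOpticalConstants) -> "tuple[Spectrum, Spectrum]":
    """Directional-hemispherical leaf reflectance and transmittance.

    Returns two :class:`~maizesail.bands.Spectrum` objects on the grid of
    the constants.  Always satisfies 0 < R, T and R + T <= 1, with equality
    only where the absorption vanishes.
    """
    nl = p.n
    k = (p.cab * c.k_cab + p.cw * c.k_cw + p.cm * c.k_cm) / nl
    theta = _layer_transmissivity(k)

    refr = c.refractive_index
    t12 = c._t12_alpha          # top surface, incidence within the 40 deg cone
    tav90 = c._tav90            # isotropic (internal) incidence
    t21 = tav90 / refr**2       # leaving the leaf from inside
    r12 = 1.0 - t12
    r21 = 1.0 - t21
    x = t12 / tav90
    y = x * (tav90 - 1.0) + 1.0 - t12

    # Reflectance/transmittance of the top elementary layer (oblique top
    # interface) via the closed-form multiple-reflection series.
    denom_l = 1.0 - (r21 * theta) ** 2
    ra = r12 + t12 * t21 * r21 * theta**2 / denom_l
    ta = t12 * t21 * theta / denom_l
    # Equivalent layer with isotropic illumination on both faces.
    r90 = (ra - y) / x
    t90 = ta / x

    # Stokes solution for the N-1 layers beneath the top layer.
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.sqrt(
            np.maximum((t90**2 - r90**2 - 1.0) ** 2 - 4.0 * r90**2, 0.0)
        )
        beta = (1.0 + r90**2 - t90**2 - delta) / (2.0 * r90)
        va = (1.0 + r90**2 - t90**2 + delta) / (2.0 * r90)
        vb = np.sqrt(beta * (va - r90) / (va * (beta - r90)))
        vbnn = vb ** (nl - 1.0)
        vbnn2 = vbnn**2
        va2 = va**2
        denx = va2 * vbnn2 - 1.0
        r_sub = va * (vbnn2 - 1.0) / denx
        t_sub = vbnn * (va2 - 1.0) / denx

    # Conservative (non-absorbing) wavelengths degenerate in the Stokes
    # algebra; the limit is the classical pile-of-plates formula.
    cons = (r90 + t90) >= 1.0 - 1e-12
    if np.any(cons):
        tc = t90[cons]
        t_sub[cons] = tc / (tc + (1.0 - tc) * (nl - 1.0))
        r_sub[cons] = 1.0 - t_sub[cons]

    denom = 1.0 - r_sub * r90
    tran = ta * t_sub / denom
    refl = ra + ta * r_sub * t90 / denom

    if not (np.all(np.isfinite(refl)) and np.all(np.isfinite(tran))):
        raise FloatingPointError("leaf radiative transfer produced non-finite output")
    return (
        Spectrum(c.wavelengths, refl),
        Spectrum(c.wavelengths, tran),
    )


# ---------------------------------------------------------------------------
# constants file schema: wavelength_nm, n, k_cab, k_cw, k_cm

_CONSTANT_COLUMNS = ("wavelength_nm", "n", "k_cab", "k_cw", "k_cm")


def write_constants(c: LeafOpticalConstants, path: "str | Path") -> None:
    pd.DataFrame(
        {
            "wavelength_nm": c.wavelengths,
            "n": c.refractive_index,
            "k_cab": c.k_cab,
            "k_cw": c.k_cw,
            "k_cm": c.k_cm,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_constants(path: "str | Path") -> LeafOpticalConstants:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [col for col in _CONSTANT_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"constants file missing columns: {missing}")
    return LeafOpticalConstants(
        df["wavelength_nm"].to_numpy(dtype=float),
        df["n"].to_numpy(dtype=float),
        df["k_cab"].to_numpy(dtype=float),
        df["k_cw"].to_numpy(dtype=float),
        df["k_cm"].to_numpy(dtype=float),
    )
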