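"""Shared fixtures: sensor grid, surrogate optics, soil, and a small LUT."""
from __future__ import annotations

import pytest

from maizesail import bands, foursail, lut, prospect4


@pytest.fixture(scope="session")
def band_set():
    return bands.default_band_set()


@pytest.fixture(scope="session")
def constants():
    return prospect4.synthetic_constants()


@pytest.fixture(scope="session")
def soil_ref():
    return foursail.default_soil()


@pytest.fixture(scope="session")
def leaf_spectra(constants):
    return prospect4.leaf_rt(
        prospect4.LeafParams(n=1.6, cab=55.0, cw=0.02, cm=0.005), constants
    )


@pytest.fixture(scope="session")
def small_lut(band_set, constants, soil_ref):
    """300-record LUT on the default design, reused across tests."""
    cfg = lut.default_sampling_config(n=300, seed=42)
    return lut.build_lut(cfg, band_set, constants, soil_ref)


@pytest.fixture(scope="session")
def resample_weights(band_set, constants):
    return bands.resample_matrix(band_set, constants.wavelengths)
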