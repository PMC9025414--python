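"""Look-up table: sampling design, LSE cost, inversion vs a brute-force
oracle, sensitivity indices, persistence."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maizesail import bands, lut as lut_mod
from maizesail.bands import BandSpectrum
from maizesail.lut import (
    LUT,
    ParamSpec,
    SamplingConfig,
    build_lut,
    default_sampling_config,
    gsa_first_order,
    invert,
    lse_cost,
    read_lut,
    read_lut_binary,
    sample_params,
    write_lut,
    write_lut_binary,
)


class TestSamplingConfig:
    def test_default_replicates_study_design(self):
        cfg = default_sampling_config()
        assert cfg.n == 60750
        assert cfg.free_names == ("n", "cab", "lai", "alia", "hot", "alpha_soil",
                                  "theta_v", "phi_sv")
        assert cfg.params["cw"].lo == 0.02 and cfg.params["cw"].is_fixed
        assert cfg.params["cm"].lo == 0.005 and cfg.params["cm"].is_fixed
        assert cfg.params["theta_s"].lo == 49.0 and cfg.params["theta_s"].is_fixed
        assert cfg.params["lai"].scheme == "lhs"
        assert (cfg.params["lai"].lo, cfg.params["lai"].hi) == (0.5, 7.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            ParamSpec(2.0, 1.0)

    def test_zero_samples_rejected(self):
        cfg = default_sampling_config()
        with pytest.raises(ValueError):
            cfg.replace(n=0)


class TestSampling:
    def test_seeded_determinism(self):
        cfg = default_sampling_config(n=10, seed=5)
        a, b = sample_params(cfg), sample_params(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_lai_latin_hypercube_strata(self):
        cfg = default_sampling_config(n=100, seed=3)
        lai = sample_params(cfg)["lai"].to_numpy()
        strata = np.floor((lai - 0.5) / (6.5 / 100)).astype(int)
        assert sorted(strata) == list(range(100))

    def test_all_within_ranges(self):
        cfg = default_sampling_config(n=200, seed=1)
        df = sample_params(cfg)
        for name, spec in cfg.params.items():
            assert df[name].between(spec.lo, spec.hi).all()


class TestLseCost:
    def test_identical_spectra_cost_zero(self, band_set):
        s = BandSpectrum(band_set, np.full(55, 0.3))
        assert lse_cost(s, s) == 0.0

    def test_constant_difference(self, band_set):
        a = BandSpectrum(band_set, np.full(55, 0.5))
        b = BandSpectrum(band_set, np.full(55, 0.4))
        assert lse_cost(a, b) == pytest.approx(0.55, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, band_set, seed):
        rng = np.random.default_rng(seed)
        a = BandSpectrum(band_set, rng.uniform(0, 1, 55))
        b = BandSpectrum(band_set, rng.uniform(0, 1, 55))
        assert lse_cost(a, b) == lse_cost(b, a)

    def test_band_set_mismatch_rejected(self, band_set):
        other = bands.make_band_grid(400, 850, 7.5)  # no exclusions
        a = BandSpectrum(band_set, np.full(55, 0.3))
        b = BandSpectrum(other, np.full(61, 0.3))
        with pytest.raises(ValueError, match="band set"):
            lse_cost(a, b)

    def test_excluding_band_removes_exactly_its_contribution(self, band_set):
        rng = np.random.default_rng(7)
        va, vb = rng.uniform(0, 1, 55), rng.uniform(0, 1, 55)
        full = lse_cost(BandSpectrum(band_set, va), BandSpectrum(band_set, vb))
        # deactivate one more band
        drop_center = band_set.active_centers[10]
        smaller = bands.apply_exclusions(band_set, [drop_center], tol_nm=1)
        keep = np.ones(55, dtype=bool)
        keep[10] = False
        partial = lse_cost(
            BandSpectrum(smaller, va[keep]), BandSpectrum(smaller, vb[keep])
        )
        assert full - partial == pytest.approx((va[10] - vb[10]) ** 2, rel=1e-9)


class TestInvert:
    def test_self_retrieval_of_exact_record(self, small_lut):
        i = 123
        obs = BandSpectrum(small_lut.band_set, small_lut.reflectance[i])
        res = invert(obs, small_lut, fraction=1.0 / small_lut.n)
        for p in small_lut.free_names:
            assert res.estimates[p] == small_lut.params[p].iloc[i]
        assert res.best_cost == 0.0
        assert res.n_retained == 1

    def test_fraction_one_returns_prior_mean(self, small_lut):
        rng = np.random.default_rng(0)
        r1 = invert(BandSpectrum(small_lut.band_set, rng.uniform(0, 1, 55)), small_lut, 1.0)
        r2 = invert(BandSpectrum(small_lut.band_set, rng.uniform(0, 1, 55)), small_lut, 1.0)
        for p in small_lut.free_names:
            assert r1.estimates[p] == pytest.approx(small_lut.params[p].mean(), rel=1e-12)
            assert r1.estimates[p] == pytest.approx(r2.estimates[p], rel=1e-12)

    @pytest.mark.parametrize("fraction", [0.01, 0.1, 0.33])
    def test_matches_bruteforce_oracle(self, small_lut, fraction):
        # naive oracle: full cost vector, stable full sort, mean/std by hand
        rng = np.random.default_rng(11)
        obs_vals = rng.uniform(0.0, 0.4, 55)
        res = invert(BandSpectrum(small_lut.band_set, obs_vals), small_lut, fraction)
        costs = np.array(
            [float(((small_lut.reflectance[j] - obs_vals) ** 2).sum())
             for j in range(small_lut.n)]
        )
        k = math.ceil(fraction * small_lut.n)
        order = sorted(range(small_lut.n), key=lambda j: (costs[j], j))[:k]
        assert list(res.retained_indices) == order
        for p in small_lut.free_names:
            vals = small_lut.params[p].to_numpy()[order]
            assert res.estimates[p] == pytest.approx(float(vals.mean()), rel=1e-12)
            assert res.dispersion[p] == pytest.approx(float(vals.std()), rel=1e-9)

    def test_empty_lut_rejected(self, band_set):
        empty = LUT(
            params=pd.DataFrame(columns=list(lut_mod.PARAM_NAMES), dtype=float),
            reflectance=np.empty((0, 55)),
            band_set=band_set,
            free_names=("lai",),
        )
        with pytest.raises(ValueError, match="empty"):
            invert(BandSpectrum(band_set, np.full(55, 0.2)), empty)

    def test_geometry_subset_window(self, small_lut):
        sub = small_lut.subset_geometry(theta_v=(-5.0, 5.0))
        assert sub.n < small_lut.n
        assert sub.params["theta_v"].between(-5, 5).all()
        with pytest.raises(ValueError, match="empty"):
            small_lut.subset_geometry(theta_v=(30.0, 40.0))


class TestBuildLut:
    def test_reproducible_given_seed(self, band_set, constants, soil_ref):
        cfg = default_sampling_config(n=10, seed=21)
        a = build_lut(cfg, band_set, constants, soil_ref)
        b = build_lut(cfg, band_set, constants, soil_ref)
        pd.testing.assert_frame_equal(a.params, b.params)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_reflectances_physical(self, small_lut):
        assert np.all((small_lut.reflectance >= 0) & (small_lut.reflectance <= 1))
        assert small_lut.reflectance.shape == (300, 55)


class TestGsa:
    def test_too_few_samples_rejected(self, band_set, constants, soil_ref):
        cfg = default_sampling_config(n=10)
        with pytest.raises(ValueError, match="50"):
            gsa_first_order(cfg, 100, 10, band_set, constants, soil_ref)

    def test_fixed_parameter_has_zero_index(self, band_set, constants, soil_ref):
        cfg = default_sampling_config(n=10, seed=2)
        df = gsa_first_order(cfg, 500, 10, band_set, constants, soil_ref, seed=2)
        assert np.all(df.loc["cm"].to_numpy() == 0.0)
        assert np.all(df.loc["theta_s"].to_numpy() == 0.0)

    def test_lai_is_a_leading_driver_in_red_and_nir(self, band_set, constants, soil_ref):
        # red responds to LAI through soil darkening, NIR through
        # multiple scattering; in both windows LAI carries substantial
        # first-order variance (the NIR share is diluted by the leaf
        # inclination angle, which trades against LAI there)
        cfg = default_sampling_config(n=10, seed=2)
        df = gsa_first_order(cfg, 1500, 10, band_set, constants, soil_ref, seed=5)
        centers = band_set.active_centers
        i_red = int(np.argmin(np.abs(centers - 662)))
        nir = df.loc["lai"].to_numpy()[centers >= 780]
        assert df.loc["lai"].iloc[i_red] > 0.3
        assert nir.min() > 0.15
        assert np.all((df.to_numpy() >= 0) & (df.to_numpy() <= 1.05))


class TestPersistence:
    def test_text_round_trip_is_exact(self, tmp_path, small_lut):
        write_lut(small_lut, tmp_path / "lut")
        back = read_lut(tmp_path / "lut")
        pd.testing.assert_frame_equal(back.params, small_lut.params)
        np.testing.assert_array_equal(back.reflectance, small_lut.reflectance)
        assert back.band_set == small_lut.band_set
        assert back.free_names == small_lut.free_names

    def test_binary_round_trip_is_bit_exact(self, tmp_path, small_lut):
        p = tmp_path / "lut.bin"
        write_lut_binary(small_lut, p)
        back = read_lut_binary(p)
        np.testing.assert_array_equal(back.params.to_numpy(), small_lut.params.to_numpy())
        np.testing.assert_array_equal(back.reflectance, small_lut.reflectance)
        assert back.config_hash == small_lut.config_hash

    def test_binary_magic_checked(self, tmp_path):
        p = tmp_path / "junk.bin"
        p.write_bytes(b"not a lut")
        with pytest.raises(ValueError, match="binary LUT"):
            read_lut_binary(p)
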