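"""Synthetic field campaigns: design arithmetic, growth and yield
structure, forward-simulated spectra and their closure properties."""
import numpy as np
import pandas as pd
import pytest

from maizesail import bands, lut as lut_mod, synthetic_data as sd
from maizesail.bands import BandSpectrum


@pytest.fixture(scope="module")
def default_design():
    return sd.make_design(seed=0)


class TestDesign:
    def test_replicates_study_counts(self, default_design):
        designs, campaign = default_design
        assert designs["F1"].n_points == 26
        assert designs["F1"].n_calibration == 12
        assert designs["F2"].n_points == 25
        assert designs["F2"].n_calibration == 0
        assert campaign.lai_das["F1"] == (40, 53, 74, 107, 123)

    def test_yield_point_accounting(self, default_design):
        designs, _ = default_design
        total = sum(d.n_points for d in designs.values())
        held_out = total - designs["F1"].n_calibration
        assert total == 51
        assert held_out == 39

    def test_seeded_coordinates_reproducible(self):
        a, _ = sd.make_design(seed=7)
        b, _ = sd.make_design(seed=7)
        for fid in ("F1", "F2"):
            pd.testing.assert_frame_equal(a[fid].points, b[fid].points)
            np.testing.assert_array_equal(a[fid].calibration, b[fid].calibration)

    def test_excess_calibration_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            sd.make_design({"F1": {"n_points": 5, "n_calibration": 6}}, seed=0)


class TestFootprint:
    def test_default_is_8_m2(self, default_design):
        designs, _ = default_design
        assert sd.footprint_area(designs["F1"]) == pytest.approx(8.0)

    def test_single_row_halves(self, default_design):
        designs, _ = default_design
        import dataclasses

        one_row = dataclasses.replace(designs["F1"], rows_per_sample=1)
        assert sd.footprint_area(one_row) == pytest.approx(4.0)

    def test_zero_length_degenerate(self, default_design):
        designs, _ = default_design
        import dataclasses

        flat = dataclasses.replace(designs["F1"], row_length=0.0)
        assert sd.footprint_area(flat) == 0.0


class TestGroundRecords:
    def test_f1_has_60_lai_records(self, default_design):
        designs, campaign = default_design
        g = sd.simulate_ground(designs, campaign, seed=0)
        lai = g[g["lai"].notna()]
        assert len(lai) == 60
        assert (lai["field"] == "F1").all()

    def test_biomass_bounds_yield(self, default_design):
        designs, campaign = default_design
        g = sd.simulate_ground(designs, campaign, seed=0)
        h = g[g["biomass"].notna()]
        assert len(h) == 51
        assert (h["biomass"] >= h["grain_yield"]).all()
        assert (h["grain_yield"] >= 0).all()

    def test_noise_free_biomass_monotone_in_plateau(self, default_design):
        designs, campaign = default_design
        quiet = {
            fid: sd.GrowthModel(
                stress_scale=gm.stress_scale,
                lai_noise_sd=0.0,
                biomass_noise_sd=0.0,
                yield_noise_sd=0.0,
            )
            for fid, gm in sd.DEFAULT_GROWTH.items()
        }
        g = sd.simulate_ground(designs, campaign, growth=quiet, seed=3)
        h = g[(g["field"] == "F1") & g["biomass"].notna()]
        # noise-free transfer is linear in the plateau: biomass order must
        # match yield order exactly
        assert (
            h.sort_values("biomass")["grain_yield"].is_monotonic_increasing
        )

    def test_f2_outyields_f1(self, default_design):
        designs, campaign = default_design
        g = sd.simulate_ground(designs, campaign, seed=0)
        h = g[g["biomass"].notna()]
        means = h.groupby("field")["grain_yield"].mean()
        assert means["F2"] > means["F1"]

    def test_yields_within_study_ranges(self, default_design):
        # printed campaign ranges: F1 biomass 4.4-20, yield 1.4-9.2;
        # F2 biomass 14.8-26.7, yield 8-12 t/ha
        designs, campaign = default_design
        bounds = {
            "F1": {"biomass": (4.4, 20.0), "grain_yield": (1.4, 9.2)},
            "F2": {"biomass": (14.8, 26.7), "grain_yield": (8.0, 12.0)},
        }
        n_total = n_inside = 0
        for seed in range(10):
            g = sd.simulate_ground(designs, campaign, seed=seed)
            h = g[g["biomass"].notna()]
            for fid, b in bounds.items():
                sub = h[h["field"] == fid]
                for var, (lo, hi) in b.items():
                    n_total += len(sub)
                    n_inside += sub[var].between(lo, hi).sum()
        assert n_inside / n_total >= 0.95

    def test_lai_trajectory_anchors(self, default_design):
        # field mean ~1.3 m2/m2 at 40 DAS; seasonal maximum ~4.9 at 123 DAS
        designs, campaign = default_design
        m40, m123 = [], []
        for seed in range(5):
            g = sd.simulate_ground(designs, campaign, seed=seed)
            lai = g[g["lai"].notna()]
            m40.append(lai[lai["das"] == 40]["lai"].mean())
            m123.append(lai[lai["das"] == 123]["lai"].max())
        assert np.mean(m40) == pytest.approx(1.3, abs=0.3)
        assert np.mean(m123) == pytest.approx(4.9, abs=0.8)

    def test_ground_table_round_trip(self, tmp_path, default_design):
        designs, campaign = default_design
        g = sd.simulate_ground(designs, campaign, seed=1)
        p = tmp_path / "ground.csv"
        sd.write_ground_table(g, p)
        back = sd.read_ground_table(p)
        for col in ("lai", "biomass", "grain_yield"):
            np.testing.assert_array_equal(back[col].to_numpy(), g[col].to_numpy())


@pytest.fixture(scope="module")
def f1_spectra(default_design, band_set, constants, soil_ref):
    designs, campaign = default_design
    return sd.simulate_spectra(
        {"F1": designs["F1"]}, campaign, band_set, constants, soil_ref,
        seed=0, image_das={"F1": (40, 74)},
    )


class TestSimulatedSpectra:
    def test_same_seed_identical_tables(self, default_design, band_set, constants, soil_ref):
        designs, campaign = default_design
        kw = dict(seed=5, image_das={"F1": (53,)})
        a = sd.simulate_spectra({"F1": designs["F1"]}, campaign, band_set,
                                constants, soil_ref, **kw)
        b = sd.simulate_spectra({"F1": designs["F1"]}, campaign, band_set,
                                constants, soil_ref, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_reflectances_physical(self, f1_spectra, band_set):
        vals = bands.table_band_values(f1_spectra, band_set)
        assert np.all((vals >= 0) & (vals <= 1))
        assert len(f1_spectra) == 2 * 26

    def test_draws_respect_prior_ranges(self, f1_spectra):
        cfg = lut_mod.default_sampling_config()
        for name in ("n", "cab", "alia", "hot", "alpha_soil", "theta_v", "phi_sv"):
            spec = cfg.params[name]
            assert f1_spectra[name].between(spec.lo, spec.hi).all()

    def test_bare_point_spectrum_is_scaled_soil(self, band_set, constants, soil_ref):
        # the empty-canopy limit of the forward closure: LAI 0 reproduces
        # the brightness-scaled soil after band resampling
        w = bands.resample_matrix(band_set, constants.wavelengths)
        row = dict(n=1.5, cab=55.0, cw=0.02, cm=0.005, lai=0.0, alia=60.0,
                   hot=0.1, alpha_soil=0.4, theta_s=49.0, theta_v=5.0, phi_sv=90.0)
        refl = lut_mod.forward_reflectance(row, constants, soil_ref, w)
        expected = w @ (0.4 * soil_ref.spectrum.values)
        np.testing.assert_allclose(refl, expected, rtol=0, atol=1e-12)

    def test_spectra_table_round_trip(self, tmp_path, f1_spectra, band_set):
        p = tmp_path / "spectra.csv"
        bands.write_spectra_table(f1_spectra, p)
        back = bands.read_spectra_table(p, band_set)
        np.testing.assert_array_equal(
            bands.table_band_values(back, band_set),
            bands.table_band_values(f1_spectra, band_set),
        )


def test_noise_model_bounds_and_determinism():
    nm = sd.NoiseModel(multiplicative_sd=0.1, additive_sd=0.02)
    refl = np.linspace(0.0, 1.0, 55)
    a = nm.apply(refl, np.random.default_rng(3))
    b = nm.apply(refl, np.random.default_rng(3))
    np.testing.assert_array_equal(a, b)
    assert np.all((a >= 0) & (a <= 1))


def test_campaign_closure_recovers_lai(default_design, band_set, constants, soil_ref):
    """Noise-free campaign spectra inverted against a matched LUT track
    the true LAI closely (the ground-LAI range avoids deep saturation)."""
    designs, campaign = default_design
    sp = sd.simulate_spectra(
        {"F1": designs["F1"]}, campaign, band_set, constants, soil_ref,
        noise=None, seed=0, image_das={"F1": campaign.lai_das["F1"]},
    )
    cal = set(designs["F1"].points["point_id"][designs["F1"].calibration])
    sp = sp[sp["point_id"].isin(cal)].reset_index(drop=True)
    assert len(sp) == 60
    lut = lut_mod.build_lut(
        lut_mod.default_sampling_config(n=8000, seed=7), band_set, constants, soil_ref
    )
    vals = bands.table_band_values(sp, band_set)
    est = np.array(
        [
            lut_mod.invert(BandSpectrum(band_set, vals[i]), lut, 0.10).estimates["lai"]
            for i in range(len(sp))
        ]
    )
    true = np.clip(sp["true_lai"].to_numpy(), 0.5, 7.0)
    r2 = np.corrcoef(true, est)[0, 1] ** 2
    assert r2 >= 0.8
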