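"""Synthetic phantom generator: forward model, noise statistics, geometry."""

import numpy as np
import pytest

import hoquant as hq
from hoquant.core import AIR_HU
from hoquant.errors import ConfigurationError, GeometryError

from conftest import COARSE

ALL_PAIRS = ("70/150Sn", "80/150Sn", "100/150Sn", "80/140")


class TestEnhancementModel:
    def test_spectral_separation_everywhere(self):
        for vp in ALL_PAIRS:
            for d in (10.0, 15.0, 20.0, 25.0, 30.0, 35.0):
                v = hq.enhancement_model(vp, d)
                assert v.e_low != v.e_high

    @pytest.mark.parametrize("vp", ALL_PAIRS)
    def test_size_trend_monotonicity(self, vp):
        """Soft spectra (70/80 kV) gain enhancement with object size; hard
        spectra (100/140/150Sn) lose it — the k-edge size trend."""
        sizes = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
        lows = [hq.enhancement_model(vp, d).e_low for d in sizes]
        highs = [hq.enhancement_model(vp, d).e_high for d in sizes]
        low_kv = vp.split("/")[0]
        if low_kv in ("70", "80"):
            assert all(a <= b for a, b in zip(lows, lows[1:]))
        else:  # 100 kV side decreases
            assert all(a >= b for a, b in zip(lows, lows[1:]))
        # high-kV spectra (140, 150Sn) always decrease
        assert all(a >= b for a, b in zip(highs, highs[1:]))

    def test_unknown_pair_and_diameter_rejected(self):
        with pytest.raises(ConfigurationError):
            hq.enhancement_model("90/150Sn", 10.0)
        with pytest.raises(ConfigurationError):
            hq.enhancement_model("80/150Sn", 40.0)


class TestCalibrationPhantom:
    def test_water_insert_is_zero_hu_noiseless(self, noiseless_calibration):
        pair, _ = noiseless_calibration
        stats = hq.extract_roi_mean(pair, hq.calibration.WATER_ROI)
        assert stats[0] == 0.0 and stats[1] == 0.0

    def test_centric_insert_matches_forward_model_noiseless(self, noiseless_calibration):
        pair, _ = noiseless_calibration
        v = hq.enhancement_model("80/150Sn", 10.0)
        ho = hq.extract_roi_mean(pair, hq.calibration.HOLMIUM_ROI)
        assert ho[0] == pytest.approx(10.5 * v.e_low, abs=1e-12)
        assert ho[1] == pytest.approx(10.5 * v.e_high, abs=1e-12)

    def test_seeded_generation_is_bit_reproducible(self, coarse_cal_spec):
        a, _ = hq.make_calibration_phantom(coarse_cal_spec, seed=11)
        b, _ = hq.make_calibration_phantom(coarse_cal_spec, seed=11)
        c, _ = hq.make_calibration_phantom(coarse_cal_spec, seed=12)
        assert np.array_equal(a.low, b.low) and np.array_equal(a.high, b.high)
        assert not np.array_equal(a.low, c.low)

    def test_air_and_water_means_converge_low_noise(self, coarse_cal_spec):
        """Air -> -1000 HU and water -> 0 HU within 4 standard errors, in the
        low-noise regime where the -1024 floor clamp is inactive."""
        quiet = hq.NoiseModel(sigma_ref=(5.0, 4.0))
        pair, truth = hq.make_calibration_phantom(coarse_cal_spec, seed=5, noise=quiet)
        sig = pair.noise_sigma
        air = truth.material_mask == 0
        water = (truth.material_mask == 1) & (truth.deposit_labels == 0)
        for mask, target, s in ((air, AIR_HU, sig[0]), (water, 0.0, sig[0])):
            n = mask.sum()
            assert n > 1000
            assert abs(pair.low[mask].mean() - target) < 4 * s / np.sqrt(n)

    def test_layout_rejects_insert_outside_body(self):
        with pytest.raises(GeometryError):
            hq.PhantomLayout(
                background_material="air",
                body_semi_axes=(50.0, 50.0),
                inserts=(hq.Insert("cylinder", (0.0, 0.0, 45.0), (10.0,), 1.0),),
            )

    def test_layout_rejects_overlapping_inserts(self):
        with pytest.raises(GeometryError):
            hq.PhantomLayout(
                background_material="water",
                body_semi_axes=(50.0, 50.0),
                inserts=(
                    hq.Insert("cylinder", (0.0, 0.0, 0.0), (10.0,), 1.0),
                    hq.Insert("cylinder", (0.0, 0.0, 15.0), (10.0,), 2.0),
                ),
            )


class TestNoiseModel:
    def test_noise_sd_scales_with_sqrt_dose(self):
        """Measured background noise sd follows sigma_ref*sqrt(dose_ref/mAs)
        within 5% at n >= 1e4 voxels, and the high/clinical ratio is
        sqrt(mAs_clinical/mAs_high)."""
        spec_c = hq.AcquisitionSpec(phantom_diameter=20.0, dose_mode="clinical", **COARSE)
        spec_h = hq.AcquisitionSpec(phantom_diameter=20.0, dose_mode="high", **COARSE)
        pc, tc = hq.make_dilution_phantom([], spec_c, seed=21)
        ph, _ = hq.make_dilution_phantom([], spec_h, seed=21)
        water = tc.material_mask == 1
        assert water.sum() >= 10_000
        model = hq.NoiseModel()
        for pair, spec in ((pc, spec_c), (ph, spec_h)):
            expected = model.sigma(spec.resolve_tube_current())
            assert pair.low[water].std() == pytest.approx(expected[0], rel=0.05)
            assert pair.high[water].std() == pytest.approx(expected[1], rel=0.05)
        mas_c = spec_c.resolve_tube_current()
        mas_h = spec_h.resolve_tube_current()
        ratio = ph.low[water].std() / pc.low[water].std()
        assert ratio == pytest.approx(np.sqrt(mas_c[0] / mas_h[0]), rel=0.05)

    def test_hu_floor_clamp(self):
        spec = hq.AcquisitionSpec(phantom_diameter=10.0, **COARSE)
        loud = hq.NoiseModel(sigma_ref=(200.0, 200.0))
        pair, _ = hq.make_calibration_phantom(spec, seed=1, noise=loud)
        assert pair.low.min() >= -1024.0 and pair.high.min() >= -1024.0


class TestDilutionPhantom:
    def test_truth_matches_requested_series(self):
        concs = [2.0, 4.0, 6.0, 8.0, 10.0]
        spec = hq.AcquisitionSpec(phantom_diameter=20.0, **COARSE)
        pair, truth = hq.make_dilution_phantom(concs, spec, seed=1)
        assert len(truth.layout.inserts) == 5
        got = sorted(ins.concentration for ins in truth.layout.inserts)
        assert got == sorted(concs)
        labels = set(np.unique(truth.deposit_labels)) - {0}
        assert labels == {1, 2, 3, 4, 5}

    def test_empty_series_gives_background_only(self):
        spec = hq.AcquisitionSpec(phantom_diameter=20.0, **COARSE)
        _, truth = hq.make_dilution_phantom([], spec, seed=0)
        assert truth.concentration.max() == 0.0
        assert truth.masses_mg == {}

    def test_noiseless_forward_model_linear_in_concentration(self):
        """R^2 of noiseless insert HU vs concentration is 1 to machine
        precision for any series (forward model linearity)."""
        concs = [0.5, 1.0, 2.0, 5.0, 8.0]
        spec = hq.AcquisitionSpec(phantom_diameter=20.0, **COARSE)
        pair, truth = hq.make_dilution_phantom(concs, spec, seed=0, noise=hq.NO_NOISE)
        means = []
        for ins in truth.layout.inserts:
            roi = hq.RoiSpec("cylinder", ins.center, radius=ins.size[0])
            means.append(hq.extract_roi_mean(pair, roi)[0])
        fit = hq.linear_fit([i.concentration for i in truth.layout.inserts], means)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.b == pytest.approx(0.0, abs=1e-9)

    def test_overcrowded_ring_is_geometry_error(self):
        spec = hq.AcquisitionSpec(phantom_diameter=20.0, **COARSE)
        with pytest.raises(GeometryError):
            hq.make_dilution_phantom([1.0] * 9, spec, seed=0)

    def test_negative_concentration_rejected(self):
        spec = hq.AcquisitionSpec(phantom_diameter=20.0, **COARSE)
        with pytest.raises(ConfigurationError):
            hq.make_dilution_phantom([-1.0], spec, seed=0)


class TestAnimalPhantom:
    def test_truth_mass_equals_requested_mass(self):
        deposits = [
            hq.Deposit(5.61, (0.0, -35.0, -55.0), 0.40),
            hq.Deposit(5.96, (0.0, 35.0, 55.0), 0.40),
            hq.Deposit(12.59, (0.0, 30.0, -55.0), 0.70),
        ]
        spec = hq.AcquisitionSpec(phantom_diameter="animal", **COARSE)
        _, truth = hq.make_animal_phantom(deposits, spec, seed=2)
        assert sum(truth.masses_mg.values()) == pytest.approx(5.61 + 5.96 + 12.59, rel=1e-9)
        for k, dep in enumerate(deposits, start=1):
            # bookkeeping invariant: voxel-sum mass equals the recorded mass
            assert truth.mass_of(k) == pytest.approx(truth.masses_mg[k], rel=1e-12)
            assert truth.masses_mg[k] == pytest.approx(dep.mass_mg, rel=1e-9)

    def test_noiseless_voxel_sum_recovers_analytic_mass(self):
        """With sigma=0 the rasterized voxel-sum mass matches the requested
        deposit mass to well under 0.1% (concentration renormalization)."""
        dep = hq.Deposit(10.0, (0.0, 0.0, 0.0), 0.50)
        spec = hq.AcquisitionSpec(phantom_diameter="animal", **COARSE)
        pair, truth = hq.make_animal_phantom([dep], spec, seed=0, noise=hq.NO_NOISE)
        vv = truth.voxel_volume_ml
        got = truth.concentration[truth.deposit_labels == 1].sum() * vv
        assert got == pytest.approx(10.0, rel=1e-3 * 0.1)

    def test_empty_deposit_list_gives_empty_mass_map(self):
        spec = hq.AcquisitionSpec(phantom_diameter="animal", **COARSE)
        _, truth = hq.make_animal_phantom([], spec, seed=0)
        assert truth.masses_mg == {}

    def test_deposit_outside_body_is_geometry_error(self):
        spec = hq.AcquisitionSpec(phantom_diameter="animal", **COARSE)
        with pytest.raises(GeometryError):
            hq.make_animal_phantom([hq.Deposit(5.0, (0.0, 0.0, 120.0), 0.4)], spec, seed=0)

    def test_elliptical_outline_water_equivalent_diameter(self):
        spec = hq.AcquisitionSpec(phantom_diameter="animal", **COARSE)
        _, truth = hq.make_animal_phantom([], spec, seed=0)
        wed = truth.layout.water_equivalent_diameter_cm
        assert 15.0 <= wed <= 20.0  # rabbit-cadaver range
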