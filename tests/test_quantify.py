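"""Tolerance term, SNR, dilution fits, relative deviation and mass recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hoquant as hq
from hoquant.errors import (
    DomainError,
    PairingError,
    RankError,
    SegmentationError,
    UndefinedSNRError,
)

from conftest import COARSE


class TestTolerance:
    def test_zero_concentration_value(self):
        assert hq.tolerance(0.0) == 0.5

    def test_matches_independent_arithmetic_on_grid(self):
        for c in np.linspace(0.0, 12.0, 20):
            assert hq.tolerance(float(c)) == pytest.approx(
                math.sqrt(0.5**2 + (0.1 * c) ** 2), abs=1e-12
            )

    @given(st.floats(min_value=0.0, max_value=1e3, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_quadrature_form_and_lower_bound(self, c):
        t = hq.tolerance(c)
        assert t >= 0.5
        assert t**2 == pytest.approx(0.25 + (0.1 * c) ** 2, rel=1e-12)

    def test_strictly_increasing(self):
        assert hq.tolerance(1.0) < hq.tolerance(2.0) < hq.tolerance(10.0)
        assert hq.tolerance(10.0) == pytest.approx(1.1180, abs=5e-5)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            hq.tolerance(-0.1)


class TestRelativeDeviation:
    @pytest.mark.parametrize(
        "detected,injected,expected",
        [(12.8, 12.59, 1.7), (5.5, 5.96, -7.7), (7.0, 7.0, 0.0)],
    )
    def test_worked_examples_one_decimal(self, detected, injected, expected):
        assert round(hq.relative_deviation(detected, injected), 1) == expected

    def test_nonpositive_injected_rejected(self):
        with pytest.raises(DomainError):
            hq.relative_deviation(1.0, 0.0)


class TestSnr:
    def test_mean_over_sd(self):
        rng = np.random.default_rng(0)
        vol = 65.4 + rng.standard_normal((40, 40, 40))
        mask = np.ones(vol.shape, bool)
        assert hq.snr(vol, mask) == pytest.approx(65.4, rel=0.02)

    def test_zero_mean_region_gives_zero(self):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal((20, 20, 20))
        assert abs(hq.snr(vol, np.ones(vol.shape, bool))) < 0.05

    def test_noiseless_region_is_undefined(self):
        vol = np.full((10, 10, 10), 5.0)
        with pytest.raises(UndefinedSNRError):
            hq.snr(vol, np.ones(vol.shape, bool))

    def test_snr_dose_scaling(self):
        """SNR(high)/SNR(clinical) tracks sqrt(mAs_high/mAs_clinical) for the
        same insert, averaged over seeds."""
        spec_kw = dict(voltage_pair="80/150Sn", phantom_diameter=20.0, **COARSE)
        ratios = []
        for seed in range(8):
            snrs = {}
            for dose in ("clinical", "high"):
                spec = hq.AcquisitionSpec(dose_mode=dose, **spec_kw)
                pair, truth = hq.make_dilution_phantom([10.0], spec, seed=seed)
                ins = truth.layout.inserts[0]
                roi = hq.RoiSpec("cylinder", ins.center, radius=ins.size[0])
                mask = hq.core.roi_mask(roi, pair.shape, pair.spacing)
                snrs[dose] = hq.snr(pair.low, mask)
            ratios.append(snrs["high"] / snrs["clinical"])
        mas_c = hq.AcquisitionSpec(dose_mode="clinical", **spec_kw).resolve_tube_current()
        mas_h = hq.AcquisitionSpec(dose_mode="high", **spec_kw).resolve_tube_current()
        assert np.mean(ratios) == pytest.approx(np.sqrt(mas_h[0] / mas_c[0]), rel=0.10)


class TestLinearFit:
    def test_identity_data(self):
        fit = hq.linear_fit([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert (fit.m, fit.b, fit.r_squared, fit.rmse) == (1.0, 0.0, 1.0, 0.0)

    def test_exact_affine_data_recovers_parameters(self):
        known = np.array([0.125, 0.5, 2.0, 6.0, 10.0])
        measured = 1.01 * known - 0.16
        fit = hq.linear_fit(known, measured)
        assert fit.m == pytest.approx(1.01, abs=1e-12)
        assert fit.b == pytest.approx(-0.16, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_abscissa_is_rank_error(self):
        with pytest.raises(RankError):
            hq.linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_rmse_is_about_the_fitted_line_not_identity(self):
        # data on an exact non-identity line: RMSE 0 despite large offset
        known = [1.0, 2.0, 3.0]
        measured = [11.0, 12.0, 13.0]
        fit = hq.linear_fit(known, measured)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.b == pytest.approx(10.0)


class TestEvaluateDilution:
    def test_noiseless_series_is_exact(self, small_table):
        spec = hq.AcquisitionSpec(phantom_diameter=20.0, **COARSE)
        pair, truth = hq.make_dilution_phantom(
            [0.5, 2.0, 8.0], spec, seed=0, noise=hq.NO_NOISE
        )
        v = hq.lookup_vector(small_table, "80/150Sn", 20.0)
        cmap, _ = hq.decompose_image(pair, hq.MaterialBasis(holmium=v))
        result, fit = hq.evaluate_dilution(cmap, truth)
        assert result.all_within_tolerance
        assert fit.m == pytest.approx(1.0, abs=1e-9)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_roi_truth_mismatch_is_pairing_error(self, small_table):
        spec = hq.AcquisitionSpec(phantom_diameter=20.0, **COARSE)
        pair, truth = hq.make_dilution_phantom([1.0, 2.0], spec, seed=0)
        v = hq.lookup_vector(small_table, "80/150Sn", 20.0)
        cmap, _ = hq.decompose_image(pair, hq.MaterialBasis(holmium=v))
        one_roi = [hq.RoiSpec("cylinder", truth.layout.inserts[0].center, radius=7.5)]
        with pytest.raises(PairingError):
            hq.evaluate_dilution(cmap, truth, one_roi)

    def test_miscalibrated_vector_scales_slope_inversely(self, small_table):
        """A vector overestimated by x1.2 makes recovered concentrations (and
        the fitted slope) smaller by 1/1.2."""
        spec = hq.AcquisitionSpec(phantom_diameter=20.0, **COARSE)
        pair, truth = hq.make_dilution_phantom(
            [2.0, 4.0, 8.0], spec, seed=0, noise=hq.NO_NOISE
        )
        v = hq.lookup_vector(small_table, "80/150Sn", 20.0)
        bad = hq.EnhancementVector(
            "holmium", 1.2 * v.e_low, 1.2 * v.e_high, v.voltage_pair, v.diameter_cm
        )
        cmap, _ = hq.decompose_image(pair, hq.MaterialBasis(holmium=bad))
        _, fit = hq.evaluate_dilution(cmap, truth)
        assert fit.m == pytest.approx(1.0 / 1.2, abs=1e-9)


class TestMassRecovery:
    def test_uniform_deposit_definition(self):
        conc = np.zeros((4, 10, 10))
        conc[:, 2:6, 2:6] = 10.0  # mg/mL
        mask = conc > 0
        spacing = (5.0, 2.5, 2.5)  # voxel volume 31.25 mm^3
        expected = 10.0 * mask.sum() * np.prod(spacing) / 1000.0
        assert hq.total_mass(conc, mask, spacing) == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_is_segmentation_error(self):
        conc = np.zeros((4, 4, 4))
        with pytest.raises(SegmentationError):
            hq.total_mass(conc, conc > 0, (1.0, 1.0, 1.0))

    def test_noiseless_animal_mass_recovery_within_rasterization(self, small_table):
        spec = hq.AcquisitionSpec(phantom_diameter="animal", **COARSE)
        deposits = [
            hq.Deposit(5.96, (0.0, -30.0, 55.0), 0.40),
            hq.Deposit(12.59, (0.0, 30.0, -55.0), 0.70),
        ]
        pair, truth = hq.make_animal_phantom(deposits, spec, seed=0, noise=hq.NO_NOISE)
        wed = truth.layout.water_equivalent_diameter_cm
        v = hq.lookup_vector(small_table, "80/150Sn", wed, allow_interpolation=True)
        cmap, _ = hq.decompose_image(pair, hq.MaterialBasis(holmium=v))
        result = hq.evaluate_mass(cmap, truth)
        for d in result.deposits:
            assert abs(d.relative_deviation_pct) < 1.0

    def test_mass_conservation_on_full_volume_mask(self, small_table):
        """Unthresholded whole-volume integral of a sigma=0 map equals the
        ground-truth total to < 1%."""
        spec = hq.AcquisitionSpec(phantom_diameter="animal", **COARSE)
        deposits = [hq.Deposit(10.0, (0.0, 0.0, 0.0), 0.50)]
        pair, truth = hq.make_animal_phantom(deposits, spec, seed=0, noise=hq.NO_NOISE)
        wed = truth.layout.water_equivalent_diameter_cm
        v = hq.lookup_vector(small_table, "80/150Sn", wed, allow_interpolation=True)
        cmap, _ = hq.decompose_image(pair, hq.MaterialBasis(holmium=v))
        full = np.ones(cmap.shape, bool)
        assert hq.total_mass(cmap, full) == pytest.approx(10.0, rel=0.01)

    def test_segmentation_threshold_excludes_clean_background(self, small_table):
        spec = hq.AcquisitionSpec(phantom_diameter="animal", dose_mode="high", **COARSE)
        deposits = [hq.Deposit(10.0, (0.0, 0.0, 0.0), 0.50)]
        pair, truth = hq.make_animal_phantom(deposits, spec, seed=4)
        wed = truth.layout.water_equivalent_diameter_cm
        v = hq.lookup_vector(small_table, "80/150Sn", wed, allow_interpolation=True)
        cmap, _ = hq.decompose_image(pair, hq.MaterialBasis(holmium=v))
        labels = hq.segment_deposits(cmap)
        # a single connected deposit, no percolating background components
        sizes = np.bincount(labels.ravel())[1:]
        assert (sizes > 10).sum() == 1
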