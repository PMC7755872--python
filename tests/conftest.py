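"""Shared fixtures: coarse, fast phantom grids for unit tests.

Unit tests run at a reduced grid (3 x 1 x 1 mm voxels, 6 slices) so the whole
suite stays desk-scale; acceptance tests use the package defaults.
"""

import pytest

import hoquant as hq

COARSE = dict(voxel_spacing=(3.0, 1.0, 1.0), slice_count=6)


@pytest.fixture(scope="session")
def coarse_cal_spec():
    return hq.AcquisitionSpec(voltage_pair="80/150Sn", phantom_diameter=10.0, **COARSE)


@pytest.fixture(scope="session")
def noiseless_calibration(coarse_cal_spec):
    """sigma = 0 calibration phantom (pair, truth) at the coarse grid."""
    return hq.make_calibration_phantom(coarse_cal_spec, seed=7, noise=hq.NO_NOISE)


@pytest.fixture(scope="session")
def noisy_calibration(coarse_cal_spec):
    return hq.make_calibration_phantom(coarse_cal_spec, seed=7)


@pytest.fixture(scope="session")
def true_vector_80_150sn_10cm():
    return hq.enhancement_model("80/150Sn", 10.0)


@pytest.fixture(scope="session")
def small_table():
    """Noiseless calibration table over one voltage pair, three sizes."""
    cfg = hq.PipelineConfig(
        experiment="calibration",
        voltage_pairs=("80/150Sn",),
        diameters_cm=(10.0, 15.0, 20.0),
        slice_count=COARSE["slice_count"],
        voxel_spacing=COARSE["voxel_spacing"],
    )
    return hq.calibrate_grid(cfg)
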