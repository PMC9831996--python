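import numpy as np
import pytest

from octforce import simkit as sk


@pytest.fixture(scope="session")
def small_swei_geometry() -> sk.ScanGeometry:
    """Reduced-depth SWEI geometry (same axial/lateral pitch as full scale)."""
    return sk.ScanGeometry.default_swei(depth_px=48, depth_extent_mm=0.353)


@pytest.fixture(scope="session")
def gel10() -> sk.MaterialSpec:
    return sk.make_material("gelatin", concentration=0.10)


@pytest.fixture(scope="session")
def desk_geometry() -> sk.ScanGeometry:
    return sk.ScanGeometry(depth_px=256, lateral_w_px=16, lateral_d_px=16,
                           depth_extent_mm=4.0, lateral_extent_w_mm=3.0,
                           lateral_extent_d_mm=3.0, bscan_rate_hz=14200.0,
                           volume_rate_hz=2.0)


@pytest.fixture(scope="session")
def palpation_record(gel10, desk_geometry) -> sk.PalpationRecord:
    traj = sk.sinusoidal_trajectory(seed=3)
    geom = sk.ScanGeometry(**{**desk_geometry.__dict__,
                              "volume_rate_hz": 10 / traj.duration_s})
    return sk.simulate_palpation(gel10, geom, traj, seed=11,
                                 sample_id="S1", location_id="L1")
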