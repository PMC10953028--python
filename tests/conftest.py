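import numpy as np
import pytest

import wavetof as wt


@pytest.fixture(scope="session")
def protocol_params():
    """The wave-TOF protocol: 10 mT/m, 15 cycles, 121 Hz/px, 256 samples."""
    return wt.WaveParams(g_max=10.0, n_cyc=15, bw_per_pixel=121.0, n_read=256)


@pytest.fixture(scope="session")
def desk_wave():
    """Protocol wave parameters on the desk-scale 64-sample readout."""
    return wt.WaveParams(g_max=10.0, n_cyc=15, bw_per_pixel=121.0, n_read=64)


@pytest.fixture(scope="session")
def small_phantom():
    """32x32x16 vessel phantom shared by cheaper integration tests."""
    return wt.make_vessel_phantom(wt.PhantomSpec(dims=(32, 32, 16)))


@pytest.fixture(scope="session")
def small_coils(small_phantom):
    spec = small_phantom.spec
    return wt.make_coil_maps(4, spec.dims, small_phantom.support, seed=0)


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64x64x16 study phantom."""
    return wt.make_vessel_phantom(wt.PhantomSpec())


@pytest.fixture(scope="session")
def default_coils(default_phantom):
    spec = default_phantom.spec
    return wt.make_coil_maps(spec.n_coils, spec.dims, default_phantom.support, seed=0)


@pytest.fixture(scope="session")
def tiny_wave_op():
    """8x8x4 wave operator with 2 coils, for oracle-level checks."""
    rng = np.random.default_rng(7)
    dims = (8, 8, 4)
    support = np.ones(dims, bool)
    coils = wt.make_coil_maps(2, dims, support, seed=1)
    params = wt.WaveParams(g_max=10.0, n_cyc=3, bw_per_pixel=121.0, n_read=8, os_factor=3)
    fov = (200.0, 200.0, 26.4)
    traj = wt.nominal_trajectory(params, fov[0])
    op = wt.wave_operator(coils, traj, fov, params.os_factor)
    return {"op": op, "traj": traj, "params": params, "fov": fov, "rng": rng}


def nrmse(a, b, region=None):
    a, b = np.asarray(a), np.asarray(b)
    if region is not None:
        a, b = a[region], b[region]
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
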