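import numpy as np
import pytest

from ptychokit import Geometry, ScanSpec, SimConfig, build_pods, run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def geom_far():
    """Visible-light far-field geometry (binned CCD, 145 mm downstream)."""
    return Geometry(lam=650e-9, z=0.145, dpsize=72e-6, N=(32, 32))


@pytest.fixture
def geom_near():
    return Geometry(lam=650e-9, z=1e-3, dpsize=1e-6, N=(32, 32), regime="nearfield")


def small_scan(grid=(3, 3), N=(32, 32), seed=3, **sim_kwargs):
    """Simulated scan with physically sensible sampling: the probe spans
    ~N/4 real-space pixels and adjacent illuminations overlap by 60%."""
    geom = Geometry(lam=650e-9, z=0.145, dpsize=72e-6, N=N)
    diameter = (N[0] // 4) * geom.rpsize[0]
    defaults = dict(
        grid=grid,
        step=0.4 * diameter,
        jitter=0.1,
        probe_diameter=diameter,
        photons=1e4,
        seed=seed,
    )
    defaults.update(sim_kwargs)
    config = SimConfig(geometry=geom, **defaults)
    frames, truth = run_simulation(config)
    return config, frames, truth


def network_at_truth(frames, truth, geometry, n_probe_modes=None):
    """Pod network with probe/object/exit set to the simulated ground truth."""
    nmodes = truth["probe"].shape[0] if n_probe_modes is None else n_probe_modes
    spec = ScanSpec(
        positions=truth["positions"], geometry=geometry, n_probe_modes=nmodes
    )
    network = build_pods(spec, frames)
    network.containers["probe"].storages["p0"].data[...] = truth["probe"]
    network.containers["object"].storages["o0"].data[...] = truth["object"]
    for pod in network.pods:
        pod.exit = pod.probe * pod.object
    return network
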