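import numpy as np
import pytest

from tofrecon import ksim, phantom_io


@pytest.fixture(scope="session")
def default_phantom() -> phantom_io.MagnitudeVolume:
    """The 64x64x24 default phantom (thin-slab geometry)."""
    return phantom_io.generate_tof_phantom(phantom_io.PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def small_phantom() -> phantom_io.MagnitudeVolume:
    return phantom_io.generate_tof_phantom(
        phantom_io.PhantomConfig(shape=(32, 32, 16), n_vessels=4, seed=7)
    )


@pytest.fixture(scope="session")
def small_acq(small_phantom) -> ksim.SimulatedAcquisition:
    """Fully sampled 4-coil simulated acquisition of the small phantom."""
    return ksim.simulate_acquisition(
        small_phantom,
        R=1.0,
        pf_fraction=0.0,
        calib=(8, 4),
        seed=11,
        coil_cfg=ksim.CoilSimConfig(n_coils=4, seed=13),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_payload_pair(tmp_path_factory):
    """Two independent runs of the toy end-to-end demo with the same seed,
    shared across CLI and acceptance tests (it is the expensive fixture)."""
    from tofrecon.cli import run_demo

    out1 = tmp_path_factory.mktemp("demo1")
    out2 = tmp_path_factory.mktemp("demo2")
    p1 = run_demo(7, out1)
    p2 = run_demo(7, out2)
    return (p1, out1), (p2, out2)
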