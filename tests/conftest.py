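import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import flimphasor as fp

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

F_MOD = 8.0e7


@pytest.fixture(scope="session")
def two_fluor():
    """256x256 two-fluorophore (1 ns / 3 ns) scene with clean phases."""
    spec = fp.two_fluorophore_spec()
    scene = fp.generate_scene(spec, seed=0)
    phases = fp.simulate_fd_phases(scene, F_MOD)
    return scene, phases


@pytest.fixture(scope="session")
def tiny_cnn():
    """A small CNN trained quickly on a 96x96 scene (unit-test scale)."""
    spec = fp.two_fluorophore_spec(shape=(96, 96), n_disks=4)
    return fp.train_cnn_on_scene(
        spec, depth=4, width=8, epochs=10, n_patches=96, patch_size=24, seed=7
    )


@pytest.fixture(scope="session")
def trained_cnn():
    """The default-sized CNN trained on a BPAE-like scene (held out from
    the two-fluorophore evaluation scene)."""
    return fp.train_cnn_on_scene(fp.bpae_like_spec(), seed=123)


def reference_lifetime(scene):
    return fp.LifetimeImage(
        tau_ns=np.where(scene.label > 0, scene.tau_ns, np.nan),
        valid=scene.label > 0,
    )
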