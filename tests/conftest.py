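import numpy as np
import pytest

from skullray import CTVolume, ShellPhantomSpec, make_shell_phantom


@pytest.fixture(scope="session")
def shell96():
    """Default noise-free shell phantom on a 96^3 grid at 2 mm pitch."""
    return make_shell_phantom(ShellPhantomSpec(), shape=(96, 96, 96), spacing=2.0, seed=1)


@pytest.fixture(scope="session")
def shell160():
    """Noise-free shell phantom at 1 mm pitch (sub-voxel geometry checks)."""
    return make_shell_phantom(ShellPhantomSpec(), shape=(160, 160, 160), spacing=1.0, seed=1)


@pytest.fixture()
def water_vol():
    """Uniform water-only volume, 32^3 at 2 mm."""
    return CTVolume(np.zeros((32, 32, 32)), spacing=(2.0, 2.0, 2.0), origin=(-31.0, -31.0, -31.0))
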