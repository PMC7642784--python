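import numpy as np
import pytest

import cryodenoise as cd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def phantom():
    """A deterministic 128² disc phantom at 1 Å/px."""
    return cd.generate_phantom(cd.PhantomSpec(size=128, seed=7))


@pytest.fixture
def noisy_micrograph(rng):
    """Pure white-noise micrograph (no signal), 128² at 1 Å/px."""
    return cd.Micrograph(rng.normal(size=(128, 128)), 1.0, name="noise")


@pytest.fixture
def ctf_params():
    return cd.CtfParams(defocus_u=12000.0, defocus_v=11000.0, astig_angle=0.4)


def random_ctf_params(rng) -> cd.CtfParams:
    return cd.CtfParams(
        defocus_u=float(rng.uniform(3000, 30000)),
        defocus_v=float(rng.uniform(3000, 30000)),
        astig_angle=float(rng.uniform(0, np.pi)),
        voltage=float(rng.choice([200.0, 300.0])),
        cs=float(rng.uniform(0.0, 2.7)),
        amplitude_contrast=float(rng.uniform(0.0, 0.15)),
        phase_shift=float(rng.choice([0.0, np.pi / 2])),
    )
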