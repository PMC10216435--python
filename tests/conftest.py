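import numpy as np
import pytest

from unmixlabel.hypercube import CalibrationFrames, Hypercube
from unmixlabel.phantom import (
    PhantomConfig,
    _PhantomEndmembers,
    make_scene,
    pure_reference_marks,
)
from unmixlabel.unmixing import EndmemberSet


@pytest.fixture(scope="session")
def endmember_set() -> EndmemberSet:
    """A seeded 4 x 528 phantom endmember set in SNV units."""
    from unmixlabel.phantom import make_endmembers

    return make_endmembers(seed=12345)


@pytest.fixture(scope="session")
def small_endmembers() -> EndmemberSet:
    """Tiny, hand-checkable 3-endmember set on a 12-band grid."""
    rng = np.random.default_rng(7)
    spectra = rng.normal(size=(3, 12))
    return EndmemberSet(spectra, ("IC", "CIS", "fat"), np.arange(12, dtype=float))


@pytest.fixture(scope="session")
def noiseless_config() -> PhantomConfig:
    return PhantomConfig(noise_sd=0.0, spectral_variability=0.0)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return make_scene(noiseless_config, seed=42)


@pytest.fixture(scope="session")
def reference_scene(noiseless_config):
    """Noiseless scene holding one pure 10x10 region per tissue class."""
    pe = _PhantomEndmembers.generate(np.random.SeedSequence(42).spawn(1)[0],
                                     noiseless_config)
    return make_scene(noiseless_config, seed=42, endmembers=pe,
                      marks=pure_reference_marks())


def toy_cube(rows=6, cols=5, bands=8, camera="VIS", seed=0, pitch=0.5) -> Hypercube:
    rng = np.random.default_rng(seed)
    wl = 400.0 + 3.0 * np.arange(bands)
    return Hypercube(rng.uniform(0.1, 0.9, (rows, cols, bands)), wl, camera, pitch)


def toy_refs(shape) -> CalibrationFrames:
    white = np.full(shape, 0.9)
    dark = np.full(shape, 0.1)
    return CalibrationFrames(white, dark)
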