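import numpy as np
import pytest

from flybait import (DEFAULT_GRID, PanelSpec, ReceptorSet, Spectrum, adapt,
                     generate_panel)
from flybait import fixtures
from flybait.receptors import RECEPTOR_CLASSES


def flat_spectrum(value: float, role="reflectance", grid=DEFAULT_GRID, name=""):
    return Spectrum(grid=grid, values=np.full(grid.n_points, float(value)),
                    role=role, name=name)


@pytest.fixture(scope="session")
def illuminant():
    return fixtures.load_illuminant()


@pytest.fixture(scope="session")
def background():
    return fixtures.load_background()


@pytest.fixture(scope="session")
def receptors():
    return fixtures.load_receptors()


@pytest.fixture(scope="session")
def state(background, illuminant, receptors):
    return adapt(background, illuminant, receptors)


@pytest.fixture(scope="session")
def flat_receptors():
    """Five flat unit sensitivities: every class sees every wavelength equally."""
    sens = {c: flat_spectrum(1.0, role="sensitivity", name=c) for c in RECEPTOR_CLASSES}
    return ReceptorSet(sensitivities=sens)


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(PanelSpec(n_baits=12, seed=42))
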