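import numpy as np
import pytest

from iminokinetics.synthetic import (
    DEFAULT_MIXING_TIMES,
    DEFAULT_NU1_GRID,
    GroundTruthSite,
    StudyDesign,
)
from iminokinetics.types import DuplexSite, ModificationState


@pytest.fixture
def g_site() -> DuplexSite:
    return DuplexSite("C/C", 7, "G", ModificationState.C)


@pytest.fixture
def t_site() -> DuplexSite:
    return DuplexSite("C/C", 4, "T", None)


@pytest.fixture
def truth(g_site) -> GroundTruthSite:
    """A representative imino site in the fast-exchange regime."""
    return GroundTruthSite(
        site=g_site, k1h_true=2.0, ra_true=25.0, rb_true=0.6,
        r20_true=30.0, kex_true=2.0e4, pb_true=0.005,
        dw_true=2.0 * np.pi * 1200.0, noise_sigma=0.002,
    )


@pytest.fixture
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture
def mixing_times() -> np.ndarray:
    return DEFAULT_MIXING_TIMES.copy()


@pytest.fixture
def nu1_grid() -> np.ndarray:
    return DEFAULT_NU1_GRID.copy()
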