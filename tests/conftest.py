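import numpy as np
import pytest

from petrt.synthstudy import StudyDesign, true_input_function

SMALL_REGIONS = ("Cerebellum", "Medial Temporal Lobe", "Occipital Cortex")


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign(n_subjects=2, seed=1)


@pytest.fixture(scope="session")
def frames(default_design):
    return np.asarray(default_design.frame_schedule)


@pytest.fixture(scope="session")
def true_input(default_design):
    """Noiseless parent-plasma curve of the default design."""
    return true_input_function(default_design)


@pytest.fixture
def small_design():
    """Three regions, two subjects: cheap enough for per-test pipelines."""
    return StudyDesign(n_subjects=2, region_names=SMALL_REGIONS, seed=7)
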