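import numpy as np
import pytest

from hygrostab import (GAB_PUBLISHED, GT_PUBLISHED, StudyConfig, gen_study,
                       run_study)


@pytest.fixture(scope="session")
def gab_params():
    return GAB_PUBLISHED


@pytest.fixture(scope="session")
def gt_params():
    return GT_PUBLISHED


@pytest.fixture(scope="session")
def aw_grid():
    """The instrument's adsorption grid: a_w 0.1 to 0.9 in 0.1 steps."""
    return np.round(np.arange(0.1, 0.91, 0.1), 10)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A full synthetic study dataset (seed 1) shared across tests."""
    out = tmp_path_factory.mktemp("study")
    cfg = StudyConfig(seed=1)
    gen_study(cfg, out)
    return cfg, out


@pytest.fixture(scope="session")
def study_report(study_dir):
    cfg, out = study_dir
    return cfg, run_study(cfg, out)
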