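import numpy as np
import pytest

from brainmosaic.synthetic_study import StudyConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A reduced cohort (fast): fewer brains/regions, higher rate so that a
    handful of developmental clones is planted deterministically."""
    config = StudyConfig(
        n_control=3, n_ad=3, n_lb=3,
        region_design={"CB": 9, "EC": 8, "FC": 5, "Med": 4, "Cin": 2},
        n_blood_paired=2,
        rate=6e-9,
        n_background_sites=15,
        n_germline_per_individual=2,
        seed=42,
    )
    reads, truth = generate_study(config)
    return config, reads, truth


@pytest.fixture(scope="session")
def default_study():
    """One full-size cohort at the default design constants."""
    config = StudyConfig(seed=7)
    reads, truth = generate_study(config)
    return config, reads, truth
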