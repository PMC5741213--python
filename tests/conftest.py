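import numpy as np
import pytest

from sfscene.expdesign import make_schedule
from sfscene.preproc_glm import extract_subject_patterns, percent_signal_change
from sfscene.synthbold import SyntheticConfig, make_box_roi, simulate_subject


@pytest.fixture(scope="session")
def schedules8():
    """Default 8-run block schedule, seeded."""
    return make_schedule(seed=7)


@pytest.fixture(scope="session")
def small_roi():
    return make_box_roi("PPA", (0, 0, 0), (4, 5, 3))  # 60 voxels


@pytest.fixture(scope="session")
def simulated_subject(schedules8, small_roi):
    """One synthetic subject with clearly decodable signal."""
    config = SyntheticConfig(
        n_voxels=60, effect_size=1.0, freq_effect=1.0, seed=11
    )
    runs, truth = simulate_subject(config, [small_roi], schedules8, subject_id="sub-01")
    return runs, truth


@pytest.fixture(scope="session")
def subject_patterns(simulated_subject):
    runs, _ = simulated_subject
    runs = [percent_signal_change(r) for r in runs]
    return extract_subject_patterns(runs)


@pytest.fixture(scope="session")
def null_patterns(schedules8, small_roi):
    """Patterns from a subject with zero embedded effect (pure noise)."""
    config = SyntheticConfig(
        n_voxels=60, effect_size=0.0, freq_effect=0.0, seed=23
    )
    runs, _ = simulate_subject(config, [small_roi], schedules8, subject_id="sub-99")
    runs = [percent_signal_change(r) for r in runs]
    return extract_subject_patterns(runs)
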