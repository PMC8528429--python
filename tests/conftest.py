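import warnings

import numpy as np
import pytest

import cycleomics as co

# statsmodels RLM emits convergence chatter on degenerate genes; irrelevant here
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_cohort():
    """Modest two-group cohort with rhythmic truth, control arm only."""
    cfg = co.SimConfig(
        n_genes=300,
        frac_rhythmic=0.5,
        treatments=("control",),
        seed=123,
    )
    tc, truth = co.simulate_timecourse(cfg)
    return tc, truth, cfg


@pytest.fixture(scope="session")
def eight_phase_design():
    """7 subjects observed at 8 distinct phases (no folding)."""
    times = np.tile(np.arange(8) * 6.0, 7)
    subjects = np.repeat([f"s{i}" for i in range(7)], 8)
    return times, subjects, 48.0
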