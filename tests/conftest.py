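import numpy as np
import pytest

import tracekin as tk


@pytest.fixture
def noiseless_labeling():
    return tk.LabelingModel(
        log10_initial_sd=0.0, inheritance_sd=0.0, instrument_cv_log10=0.0
    )


@pytest.fixture
def noisy_labeling():
    return tk.LabelingModel(
        log10_initial_sd=0.06, inheritance_sd=0.0, instrument_cv_log10=0.0
    )


@pytest.fixture
def three_gen_cohort(noiseless_labeling):
    profile = tk.DivisionProfile([0.5, 0.3, 0.2])
    return tk.simulate_cohort(profile, 10_000, noiseless_labeling, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def event_frequencies(table, n_generations):
    """True per-generation event percentages from simulator labels."""
    tg = table.true_generation
    return np.array([100.0 * np.mean(tg == g) for g in range(1, n_generations + 1)])
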