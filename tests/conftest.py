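import numpy as np
import pytest

import rtbold as rb


@pytest.fixture(scope="session")
def default_spec():
    return rb.ScheduleSpec()


@pytest.fixture(scope="session")
def small_spec():
    # two runs keep per-test fits fast while exercising run structure
    return rb.ScheduleSpec(n_runs=2)


@pytest.fixture(scope="session")
def rt_model():
    return rb.RTModel()


@pytest.fixture(scope="session")
def participant(small_spec, rt_model):
    """One simulated participant: (table, series, filter result)."""
    table, series = rb.simulate_participant(
        small_spec, rt_model, rb.BoldTruth(), seed=42
    )
    filt = rb.filter_trials(table)
    return table, series, filt


@pytest.fixture(scope="session")
def fitted(participant, small_spec):
    table, series, filt = participant
    design = rb.build_design(
        table, filt, tr=small_spec.tr,
        n_volumes_per_run=small_spec.n_volumes_per_run,
    )
    fit = rb.FirstLevelModel(series, design).fit()
    return table, series, filt, design, fit


def retained_rt_lists(table, filt):
    rt = dict(zip(table["trial_id"], table["response_time"]))
    cong = [(t, rt[t]) for t in filt.retained["correct_congruent"]]
    incong = [(t, rt[t]) for t in filt.retained["correct_incongruent"]]
    return cong, incong


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
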