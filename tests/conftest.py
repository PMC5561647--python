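import numpy as np
import pandas as pd
import pytest

from flxsig import behavior as bhv
from flxsig import synthetic as syn


def make_records(rows):
    """Build a behavioral table from (animal_id, group, session, epm_t, epm_e, nsf, food, st)."""
    cols = [
        "animal_id",
        "group",
        "session",
        "epm_open_time_s",
        "epm_open_entries",
        "nsf_latency_s",
        "nsf_food_mg_per_g",
        "st_grooming_s",
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def default_cohort():
    return syn.simulate_behavior(syn.BehavioralSimConfig(seed=11))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    z = bhv.zscore_measures(default_cohort)
    return bhv.emotionality(z)


@pytest.fixture(scope="session")
def small_proteome():
    cfg = syn.ProteomeSimConfig(n_proteins=120, seed=21)
    psms, truth = syn.simulate_psms(cfg)
    design = syn.sample_design(cfg).set_index("sample_id")["group"]
    return cfg, psms, truth, design


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
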