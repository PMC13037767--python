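import numpy as np
import pandas as pd
import pytest

from wearmiss import GeneratorConfig, generate
from wearmiss.data_model import make_dataset


def tiny_frames(patterns, hr=None):
    """Build night/covariate frames from per-participant 0/1 missingness tuples."""
    stage_vals = {"deep_s": 4000.0, "light_s": 13000.0, "rem_s": 5500.0,
                  "awake_s": 1500.0, "unmeasurable_s": 0.0}
    rows = []
    for i, pat in enumerate(patterns):
        for t, miss in enumerate(pat, start=1):
            rec = {"participant_id": f"S{i:03d}", "night_index": t,
                   "hr_present_prior_day": 1 if hr is None else hr[i][t - 1]}
            for k, v in stage_vals.items():
                rec[k] = np.nan if miss else v + 10 * i + t
            rows.append(rec)
    cov = pd.DataFrame({
        "participant_id": [f"S{i:03d}" for i in range(len(patterns))],
        "household_size": [1 + i % 4 for i in range(len(patterns))],
        "education_level": [1 + i % 3 for i in range(len(patterns))],
        "employed": [i % 2 for i in range(len(patterns))],
        "married": [(i // 2) % 2 for i in range(len(patterns))],
        "n_children": [i % 3 for i in range(len(patterns))],
        "site": [["A", "B", "C"][i % 3] for i in range(len(patterns))],
    })
    return pd.DataFrame(rows), cov


def tiny_dataset(patterns, hr=None):
    nights, cov = tiny_frames(patterns, hr=hr)
    return make_dataset(nights, cov)


@pytest.fixture(scope="session")
def mar_dataset():
    """A default-configuration MAR cohort (299 participants, 5 nights)."""
    return generate(GeneratorConfig(mechanism="MAR", seed=20260921))


@pytest.fixture(scope="session")
def mcar_dataset():
    return generate(GeneratorConfig(mechanism="MCAR", seed=20260922))


@pytest.fixture(scope="session")
def small_mar_dataset():
    return generate(GeneratorConfig(mechanism="MAR", n_participants=60, seed=7))
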