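import numpy as np
import pandas as pd
import pytest

import microperm as mp
from microperm.io_config import RunConfig, RunReport
from microperm.pipeline import prepare


@pytest.fixture(scope="session")
def pmu_cohort():
    """One default-scenario synthetic cohort with its ground truth."""
    scenario = mp.scenario_presets("pmu-like", seed=7)
    counts, design, truth = mp.simulate_cohort(scenario)
    return counts, design, truth


@pytest.fixture(scope="session")
def prepared(pmu_cohort):
    """Filtered counts, rarefied set and a small CLR stack for the cohort."""
    counts, design, _ = pmu_cohort
    config = RunConfig(n_instances=2, rng_seed=7)
    retained, rare, clr = prepare(counts, config, RunReport())
    return retained, rare, clr, design.loc[list(rare.sample_ids)]


@pytest.fixture
def toy_counts():
    """3 samples × 4 features with distinct compositions."""
    return mp.CountTable(
        ("s1", "s2", "s3"),
        ("fA", "fB", "fC", "fD"),
        np.array([[10, 5, 3, 2], [2, 8, 6, 4], [7, 7, 7, 7]]),
    )


@pytest.fixture
def toy_design():
    rows = []
    for subj in ("F01", "F02", "F03"):
        for i, tp in enumerate(("P2", "P3", "P4", "P5")):
            rows.append(
                {
                    "sample_id": f"{subj}_{tp}",
                    "subject_id": subj,
                    "time_point": tp,
                    "delivery_mode": "C" if subj == "F01" else "V",
                    "breastfeeding_weeks": 20.0,
                    "zonulin": 100.0 + 10 * i,
                    "calprotectin": 300.0 - 20 * i,
                }
            )
    df = pd.DataFrame(rows)
    from microperm.io_config import validate_cohort

    return validate_cohort(df, ["P2", "P3", "P4", "P5"])
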