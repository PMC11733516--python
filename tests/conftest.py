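import numpy as np
import pandas as pd
import pytest

from qcla import (
    CleaningConfig,
    HashingBowEncoder,
    PlantedCounts,
    SimulationSpec,
    generate_cohort,
    run_pipeline,
)


@pytest.fixture(scope="session")
def fixture_cohort_522():
    """522-record cohort with 20 time failures, 33 irrelevance flags and
    52 word-minimum failures planted disjointly."""
    spec = SimulationSpec(
        n_respondents=522,
        planted=PlantedCounts(time_fail=20, irrelevant=33, wordmin_fail=52),
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Clean 120-respondent dataset for encoding/prediction tests."""
    raw, _ = generate_cohort(SimulationSpec(n_respondents=120, seed=7))
    dataset, ledger = run_pipeline(raw, CleaningConfig())
    assert ledger.final_n == 120
    return dataset


@pytest.fixture(scope="session")
def tiny_encoder():
    return HashingBowEncoder(dim=32, seed=0)


def make_text_dataset(rows: list[tuple[str, list[int]]]) -> pd.DataFrame:
    """Minimal clean-dataset frame: one question, explicit items."""
    return pd.DataFrame(
        [
            {
                "id": f"R{i}",
                "q1": text,
                **{f"gdt_{k+1}": items[k] for k in range(4)},
            }
            for i, (text, items) in enumerate(rows)
        ]
    )
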