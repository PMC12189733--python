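import numpy as np
import pandas as pd
import pytest

from effbias import (
    CohortSpec,
    FeatureTable,
    RunConfig,
    generate_cohort,
    generate_knowledge,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """One reference cohort at the study conditions, with knowledge base."""
    spec = CohortSpec(seed=11)
    table, truth = generate_cohort(spec)
    bundle = generate_knowledge(truth, seed=12)
    return table, truth, bundle


@pytest.fixture(scope="session")
def fast_config():
    """Run configuration with a reduced permutation count for tests."""
    return RunConfig(seed=7, n_perm=2000)


@pytest.fixture
def small_table():
    """Tiny hand-made feature table: 8 samples (2/group), 3 metabolites."""
    rng = np.random.default_rng(3)
    groups = ["control", "control", "challenge", "challenge",
              "treated", "treated", "drug_alone", "drug_alone"]
    sample_ids = [f"s{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.lognormal(mean=5, sigma=0.3, size=(8, 3)),
        index=sample_ids, columns=["M1", "M2", "M3"],
    )
    return FeatureTable(values=values, groups=pd.Series(groups, index=sample_ids, name="group"))
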