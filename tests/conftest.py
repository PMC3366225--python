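import numpy as np
import pandas as pd
import pytest

from zhengmine import cohort as cohort_mod
from zhengmine import network as network_mod


@pytest.fixture(scope="session")
def default_cohort() -> cohort_mod.Cohort:
    """One default-sized synthetic cohort shared across read-only tests."""
    return cohort_mod.generate_cohort(
        cohort_mod.GeneratorConfig(random_seed=7)
    )


@pytest.fixture(scope="session")
def default_network(default_cohort) -> network_mod.AssociationNetwork:
    return network_mod.build_association_network(
        default_cohort, network_mod.NetworkConfig(edge_budget=120)
    )


@pytest.fixture()
def tiny_cohort() -> cohort_mod.Cohort:
    """Four symptoms, no biomarkers — for small-graph network tests."""
    rng = np.random.default_rng(42)
    symptoms = pd.DataFrame(
        rng.integers(0, 2, size=(60, 4)), columns=list("abcd")
    )
    return cohort_mod.Cohort(
        patient_ids=[f"P{i}" for i in range(60)],
        symptoms=symptoms,
        biomarkers=pd.DataFrame(index=range(60)),
        labels=pd.DataFrame(index=range(60)),
    )
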