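import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import biomorph as bm

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_profiles():
    """3 rows × 4 features with known values."""
    df = pd.DataFrame(
        {
            "f_a": [1.0, 2.0, 3.0],
            "f_b": [0.0, 0.0, 0.0],
            "f_c": [-1.0, 1.0, 0.0],
            "f_d": [10.0, 20.0, 30.0],
        },
        index=["r1", "r2", "r3"],
    )
    return bm.MorphProfileTable(df)


@pytest.fixture(scope="session")
def default_panel():
    """One simulated CRISPR panel at the default study conditions."""
    scenario = bm.default_scenario(seed=11)
    profiles, readouts, meta = bm.generate_crispr_panel(scenario)
    return scenario, profiles, readouts, meta


@pytest.fixture(scope="session")
def default_screen():
    scenario = bm.default_scenario(seed=11)
    profiles, labels = bm.generate_compound_screen(scenario)
    return scenario, profiles, labels


def make_term(features, l3="vb_percent_dead", l4="Chromatin Modifiers",
              l1="viability", l2="cell_death"):
    return bm.BioMorphTerm(
        level1_assay=l1,
        level2_measurement=l2,
        level3_phenotype=l3,
        level4_process=l4,
        level5_features=frozenset(features),
        regression_gate=bm.GateResult("r_squared", 0.9, True, 0),
        classifier_gate=bm.GateResult("mcc", 0.9, True, 0),
    )
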