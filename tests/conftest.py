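import numpy as np
import pandas as pd
import pytest

from cytopred.cohort import Cohort, VariableSpec
from cytopred.synthetic import SyntheticConfig, generate


def _clin(name, vtype):
    return VariableSpec(name=name, vtype=vtype, provenance="clinical")


def _cyto(name, cytokine, stim, dur, tp):
    return VariableSpec(name=name, vtype="continuous", provenance="cytokine",
                        cytokine=cytokine, stimulation=stim, duration_h=dur,
                        timepoint=tp)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Six patients, one cytokine condition and three clinical variables,
    with a sprinkling of missing cells."""
    variables = [
        _cyto("IL15_PHA_24h_CB", "IL15", "PHA", 24, "CB"),
        _clin("famhist_first_degree", "ordinal"),
        _clin("tobacco_pregnancy", "binary"),
        _clin("delivery_mode", "nominal"),
    ]
    values = pd.DataFrame(
        {
            "IL15_PHA_24h_CB": [5.2, np.nan, 18.4, 22.0, 19.5, np.nan],
            "famhist_first_degree": [2, 1, 0, np.nan, 1, 0],
            "tobacco_pregnancy": [1, 0, 0, 1, np.nan, 0],
            "delivery_mode": [0, 1, 0, 0, 1, 0],
        },
        index=pd.Index([f"P{i}" for i in range(1, 7)], name="patient_id"),
        dtype=float,
    )
    labels = pd.Series(["IGE", "IGE", "NONALL", "NONALL", "NONALL",
                        "NONIGE_OR_UNCERTAIN"], index=values.index)
    return Cohort(values, variables, labels)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The default 131-patient synthetic cohort, seed 1."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)
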