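import numpy as np
import pytest

from emrfuse.schema import FeatureSchema, PatientRecord
from emrfuse.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def schema():
    return FeatureSchema.default()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_record(schema, rid="R0", label=1, **overrides):
    """A fully measured, in-range record; override individual fields as needed."""
    values = {
        "sex": "male",
        "fever": "yes",
        "age": 64.0,
        "crp": 12.0,
        "ph": 7.38,
        "pao2": 80.0,
        "paco2": 42.0,
        "hco3": 25.0,
        "wbc": 8.5,
        "neut_pct": 63.0,
        "hgb": 132.0,
    }
    values.update(overrides)
    text = {"ct_report": "Chest CT: emphysema noted.", "history": "chronic cough."}
    return PatientRecord(id=rid, values=values, text=text, label=label)


@pytest.fixture
def record(schema):
    return make_record(schema)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=80, n_female=30, n_male=50, seed=11)
    return generate_cohort(cfg)
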