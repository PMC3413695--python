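import numpy as np
import pytest

from brushdx.cohort import default_cohort_spec, generate_cohort
from brushdx.io_tables import CtRecord, CtValue, Cytology, Group
from brushdx.qpcr import compute_delta_ct


def make_record(pid, group, cytology, ct_map):
    """Build a CtRecord from a {gene: value | (value, censored)} mapping."""
    ct = {}
    for gene, v in ct_map.items():
        if isinstance(v, tuple):
            ct[gene] = CtValue(v[0], censored=v[1])
        elif v is None:
            ct[gene] = CtValue(None)
        else:
            ct[gene] = CtValue(float(v))
    return CtRecord(pid, Group(group), Cytology(cytology), ct)


@pytest.fixture
def toy_records():
    """Five hand-made patients over GAPDH + two targets."""
    return [
        make_record("P1", "malignant", "suspicious",
                    {"GAPDH": 18.2, "IGF2BP3": 27.8, "NEK2": 26.5}),
        make_record("P2", "malignant", "positive",
                    {"GAPDH": 20.0, "IGF2BP3": 28.0, "NEK2": 29.0}),
        make_record("P3", "malignant", "negative",
                    {"GAPDH": 19.0, "IGF2BP3": 31.5, "NEK2": 27.5}),
        make_record("P4", "benign", "negative",
                    {"GAPDH": 18.5, "IGF2BP3": 32.0, "NEK2": 29.5}),
        make_record("P5", "benign", "atypical",
                    {"GAPDH": 19.5, "IGF2BP3": 33.5, "NEK2": 30.5}),
    ]


@pytest.fixture
def toy_matrix(toy_records):
    return compute_delta_ct(toy_records, reference="GAPDH")


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec(seed=20260101)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    return compute_delta_ct(default_cohort, reference="GAPDH")


@pytest.fixture
def rng():
    return np.random.default_rng(97531)
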