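import numpy as np
import pytest

from sepsispanel import make_labels, planted_panel_cohort, standardize

#: The five-marker panel with the sign pattern of its sepsis associations:
#: bandemia, CD64 induction and leukocytosis up; thrombocytopenia and the
#: mature-neutrophil share down.
PANEL_EFFECTS = {"Bands": 1.0, "CD64": 0.9, "WBC": 0.8,
                 "Plt": -0.9, "Segs": -0.8}


@pytest.fixture(scope="session")
def planted_dataset():
    """Balanced n=600 cohort with the five-marker planted panel."""
    table, truth = planted_panel_cohort(
        list(PANEL_EFFECTS), PANEL_EFFECTS, n_pos=300, n_neg=300, seed=11)
    return make_labels(table), truth


@pytest.fixture(scope="session")
def planted_standardized(planted_dataset):
    ds, truth = planted_dataset
    return standardize(ds.X, names=ds.names), ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
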