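import numpy as np
import pytest

from concordnet import SymptomTable, build_concordance

# 10-symptom subset used for the worked concordance examples
SUBSET_10 = (
    "fatigue", "mth_ulc", "rsleep", "slpmuch", "shaky",
    "moodchng", "lighthd", "dizzy", "headache", "feetswll",
)
PATIENT_A = ("mth_ulc", "slpmuch", "headache")
PATIENT_B = ("mth_ulc", "slpmuch", "dizzy", "rsleep", "lighthd")


def vector_for(symptoms, labels=SUBSET_10):
    x = np.zeros(len(labels), dtype=np.uint8)
    for s in symptoms:
        x[labels.index(s)] = 1
    return x


@pytest.fixture
def patient_a_matrix():
    return build_concordance(vector_for(PATIENT_A), SUBSET_10)


@pytest.fixture
def patient_b_matrix():
    return build_concordance(vector_for(PATIENT_B), SUBSET_10)


@pytest.fixture
def small_table():
    return SymptomTable(
        ("P1", "P2", "P3"),
        ("fatigue", "rsleep", "headache"),
        np.array([[1, 1, 0], [1, 1, 0], [1, 0, 1]]),
    )


@pytest.fixture
def write_csv(tmp_path):
    def _write(text, name="table.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20240314)


def random_weighted_graph(rng, n, density=0.7):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    return w + w.T
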