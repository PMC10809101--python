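import numpy as np
import pytest

from lungtraj.prep import DesignMatrix, build_design, filter_training
from lungtraj.synthetic import CohortConfig, TrueModel, generate_cohort


def make_truth(intercepts_fev1, intercepts_fvc=None, sigma=0.6,
               slopes=None, log_hr=None, log_rate=None, zero_prob=0.2,
               weights=None, reference=0):
    """Compact constructor for K-component ground truths used across tests."""
    f1 = np.asarray(intercepts_fev1, dtype=float)
    K = len(f1)
    f2 = np.asarray(intercepts_fvc, dtype=float) if intercepts_fvc is not None \
        else f1 * 0.8
    slopes = np.full(K, -0.008) if slopes is None else np.asarray(slopes, float)
    B = np.zeros((K, 2, 4))
    B[:, 0, 0], B[:, 1, 0] = f1, f2
    B[:, 0, 1], B[:, 1, 1] = slopes, slopes * 0.8
    B[:, 0, 2], B[:, 1, 2] = -0.003, -0.002
    B[:, 0, 3], B[:, 1, 3] = -0.004, -0.003
    if log_hr is None:
        log_hr = np.zeros(K)
    if log_rate is None:
        log_rate = np.log(np.full(K, 0.4))
    return TrueModel(
        weights=np.full(K, 1.0 / K) if weights is None else np.asarray(weights),
        B=B,
        sigma=np.full((K, 2), sigma),
        al_mean=0.040 - 0.002 * np.arange(K),
        al_sd=np.full(K, 0.0039),
        log_hr=np.asarray(log_hr, float),
        log_rate=np.asarray(log_rate, float),
        zero_prob=np.full(K, zero_prob),
        parental_prev={},
        reference=reference,
    )


@pytest.fixture(scope="session")
def three_comp_truth():
    # separation >= 1.5 Z between adjacent components
    return make_truth([0.3, -1.7, -3.7], [0.5, -1.2, -2.5], sigma=0.6)


@pytest.fixture(scope="session")
def three_comp_cohort(three_comp_truth):
    cc = CohortConfig(n_subjects=600, censor_lo=12.0, censor_hi=14.0,
                      dropout_prob=0.05)
    return generate_cohort(cc, three_comp_truth, seed=42)


@pytest.fixture(scope="session")
def three_comp_design(three_comp_cohort):
    visits, _, _, _ = three_comp_cohort
    retained, _ = filter_training(visits)
    return build_design(retained)


@pytest.fixture()
def simple_design():
    """Single-population regression design with known coefficients."""
    rng = np.random.default_rng(7)
    n = 200
    X = np.column_stack([
        np.ones(n),
        rng.uniform(0.0, 45.0, n),
        rng.uniform(0.0, 90.0, n),
        rng.uniform(0.0, 45.0, n) * (rng.random(n) < 0.5),
    ])
    beta = np.array([[0.4, -0.01, -0.003, -0.002],
                     [0.2, -0.006, -0.002, -0.001]])
    Y = np.column_stack([
        X @ beta[0] + rng.normal(0.0, 0.6, n),
        X @ beta[1] + rng.normal(0.0, 0.5, n),
    ])
    ids = np.array([f"P{i:04d}" for i in range(n)])
    return DesignMatrix(X=X, Y=Y, subject_ids=ids, subject_index=np.arange(n))


def subject_truth_labels(labels, n_total, subject_ids):
    """Map the generator's per-index labels onto a subject-id subset."""
    idx = {f"S{i:05d}": i for i in range(n_total)}
    return np.asarray(labels)[[idx[s] for s in subject_ids]]
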