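import numpy as np
import pytest

from battkit import dimension as dim
from battkit import synthgen as sg


@pytest.fixture(scope="session")
def extensive_spec():
    return sg.extensive_battery_preset()


@pytest.fixture(scope="session")
def cohort(extensive_spec):
    """One default extensive-preset cohort (n = 75, 4 factors)."""
    latent, scores, items = sg.simulate_cohort(extensive_spec, 75, 4, seed=3)
    return latent, scores, items


@pytest.fixture(scope="session")
def fitted_model(cohort):
    _, scores, _ = cohort
    z = dim.standardize(scores)
    model = dim.fit_rotated_pca(z, 4)
    comp = dim.component_scores(model, z)
    return z, model, comp


def make_noiseless_scores(n_patients: int, loadings: np.ndarray, seed: int = 0,
                          center: float = 50.0, slope: float = 5.0) -> dim.ScoreMatrix:
    """Exact low-rank percent score matrix: affine in latent, no noise."""
    rng = np.random.default_rng(seed)
    k = loadings.shape[1]
    latent = rng.standard_normal((n_patients, k))
    vals = np.clip(center + slope * latent @ loadings.T, 0, 100)
    return dim.ScoreMatrix(vals, [f"P{i}" for i in range(n_patients)],
                           [f"T{j}" for j in range(loadings.shape[0])])
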