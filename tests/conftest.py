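import numpy as np
import pytest

from nanodoe import datasets, fit_rsm


@pytest.fixture(scope="session")
def study():
    """The bundled 17-run study: (DesignTable, ResponseSet)."""
    return datasets.load_study()


@pytest.fixture(scope="session")
def study_models(study):
    """The three reduced models fitted to the bundled run table."""
    _, data = study
    return {name: fit_rsm(data, spec)
            for name, spec in datasets.STUDY_MODEL_SPECS.items()}


@pytest.fixture(scope="session")
def factors():
    return datasets.load_factors()


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent OLS oracle: explicit Gram-matrix inversion."""
    return np.linalg.inv(X.T @ X) @ (X.T @ y)
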