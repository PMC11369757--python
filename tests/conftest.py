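import numpy as np
import pytest

from alfgp.geometry import compute_alf, featurize_set, periodic_mask
from alfgp.gpr import KernelSpec
from alfgp.synthetic import default_toy, sample_conformers


@pytest.fixture(scope="session")
def toy_spec():
    return default_toy()


@pytest.fixture(scope="session")
def small_conformers(toy_spec):
    """120 toy frames with properties, shared across test modules."""
    rng = np.random.default_rng(42)
    return sample_conformers(toy_spec, 120, spread=0.05, rng=rng)


@pytest.fixture(scope="session")
def small_features(small_conformers):
    """(X_train, y_train, X_val, y_val, kernel_spec) for atom 0 / E_IQA."""
    alf = compute_alf(small_conformers.geometry(0))
    X = featurize_set(small_conformers, alf, 0)
    y = small_conformers.atomic_properties["E_IQA"][:, 0]
    spec = KernelSpec(periodic_mask(small_conformers.n_atoms))
    return X[:90], y[:90], X[90:], y[90:], spec
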