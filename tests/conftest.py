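import numpy as np
import pandas as pd
import pytest

from cerebrad.pipeline import FeatureMatrix, column_index
from cerebrad.synthetic import CohortSpec, generate_label_map, generate_subject


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small but valid cohort world: 4 regions on a 24x24x16 grid."""
    return CohortSpec(n_per_group=2, grid_shape=(24, 24, 16), n_regions=4, seed=7)


@pytest.fixture(scope="session")
def tiny_label_map(tiny_spec):
    return generate_label_map(tiny_spec)


@pytest.fixture(scope="session")
def tiny_subject(tiny_spec, tiny_label_map):
    return generate_subject(tiny_spec, "HC", 1, label_map=tiny_label_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_gaussian_feature_matrix(
    n_per_class=30,
    n_regions=4,
    n_informative=30,
    shift=1.0,
    groups=("HC", "AD"),
    seed=0,
) -> FeatureMatrix:
    """Directly simulated feature matrix (no imaging): Gaussian noise plus a
    mean shift on the first ``n_informative`` columns of the second class."""
    rng = np.random.default_rng(seed)
    cols = column_index(("T1",), n_regions)
    p = len(cols)
    X = rng.standard_normal((2 * n_per_class, p))
    X[n_per_class:, :n_informative] += shift
    ids = [f"s{i:03d}" for i in range(2 * n_per_class)]
    labels = pd.Series([groups[0]] * n_per_class + [groups[1]] * n_per_class, index=ids)
    return FeatureMatrix(
        values=pd.DataFrame(X, index=ids, columns=cols),
        labels=labels,
        flags=pd.DataFrame(False, index=ids, columns=cols),
    )


@pytest.fixture()
def gaussian_fm() -> FeatureMatrix:
    return make_gaussian_feature_matrix()
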