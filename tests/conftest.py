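import numpy as np
import pytest

from decisionpath.core import DiscreteDataset, VariableSpec


def build_dataset(X, y, domains=None, target_domain=(0, 1), positive=1,
                  names=None):
    """Construct a DiscreteDataset from integer-coded arrays."""
    X = np.asarray(X, dtype=np.int32).reshape(len(X), -1) if len(X) else np.zeros((0, len(domains or [])), dtype=np.int32)
    p = X.shape[1]
    if domains is None:
        domains = [tuple(range(max(2, int(X[:, j].max()) + 1 if len(X) else 2)))
                   for j in range(p)]
    if names is None:
        names = [f"V{j + 1}" for j in range(p)]
    schema = [VariableSpec(name=names[j], domain=tuple(domains[j])) for j in range(p)]
    target = VariableSpec(name="T", domain=tuple(target_domain))
    return DiscreteDataset(schema, target, X, np.asarray(y, dtype=np.int32),
                           positive=positive)


def random_dataset(rng, max_predictors=4, max_rows=12, missing_prob=0.1):
    """Small random dataset + person for oracle-equivalence checks."""
    p = int(rng.integers(1, max_predictors + 1))
    n = int(rng.integers(2, max_rows + 1))
    domains = [tuple(range(int(rng.integers(2, 4)))) for _ in range(p)]
    X = np.column_stack([rng.integers(0, len(d), size=n) for d in domains]).astype(np.int32)
    X[rng.random(X.shape) < missing_prob] = -1
    y = rng.integers(0, 2, size=n).astype(np.int32)
    person = np.array([rng.integers(0, len(d)) for d in domains], dtype=np.int32)
    person[rng.random(p) < 0.25] = -1
    return build_dataset(X, y, domains=domains), person


@pytest.fixture
def six_row_dataset():
    """6 rows over V1 in {a,b}, V2 in {x,y,z}; binary outcome no/yes."""
    X = np.array([[0, 0], [0, 1], [1, 2], [1, 0], [0, 2], [1, 1]], dtype=np.int32)
    y = np.array([0, 1, 1, 0, 1, 0], dtype=np.int32)
    return build_dataset(X, y, domains=[("a", "b"), ("x", "y", "z")],
                         target_domain=("no", "yes"), positive="yes")
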