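import numpy as np
import pytest

from crossdecomp import (
    METHODS,
    DataBlock,
    default_abcd_like_spec,
    fit_method,
    generate_dataset,
    permutation_test,
    preprocess_blocks,
)

# generation seed pinned by the recovery example (n=2000, seed=1)
DEFAULT_SEED = 1
DEFAULT_N = 2000


def make_block(values, prefix="v", ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if ids is None:
        ids = [f"s{i + 1}" for i in range(n)]
    return DataBlock(tuple(ids), tuple(f"{prefix}{j + 1}" for j in range(p)), values)


def random_blocks(rng, n, p, m, prefixes=("x", "y")):
    X = make_block(rng.standard_normal((n, p)), prefixes[0])
    Y = make_block(rng.standard_normal((n, m)), prefixes[1])
    return X, Y


def cosine(a, b):
    return float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_data():
    """The standard synthetic run shared across modules (n=2000, seed=1)."""
    spec = default_abcd_like_spec(DEFAULT_N, seed=DEFAULT_SEED)
    x, y, confounds, truth = generate_dataset(spec)
    xp, yp = preprocess_blocks(x, y, confounds)
    return {
        "spec": spec,
        "x": x,
        "y": y,
        "confounds": confounds,
        "truth": truth,
        "xp": xp,
        "yp": yp,
    }


@pytest.fixture(scope="session")
def default_fits(default_data):
    xp, yp = default_data["xp"], default_data["yp"]
    return {m: fit_method(m, xp, yp, k=4) for m in METHODS}


@pytest.fixture(scope="session")
def default_reports(default_data):
    """B=1000 permutation reports on the standard run (slow; shared)."""
    xp, yp = default_data["xp"], default_data["yp"]
    return {
        m: permutation_test(xp, yp, m, k=4, B=1000, seed=DEFAULT_SEED)
        for m in METHODS
    }
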