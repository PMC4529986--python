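import numpy as np
import pytest

from patchbind.fixtures import FixtureSpec, load_benchmark
from patchbind.prediction import crossvalidate
from patchbind.structure import annotate_complex

BENCH_SEED = 7


@pytest.fixture(scope="session")
def bench_spec():
    return FixtureSpec(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def benchmark(bench_spec):
    """The default synthetic benchmark, annotated.  Treat as read-only."""
    complexes, pssms, truths = load_benchmark(bench_spec)
    for cm in complexes:
        annotate_complex(cm)
    return complexes, pssms, truths


@pytest.fixture(scope="session")
def cv_result(benchmark):
    """One shared 4-fold cross-validation run on the default benchmark."""
    complexes, pssms, _ = benchmark
    return crossvalidate(complexes, pssms, n_folds=4, seed=BENCH_SEED,
                         annotate=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid(rng):
    """A random proper rotation and translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-50, 50, size=3)
    return rot, t
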