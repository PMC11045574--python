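import numpy as np
import pytest

from scalemok import GRMConfig, ResponseMatrix


def make_matrix(values, levels: int = 5, item_ids=None) -> ResponseMatrix:
    """ResponseMatrix from internal-coded values with no missingness."""
    values = np.asarray(values, dtype=np.int64)
    if item_ids is None:
        item_ids = [f"q{k + 1}" for k in range(values.shape[1])]
    return ResponseMatrix(
        values, list(item_ids), np.zeros(values.shape, dtype=bool), levels=levels
    )


def guttman_matrix(n_per_level: int = 4, j: int = 5) -> ResponseMatrix:
    """Deterministic Guttman-structured data: every item is a nondecreasing
    step function of one common person ordering, so all columns are
    comonotone and every H coefficient equals 1."""
    s = np.repeat(np.arange(10), n_per_level)
    values = np.column_stack(
        [np.clip((s - k) // 2, 0, 4) for k in range(j)]
    )
    return make_matrix(values)


def random_matrix(rng: np.random.Generator, n: int, j: int, levels: int = 5):
    """Random ordinal matrix with a mild common factor so variances and
    covariances are all nondegenerate."""
    theta = rng.standard_normal((n, 1))
    raw = theta + rng.standard_normal((n, j))
    cuts = np.quantile(raw, [0.2, 0.4, 0.6, 0.8][: levels - 1])
    return make_matrix((raw[..., None] > cuts).sum(axis=2), levels=levels)


def single_factor_config(seed: int, n: int = 2000, a: float = 1.8) -> GRMConfig:
    """Unidimensional common-discrimination generator: the null model under
    which monotonicity and invariant item ordering hold exactly."""
    return GRMConfig(
        n=n,
        seed=seed,
        discriminations=np.full(9, a),
        cluster_assignment=np.zeros(9, dtype=int),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def guttman():
    return guttman_matrix()
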