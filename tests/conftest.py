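import numpy as np
import pytest

from obsight.preprocess import ExpressionTimeSeries


def random_stable_system(n, r, seed=0, eig_range=(0.3, 0.95)):
    """A diagonalizable rank-r operator with known real spectrum on n genes."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, r))
    A, _ = np.linalg.qr(A)
    eigs = rng.uniform(*eig_range, size=r)
    K = A @ np.diag(eigs) @ A.T
    z0 = A @ rng.normal(size=r)
    return K, np.sort(eigs)[::-1], z0


def trajectory(K, z0, m):
    """Columns z0, Kz0, ..., K^{m-1} z0."""
    cols = []
    x = np.asarray(z0, dtype=float).copy()
    for _ in range(m):
        cols.append(x.copy())
        x = K @ x
    return np.column_stack(cols)


def roc_auc(scores, labels):
    """Rank-based AUC (Mann-Whitney)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(scores)
    ranks = np.empty(scores.size)
    ranks[order] = np.arange(1, scores.size + 1)
    n1, n0 = labels.sum(), (~labels).sum()
    return (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


@pytest.fixture
def paired_expression():
    """Tiny paired perturbed/control TPM series: 4 genes, 3 times, 2 reps."""
    def make(values_p, values_c=None, unit="TPM"):
        if values_c is None:
            values_c = np.asarray(values_p).copy()
        kw = dict(
            gene_ids=[f"g{i}" for i in range(np.asarray(values_p).shape[0])],
            time_min=[0.0, 10.0, 20.0],
            replicate_ids=["r1", "r2"],
            unit=unit,
        )
        return (
            ExpressionTimeSeries(values=values_p, condition="perturbed", **kw),
            ExpressionTimeSeries(values=values_c, condition="control", **kw),
        )

    return make
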