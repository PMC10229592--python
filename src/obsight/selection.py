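"""Biomarker gene-set selection from the observability ranking.

Three strategies turn the per-gene sampling weights into a candidate
reporter panel of k genes:

* top-rank — simply take the k highest-|weight| genes (top responders, but
  typically highly co-expressed);
* correlation threshold — walk down the ranking greedily, admitting a gene
  only if its |Pearson| correlation with every previously admitted gene is
  below a threshold;
* random search — Monte Carlo sampling of k-subsets from the top of the
  ranking, scored jointly by cell-state reconstruction accuracy and by the
  set-correlation metric

      C = || 1_{k x k} - |R| ||_F,

  the Frobenius distance between the all-ones matrix and the elementwise
  absolute Pearson matrix of the set's trajectories.  C = 0 means every
  pair is perfectly correlated (a redundant panel); C grows toward
  sqrt(k^2 - k) as the set decorrelates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observability import GeneWeights
from .reconstruction import mask_to_support, reconstruct

__all__ = [
    "GeneSetEvaluation",
    "correlation_metric",
    "select_top_k",
    "select_correlation_threshold",
    "random_set_search",
]


@dataclass
class GeneSetEvaluation:
    gene_ids: list
    gene_index: np.ndarray
    C_metric: float
    strategy: str
    recon_r2: float | None = None
    rank_percentiles: list[float] = field(default_factory=list)


def correlation_metric(trajectories: np.ndarray) -> float:
    """Set-correlation metric C = ||1 - |Pearson|||_F of a k x time matrix."""
    X = np.asarray(trajectories, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 gene trajectories")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("constant trajectory; Pearson correlation undefined")
    R = np.corrcoef(X)
    return float(np.linalg.norm(1.0 - np.abs(R), ord="fro"))


def _ids(weights: GeneWeights, idx: np.ndarray) -> list:
    if weights.gene_ids is not None:
        return [weights.gene_ids[i] for i in idx]
    return idx.tolist()


def _percentiles(ranking: np.ndarray, idx: np.ndarray) -> list[float]:
    pos = {g: p for p, g in enumerate(ranking)}
    n = ranking.size
    return [100.0 * (1 - pos[g] / n) for g in idx]


def select_top_k(
    weights: GeneWeights,
    trajectories: np.ndarray,
    k: int = 15,
    normalized: bool = False,
) -> GeneSetEvaluation:
    """The k top-ranked genes by |weight|."""
    ranking = weights.ranking(normalized=normalized)
    idx = ranking[:k]
    return GeneSetEvaluation(
        gene_ids=_ids(weights, idx),
        gene_index=idx,
        C_metric=correlation_metric(trajectories[idx]) if k >= 2 else 0.0,
        strategy="top_rank",
        rank_percentiles=_percentiles(ranking, idx),
    )


def select_correlation_threshold(
    weights: GeneWeights,
    trajectories: np.ndarray,
    threshold: float = 0.5,
    k: int = 15,
    normalized: bool = False,
) -> GeneSetEvaluation:
    """Greedy rank walk admitting only weakly correlated genes.

    Starts from the top-ranked gene and admits each subsequent gene iff its
    maximum |Pearson| correlation with all previously admitted genes is
    strictly below ``threshold``; stops at k genes or the end of the list.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ranking = weights.ranking(normalized=normalized)
    X = np.asarray(trajectories, dtype=float)
    admitted: list[int] = []
    for g in ranking:
        if not admitted:
            admitted.append(int(g))
        else:
            r = np.abs(np.corrcoef(X[admitted + [int(g)]])[-1, :-1])
            if np.max(r) < threshold:
                admitted.append(int(g))
        if len(admitted) == k:
            break
    if len(admitted) < k:
        warnings.warn(
            f"only {len(admitted)} genes pass the correlation threshold "
            f"{threshold}; requested {k}",
            stacklevel=2,
        )
    idx = np.asarray(admitted, dtype=int)
    return GeneSetEvaluation(
        gene_ids=_ids(weights, idx),
        gene_index=idx,
        C_metric=correlation_metric(X[idx]) if idx.size >= 2 else 0.0,
        strategy="correlation_threshold",
        rank_percentiles=_percentiles(ranking, idx),
    )


def evaluate_gene_set(
    weights: GeneWeights,
    trajectories: np.ndarray,
    K: np.ndarray,
    z0: np.ndarray,
    gene_index: np.ndarray,
    T: int = 8,
    strategy: str = "manual",
) -> GeneSetEvaluation:
    """Score an arbitrary gene set by C and reconstruction R^2 at horizon T."""
    idx = np.asarray(gene_index, dtype=int)
    w_masked = mask_to_support(weights.primary_w, idx)
    res = reconstruct(K, w_masked, z0, T)
    ranking = weights.ranking()
    return GeneSetEvaluation(
        gene_ids=_ids(weights, idx),
        gene_index=idx,
        C_metric=correlation_metric(np.asarray(trajectories)[idx]),
        strategy=strategy,
        recon_r2=res.r2,
        rank_percentiles=_percentiles(ranking, idx),
    )


def random_set_search(
    weights: GeneWeights,
    trajectories: np.ndarray,
    K: np.ndarray,
    z0: np.ndarray,
    k: int = 15,
    pool_fraction: float = 0.5,
    trials: int = 10_000,
    T: int = 8,
    seed: int = 0,
    normalized: bool = False,
) -> pd.DataFrame:
    """Monte Carlo search over k-subsets of the top of the ranking.

    Each trial draws a uniform k-subset of the pool (top ``pool_fraction``
    of the ranking, default the top half), reconstructs the cell state from
    those genes over T time points, and computes the set-correlation metric.
    Returns one row per trial with percentile annotations for both scores.
    """
    ranking = weights.ranking(normalized=normalized)
    pool = ranking[: int(np.ceil(pool_fraction * ranking.size))]
    if pool.size < k:
        raise ValueError(f"pool of {pool.size} genes smaller than k={k}")
    X = np.asarray(trajectories, dtype=float)
    rows = []
    for trial in range(trials):
        rng = np.random.default_rng([seed, trial])
        idx = np.sort(rng.choice(pool, size=k, replace=False))
        w_masked = mask_to_support(weights.primary_w, idx)
        res = reconstruct(K, w_masked, z0, T)
        rows.append(
            {
                "trial": trial,
                "genes": ",".join(str(g) for g in _ids(weights, idx)),
                "C": correlation_metric(X[idx]),
                "recon_r2": res.r2,
            }
        )
    df = pd.DataFrame(rows)
    df["r2_percentile"] = df["recon_r2"].rank(pct=True) * 100
    df["C_percentile"] = df["C"].rank(pct=True) * 100
    return df
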