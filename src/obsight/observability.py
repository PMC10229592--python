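"""Gram-matrix observability analysis and gene sampling weights.

A scalar readout y_t = w' K^t z0 of the linear cell-state model carries
finite-horizon signal energy

    E_y = sum_{i=0..m} (w' K^i z0)^2 = w' G w,
    G   = sum_{i=0..m} K^i z0 z0' (K^i)',

summed over all available initial conditions.  Maximizing E_y over
orthonormal weight rows W (the relaxed sensor-placement program) is solved
exactly by the top eigenvectors of G: the leading eigenvector q1 is the
single weight vector that makes the cell state most observable, and each
gene's entry in q1 quantifies its contribution to observability — its
biomarker rank.  The finite horizon (default: number of modeled time
points) keeps the sum convergent when the fitted spectrum contains
marginally unstable eigenvalues.

Because experiments provide only a few replicate initial conditions, the
set is enriched with N synthetic initial conditions sampled per gene from
Uniform(min over replicates, max over replicates), which regularizes the
Gram matrix toward full rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmd import DMDModel

__all__ = [
    "GramMatrix",
    "GeneWeights",
    "enrich_initial_conditions",
    "gram_matrix",
    "reduced_gram_matrix",
    "signal_energy",
    "sampling_weights",
    "rank_genes",
]

# above this gene count the dense n x n Gram matrix is not formed; the
# reduced-order route through the DMD basis is used instead
FULL_GRAM_MAX_GENES = 5000


@dataclass
class GramMatrix:
    """Finite-horizon observability Gram matrix (full or reduced order)."""

    G: np.ndarray
    horizon: int
    reduced: bool = False
    basis_U: np.ndarray | None = None  # set for reduced matrices


@dataclass
class GeneWeights:
    """Orthonormal sampling-weight vectors ranking genes by observability.

    ``weights_W`` stacks the top-p Gram eigenvectors as rows; ``primary_w``
    is the first row q1.  ``normalized_w`` divides q1 by each gene's
    fold-change standard deviation, the display/ranking variant that puts
    genes of different dynamic range on a common footing.
    """

    weights_W: np.ndarray
    primary_w: np.ndarray
    normalized_w: np.ndarray | None
    gram_eigenvalues: np.ndarray
    horizon_m: int
    n_synthetic_ics: int
    seed: int | None
    gene_ids: list[str] | None = None

    def ranking(self, normalized: bool = False) -> np.ndarray:
        """Gene indices sorted by descending |weight| (ties by gene order)."""
        w = self.normalized_w if (normalized and self.normalized_w is not None) else self.primary_w
        return np.argsort(-np.abs(w), kind="stable")


def enrich_initial_conditions(
    replicate_z0s: np.ndarray, N: int | None = None, seed: int = 0
) -> np.ndarray:
    """Sample N synthetic initial conditions within the replicate envelope.

    Each gene is drawn i.i.d. from Uniform(min_j z0_j, max_j z0_j) over the
    replicate initial conditions.  ``N`` defaults to the gene count so the
    initial-condition matrix has full rank.  Deterministic for a fixed seed.
    """
    z0s = np.atleast_2d(np.asarray(replicate_z0s, dtype=float))
    if z0s.ndim != 2:
        raise ValueError("replicate_z0s must be (n_genes, n_replicates)")
    n = z0s.shape[0]
    if N is None:
        N = n
    if N < 1:
        raise ValueError("N must be at least 1")
    lo = z0s.min(axis=1)
    hi = z0s.max(axis=1)
    rng = np.random.default_rng(seed)
    u = rng.random((n, N))
    return lo[:, None] + u * (hi - lo)[:, None]


def gram_matrix(K: np.ndarray, Z0: np.ndarray, horizon_m: int) -> GramMatrix:
    """Finite-horizon Gram matrix G = sum_{i=0..m} K^i Z0 Z0' (K^i)'.

    ``Z0`` may hold several initial conditions as columns; the sum of their
    rank-one Gram contributions is accumulated in one pass.
    """
    K = np.asarray(K, dtype=float)
    Z0 = np.asarray(Z0, dtype=float)
    if Z0.ndim == 1:
        Z0 = Z0[:, None]
    if K.shape[0] != K.shape[1] or K.shape[0] != Z0.shape[0]:
        raise ValueError("K must be square and conformable with Z0")
    if horizon_m < 0:
        raise ValueError("horizon must be nonnegative")
    M = Z0
    G = np.zeros((K.shape[0], K.shape[0]))
    for _ in range(horizon_m + 1):
        G += M @ M.T
        M = K @ M
    G = 0.5 * (G + G.T)  # enforce exact symmetry against accumulation error
    return GramMatrix(G=G, horizon=horizon_m, reduced=False)


def reduced_gram_matrix(
    model: DMDModel, Z0: np.ndarray, horizon_m: int
) -> GramMatrix:
    """Reduced-order Gram matrix in the r-dimensional DMD basis.

    G_tilde = sum_{i=0..m} K_hat^i (U' Z0)(U' Z0)' (K_hat^i)'.  The leading
    eigenpairs of the full G are approximated by the eigenvalues of G_tilde
    and eigenvectors U @ q_tilde, avoiding any n x n matrix.
    """
    Z0 = np.asarray(Z0, dtype=float)
    if Z0.ndim == 1:
        Z0 = Z0[:, None]
    Y = model.basis_U.T @ Z0
    inner = gram_matrix(model.reduced_K, Y, horizon_m)
    return GramMatrix(
        G=inner.G, horizon=horizon_m, reduced=True, basis_U=model.basis_U
    )


def signal_energy(
    K: np.ndarray, w: np.ndarray, z0: np.ndarray, horizon_m: int
) -> float:
    """Finite-horizon output energy sum_{t=0..m} (w' K^t z0)^2."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(z0, dtype=float)
    K = np.asarray(K, dtype=float)
    energy = 0.0
    for _ in range(horizon_m + 1):
        energy += float(w @ x) ** 2
        x = K @ x
    return energy


def _fix_eigvec_signs(Q: np.ndarray) -> np.ndarray:
    for j in range(Q.shape[1]):
        i = np.argmax(np.abs(Q[:, j]))
        if Q[i, j] < 0:
            Q[:, j] *= -1
    return Q


def sampling_weights(
    G: GramMatrix,
    p: int = 1,
    gene_sigma: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    horizon_m: int | None = None,
    n_synthetic_ics: int = 0,
    seed: int | None = None,
    tie_rtol: float = 1e-8,
) -> GeneWeights:
    """Solve the relaxed sensor-placement program: top-p Gram eigenvectors.

    Rows of the returned W are the eigenvectors of G with the p largest
    eigenvalues, in descending order, with a deterministic sign convention
    (largest-|entry| component positive, so a negative weight consistently
    marks a downregulated gene).  For a reduced-order Gram matrix the
    eigenvectors are lifted back to gene space through the DMD basis.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    eigvals, eigvecs = np.linalg.eigh(G.G)
    order = np.argsort(-eigvals)
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if p > eigvecs.shape[1]:
        raise ValueError(f"p={p} exceeds the Gram dimension {eigvecs.shape[1]}")
    if eigvals.size > 1 and abs(eigvals[0] - eigvals[1]) <= tie_rtol * max(abs(eigvals[0]), 1e-300):
        warnings.warn("leading Gram eigenvalues are tied; q1 is not unique", stacklevel=2)
    Q = eigvecs[:, :p]
    if G.reduced:
        if G.basis_U is None:
            raise ValueError("reduced Gram matrix lacks its projection basis")
        Q = G.basis_U @ Q
        # lifted vectors stay orthonormal because U has orthonormal columns
    Q = _fix_eigvec_signs(Q.copy())
    primary = Q[:, 0]
    normalized = None
    if gene_sigma is not None:
        sigma = np.asarray(gene_sigma, dtype=float)
        if sigma.shape != primary.shape:
            raise ValueError("gene_sigma length does not match gene count")
        normalized = primary / sigma
    return GeneWeights(
        weights_W=Q.T,
        primary_w=primary,
        normalized_w=normalized,
        gram_eigenvalues=eigvals,
        horizon_m=G.horizon if horizon_m is None else horizon_m,
        n_synthetic_ics=n_synthetic_ics,
        seed=seed,
        gene_ids=gene_ids,
    )


def rank_genes(
    model: DMDModel,
    replicate_z0s: np.ndarray,
    gene_sigma: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    horizon_m: int | None = None,
    n_ics: int | None = None,
    p: int = 1,
    seed: int = 0,
) -> GeneWeights:
    """End-to-end gene ranking: enrich ICs, build the Gram matrix, solve.

    The dense gene-space Gram matrix is used up to ``FULL_GRAM_MAX_GENES``
    genes; beyond that the reduced-order route is mandatory.  The horizon
    defaults to the number of modeled time points (replicate trajectory
    length inferred from the shift matrices is the caller's concern; pass
    ``horizon_m`` explicitly when it differs).
    """
    z0s = np.atleast_2d(np.asarray(replicate_z0s, dtype=float))
    n = z0s.shape[0]
    if horizon_m is None:
        horizon_m = model.rank_r  # sensible fallback; callers pass m normally
    Z0_syn = enrich_initial_conditions(z0s, N=n_ics, seed=seed)
    Z0 = np.hstack([z0s, Z0_syn])
    if n <= FULL_GRAM_MAX_GENES:
        G = gram_matrix(model.full_operator(), Z0, horizon_m)
    else:
        G = reduced_gram_matrix(model, Z0, horizon_m)
    return sampling_weights(
        G,
        p=p,
        gene_sigma=gene_sigma,
        gene_ids=gene_ids,
        horizon_m=horizon_m,
        n_synthetic_ics=Z0_syn.shape[1],
        seed=seed,
    )


def weight_table(weights: GeneWeights) -> pd.DataFrame:
    """Per-gene weight export: raw and sigma-normalized weights plus ranks."""
    n = weights.primary_w.shape[0]
    ids = weights.gene_ids if weights.gene_ids is not None else [f"g{i}" for i in range(n)]
    df = pd.DataFrame({"gene_id": ids, "w": weights.primary_w})
    rank_raw = np.empty(n, dtype=int)
    rank_raw[np.argsort(-np.abs(weights.primary_w), kind="stable")] = np.arange(1, n + 1)
    df["rank_raw"] = rank_raw
    if weights.normalized_w is not None:
        df["w_normalized"] = weights.normalized_w
        rank_norm = np.empty(n, dtype=int)
        rank_norm[np.argsort(-np.abs(weights.normalized_w), kind="stable")] = np.arange(1, n + 1)
        df["rank_normalized"] = rank_norm
    return df
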