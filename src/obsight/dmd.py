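"""Exact dynamic mode decomposition of the standardized fold-change state.

DMD approximates the best-fit linear evolution operator K between
time-shifted snapshot matrices Z_f ~ K Z_p in the least-squares sense.  With
the rank-r truncated SVD Z_p = U S T', the reduced operator

    K_hat = U' Z_f T S^{-1} = U' K U

is similar to K restricted to the leading subspace: its eigenvalues are the
leading eigenvalues of K, and its eigenvectors s map to full-space dynamic
modes v = U s.  The state is then reconstructed spectrally as

    z_t = V Lambda^t b,    b = pinv(V) z_0,

so each mode contributes a damped/growing (|lambda| <> 1), possibly
oscillatory (Im lambda != 0) component to every gene's trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import FoldChangeState

__all__ = [
    "DMDModel",
    "ModeLabel",
    "build_shift_matrices",
    "fit_exact_dmd",
    "fit_from_state",
    "predict",
    "r_squared",
    "rank_scan",
    "classify_modes",
    "cluster_by_mode",
]

_IMAG_TOL = 1e-8


@dataclass
class DMDModel:
    """Rank-r exact-DMD operator in factored form.

    Attributes
    ----------
    rank_r
        Truncation rank.
    basis_U
        (n_genes, r) orthonormal projection basis (left singular vectors
        of the past snapshot matrix).
    reduced_K
        (r, r) reduced operator K_hat.
    modes_V
        (n_genes, r) complex dynamic modes (columns).
    eigenvalues
        Length-r complex spectrum of K_hat, ordered by descending magnitude
        with conjugate pairs adjacent.
    amplitudes_b
        Mode amplitudes pinv(V) @ z0, with z0 the mean of the replicate
        initial conditions.
    singular_values
        The r retained singular values of Z_p.
    """

    rank_r: int
    basis_U: np.ndarray
    reduced_K: np.ndarray
    modes_V: np.ndarray
    eigenvalues: np.ndarray
    amplitudes_b: np.ndarray
    singular_values: np.ndarray
    gene_ids: list[str] | None = None

    @property
    def n_genes(self) -> int:
        return self.basis_U.shape[0]

    def full_operator(self) -> np.ndarray:
        """The (n_genes, n_genes) projected operator K = U K_hat U'."""
        return self.basis_U @ self.reduced_K @ self.basis_U.T

    def save(self, path) -> None:
        """Serialize to JSON (complex arrays stored as re/im pairs)."""
        def enc(a: np.ndarray):
            a = np.asarray(a)
            if np.iscomplexobj(a):
                return {"re": a.real.tolist(), "im": a.imag.tolist()}
            return {"re": a.tolist()}

        payload = {
            "rank_r": self.rank_r,
            "basis_U": enc(self.basis_U),
            "reduced_K": enc(self.reduced_K),
            "modes_V": enc(self.modes_V),
            "eigenvalues": enc(self.eigenvalues),
            "amplitudes_b": enc(self.amplitudes_b),
            "singular_values": enc(self.singular_values),
            "gene_ids": self.gene_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DMDModel":
        with open(path) as fh:
            payload = json.load(fh)

        def dec(d):
            re = np.asarray(d["re"], dtype=float)
            if "im" in d:
                return re + 1j * np.asarray(d["im"], dtype=float)
            return re

        return cls(
            rank_r=int(payload["rank_r"]),
            basis_U=dec(payload["basis_U"]),
            reduced_K=dec(payload["reduced_K"]),
            modes_V=dec(payload["modes_V"]),
            eigenvalues=dec(payload["eigenvalues"]),
            amplitudes_b=dec(payload["amplitudes_b"]),
            singular_values=dec(payload["singular_values"]),
            gene_ids=payload.get("gene_ids"),
        )


@dataclass
class ModeLabel:
    """Stability/oscillation classification of one DMD eigenvalue."""

    index: int
    stability: str  # {stable, unstable, marginal}
    oscillatory: bool
    magnitude: float
    frequency: float  # arg(lambda), radians per time step


def build_shift_matrices(
    state: FoldChangeState | np.ndarray,
    n_timepoints: int | None = None,
    n_replicates: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-shifted snapshot matrices (Z_p, Z_f) from replicate trajectories.

    Within each replicate block of m columns, Z_p takes columns 0..m-2 and
    Z_f columns 1..m-1; blocks are concatenated so no (past, future) pair
    straddles a replicate boundary.
    """
    if isinstance(state, FoldChangeState):
        z, m, r = state.zbar, state.n_timepoints, state.n_replicates
    else:
        z = np.asarray(state, dtype=float)
        m = n_timepoints if n_timepoints is not None else z.shape[1]
        r = n_replicates if n_replicates is not None else 1
    if m < 2:
        raise ValueError("each replicate needs at least 2 time points")
    zp_blocks, zf_blocks = [], []
    for j in range(r):
        block = z[:, j * m : (j + 1) * m]
        zp_blocks.append(block[:, :-1])
        zf_blocks.append(block[:, 1:])
    return np.hstack(zp_blocks), np.hstack(zf_blocks)


def _deterministic_svd_signs(U: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Flip each (u, t) pair so the largest-|.| entry of u is positive.
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] *= -1
            T[:, j] *= -1
    return U, T


def _order_spectrum(eigvals: np.ndarray, eigvecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Descending |lambda|; within ties, positive imaginary part first so
    # conjugate pairs sit adjacently in a reproducible order.
    key = np.lexsort((-eigvals.imag, -np.abs(eigvals)))
    return eigvals[key], eigvecs[:, key]


def fit_exact_dmd(
    Z_p: np.ndarray,
    Z_f: np.ndarray,
    rank_r: int,
    z0: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
) -> DMDModel:
    """Fit exact DMD at truncation rank ``rank_r``.

    Parameters
    ----------
    Z_p, Z_f
        Past/future snapshot matrices from :func:`build_shift_matrices`.
    rank_r
        Number of singular values retained; must not exceed the numerical
        rank of ``Z_p``.
    z0
        Initial condition used for the amplitudes b = pinv(V) z0.  Defaults
        to the first column of ``Z_p`` (callers with replicates should pass
        the mean of replicate initial conditions).
    """
    Z_p = np.asarray(Z_p, dtype=float)
    Z_f = np.asarray(Z_f, dtype=float)
    if Z_p.shape != Z_f.shape:
        raise ValueError("Z_p and Z_f must have identical shapes")
    U, s, Vt = np.linalg.svd(Z_p, full_matrices=False)
    tol = max(Z_p.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    num_rank = int(np.sum(s > tol))
    if rank_r > num_rank:
        raise ValueError(
            f"requested rank {rank_r} exceeds numerical rank {num_rank}"
        )
    U = U[:, :rank_r].copy()
    T = Vt[:rank_r].T.copy()
    s = s[:rank_r]
    U, T = _deterministic_svd_signs(U, T)
    K_hat = U.T @ Z_f @ T / s  # right-multiplying by S^{-1}
    eigvals, eigvecs = np.linalg.eig(K_hat)
    eigvals, eigvecs = _order_spectrum(eigvals, eigvecs)
    V = U @ eigvecs
    if z0 is None:
        z0 = Z_p[:, 0]
    b = np.linalg.pinv(V) @ np.asarray(z0, dtype=complex)
    return DMDModel(
        rank_r=rank_r,
        basis_U=U,
        reduced_K=K_hat,
        modes_V=V,
        eigenvalues=eigvals,
        amplitudes_b=b,
        singular_values=s,
        gene_ids=gene_ids,
    )


def fit_from_state(state: FoldChangeState, rank_r: int = 10) -> DMDModel:
    """Fit exact DMD to a standardized fold-change state.

    Replicate blocks are concatenated respecting trajectory boundaries; the
    amplitude vector uses the mean of the replicate initial conditions.
    """
    Z_p, Z_f = build_shift_matrices(state)
    z0 = state.initial_conditions().mean(axis=1)
    return fit_exact_dmd(Z_p, Z_f, rank_r, z0=z0, gene_ids=state.gene_ids)


def predict(model: DMDModel, z0: np.ndarray, steps: int) -> np.ndarray:
    """Spectral full-horizon prediction z_t = V Lambda^t pinv(V) z0.

    Only the initial condition is fed to the model; all subsequent time
    points are extrapolated.  Returns a real (n_genes, steps + 1) matrix;
    residual imaginary parts below 1e-8 are discarded.
    """
    z0 = np.asarray(z0, dtype=complex)
    if z0.shape[0] != model.n_genes:
        raise ValueError("initial condition length does not match gene count")
    b = np.linalg.pinv(model.modes_V) @ z0
    powers = model.eigenvalues[None, :] ** np.arange(steps + 1)[:, None]
    # conjugate symmetry cancels imaginary parts for real data; residue is
    # numerical noise and is discarded
    out = model.modes_V @ (powers * b[None, :]).T
    return out.real


def r_squared(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Coefficient of determination pooled over all genes and time points.

    R^2 = 1 - SS_res / SS_dev, with residuals against the data and
    deviations measured from each gene's time-mean.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("prediction/actual shape mismatch")
    if actual.ndim == 1:
        actual = actual[None, :]
        predicted = predicted[None, :]
    gene_mean = actual.mean(axis=1, keepdims=True)
    ss_dev = float(np.sum((actual - gene_mean) ** 2))
    if ss_dev == 0.0:
        raise ValueError("zero total deviation; R^2 undefined")
    ss_res = float(np.sum((actual - predicted) ** 2))
    return 1.0 - ss_res / ss_dev


def predict_state(model: DMDModel, state: FoldChangeState, pooled: bool = True) -> float:
    """Full-horizon prediction R^2 on a fold-change state.

    One prediction per replicate, each seeded only with that replicate's
    initial condition and run for the remaining m - 1 steps.  Replicates are
    pooled into a single R^2 by default.
    """
    m = state.n_timepoints
    preds, acts = [], []
    for j in range(state.n_replicates):
        block = state.replicate_block(j)
        preds.append(predict(model, block[:, 0], m - 1))
        acts.append(block)
    if pooled:
        return r_squared(np.hstack(preds), np.hstack(acts))
    return float(np.mean([r_squared(p, a) for p, a in zip(preds, acts)]))


def rank_scan(
    state: FoldChangeState, r_values: list[int], stability_tol: float = 1e-9
) -> pd.DataFrame:
    """Fit one model per rank; report full-horizon R^2 and unstable-mode count."""
    rows = []
    for r in r_values:
        model = fit_from_state(state, r)
        n_unstable = int(np.sum(np.abs(model.eigenvalues) > 1 + stability_tol))
        rows.append({"r": r, "r2": predict_state(model, state), "n_unstable": n_unstable})
    return pd.DataFrame(rows)


def classify_modes(model: DMDModel, tol: float = 1e-9) -> list[ModeLabel]:
    """Label each eigenvalue stable/unstable/marginal and oscillatory or not.

    |lambda| < 1 decays, |lambda| > 1 grows, |lambda| within ``tol`` of the
    unit circle is marginal; a nonzero imaginary part (beyond ``tol``) marks
    an oscillatory mode (these come in conjugate pairs for real data).
    """
    labels = []
    for i, lam in enumerate(model.eigenvalues):
        mag = abs(lam)
        if mag < 1 - tol:
            stability = "stable"
        elif mag > 1 + tol:
            stability = "unstable"
        else:
            stability = "marginal"
        labels.append(
            ModeLabel(
                index=i,
                stability=stability,
                oscillatory=bool(abs(lam.imag) > tol),
                magnitude=float(mag),
                frequency=float(np.angle(lam)),
            )
        )
    return labels


def cluster_by_mode(model: DMDModel, mode_index: int, top_k: int) -> list[int]:
    """Indices of the ``top_k`` genes most loaded on one mode.

    The loading of mode j on gene i is |V[i, j]|; ties break by gene order.
    """
    if not 0 <= mode_index < model.rank_r:
        raise ValueError(f"mode index {mode_index} outside 0..{model.rank_r - 1}")
    loading = np.abs(model.modes_V[:, mode_index])
    order = np.argsort(-loading, kind="stable")
    return order[:top_k].tolist()


def mode_table(model: DMDModel, tol: float = 1e-9) -> pd.DataFrame:
    """Eigenvalue/mode summary table for export."""
    labels = classify_modes(model, tol)
    return pd.DataFrame(
        {
            "mode": [l.index for l in labels],
            "eig_real": model.eigenvalues.real,
            "eig_imag": model.eigenvalues.imag,
            "magnitude": [l.magnitude for l in labels],
            "frequency": [l.frequency for l in labels],
            "stability": [l.stability for l in labels],
            "oscillatory": [l.oscillatory for l in labels],
            "amplitude_abs": np.abs(model.amplitudes_b),
        }
    )
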