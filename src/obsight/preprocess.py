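"""Expression preprocessing: TPM normalization, low-expression filtering,
fold-change cell state, and standardization.

The cell state used throughout the package is the gene-wise fold change of a
perturbed condition relative to a matched control,

    z = (x_perturbed + 1) / (x_control + 1),

computed per (time point, replicate) snapshot on TPM values, then standardized
per gene (time-mean removed, time-standard-deviation scaled to one, pooling
all replicate columns).  The +1 pseudocount guards against division by zero
for unexpressed genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTimeSeries",
    "FoldChangeState",
    "compute_tpm",
    "filter_low_expression",
    "fold_change",
    "standardize",
    "destandardize",
    "background_subtract",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionTimeSeries:
    """Gene x (time x replicate) expression matrix for one condition.

    Columns are ordered replicate-major: all time points of replicate 1,
    then all time points of replicate 2, and so on.

    Parameters
    ----------
    values
        Nonnegative matrix of shape (n_genes, n_timepoints * n_replicates),
        raw counts or TPM.
    gene_ids
        One identifier per row.
    time_min
        Time stamps in minutes for one replicate block (strictly increasing).
    replicate_ids
        One label per replicate block.
    condition
        Free-text condition label, e.g. ``"perturbed"`` or ``"control"``.
    unit
        ``"counts"`` or ``"TPM"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    time_min: list[float]
    replicate_ids: list[str]
    condition: str
    unit: str = "TPM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.time_min = [float(t) for t in self.time_min]
        self.replicate_ids = list(self.replicate_ids)
        n, cols = self.values.shape
        if n != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} rows of values"
            )
        if cols != len(self.time_min) * len(self.replicate_ids):
            raise ValueError(
                f"{cols} columns but {len(self.time_min)} time points x "
                f"{len(self.replicate_ids)} replicates"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return len(self.time_min)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def subset_genes(self, index: np.ndarray) -> "ExpressionTimeSeries":
        """Return a copy restricted to the given gene row indices."""
        return replace(
            self,
            values=self.values[index],
            gene_ids=[self.gene_ids[i] for i in np.atleast_1d(index)],
        )

    def drop_first_timepoint(self) -> "ExpressionTimeSeries":
        """Remove the first (pre-perturbation) time point of every replicate."""
        m, r = self.n_timepoints, self.n_replicates
        keep = np.concatenate([np.arange(1, m) + j * m for j in range(r)])
        return replace(
            self, values=self.values[:, keep], time_min=self.time_min[1:]
        )


@dataclass
class FoldChangeState:
    """Standardized fold-change matrix with the statistics removed from it.

    ``zbar`` has one row per gene with (pooled) time-mean zero and population
    time-standard-deviation one; ``mu`` and ``sigma`` allow exact
    destandardization.  Replicate-major column ordering is inherited from the
    expression matrices.
    """

    zbar: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    raw_z: np.ndarray
    gene_ids: list[str]
    n_timepoints: int
    n_replicates: int
    time_min: list[float] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.zbar.shape[0]

    def replicate_block(self, j: int) -> np.ndarray:
        """Columns of ``zbar`` belonging to replicate ``j`` (0-based)."""
        m = self.n_timepoints
        return self.zbar[:, j * m : (j + 1) * m]

    def initial_conditions(self) -> np.ndarray:
        """Per-replicate initial state, shape (n_genes, n_replicates)."""
        m = self.n_timepoints
        cols = [j * m for j in range(self.n_replicates)]
        return self.zbar[:, cols]


def compute_tpm(
    counts: np.ndarray, gene_lengths_bp: np.ndarray
) -> np.ndarray:
    """Convert a counts matrix to transcripts per million.

    TPM divides each count by gene length (reads-per-base rate) and rescales
    every column to sum to 1e6, correcting for both gene length and
    sequencing depth.

    Parameters
    ----------
    counts
        Nonnegative (n_genes, n_samples) matrix.
    gene_lengths_bp
        Positive per-gene lengths in base pairs.

    Returns
    -------
    np.ndarray
        TPM matrix of the same shape; each column sums to 1e6.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if lengths.shape != (counts.shape[0],):
        raise ValueError("need exactly one length per gene")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    rate = counts / lengths[:, None]
    col_sums = rate.sum(axis=0)
    zero_cols = np.flatnonzero(col_sums == 0)
    if zero_cols.size:
        raise ValueError(f"all-zero count column(s) at index {zero_cols.tolist()}")
    return 1e6 * rate / col_sums


def counts_to_tpm(ts: ExpressionTimeSeries, gene_lengths_bp: np.ndarray) -> ExpressionTimeSeries:
    """TPM-normalize an :class:`ExpressionTimeSeries` of raw counts."""
    if ts.unit == "TPM":
        return ts
    return replace(ts, values=compute_tpm(ts.values, gene_lengths_bp), unit="TPM")


def filter_low_expression(
    perturbed: ExpressionTimeSeries,
    control: ExpressionTimeSeries,
    threshold: float = 100.0,
) -> tuple[ExpressionTimeSeries, ExpressionTimeSeries, list[str]]:
    """Drop genes whose average TPM is below ``threshold`` in *every* condition.

    A gene is kept iff its mean TPM is at least ``threshold`` in the perturbed
    or in the control condition (or both).  Both matrices are subset
    consistently so downstream fold changes stay aligned.
    """
    if perturbed.gene_ids != control.gene_ids:
        raise ValueError("gene lists differ between conditions")
    if perturbed.unit != "TPM" or control.unit != "TPM":
        raise ValueError("filtering operates on TPM values")
    mean_p = perturbed.values.mean(axis=1)
    mean_c = control.values.mean(axis=1)
    keep = np.flatnonzero((mean_p >= threshold) | (mean_c >= threshold))
    kept_ids = [perturbed.gene_ids[i] for i in keep]
    return perturbed.subset_genes(keep), control.subset_genes(keep), kept_ids


def fold_change(
    perturbed: ExpressionTimeSeries,
    control: ExpressionTimeSeries,
    drop_preinduction: bool = True,
) -> tuple[np.ndarray, ExpressionTimeSeries, ExpressionTimeSeries]:
    """Pseudocounted fold change z = (x_perturbed + 1) / (x_control + 1).

    Computed elementwise per matched (time, replicate) column: replicate j of
    the perturbed condition is divided by replicate j of the control at the
    same time index.  With ``drop_preinduction`` the t = 0 column of each
    replicate (sampled before the perturbation) is removed first, from both
    conditions.

    Returns the fold-change matrix along with the (possibly t0-trimmed)
    expression objects actually used.
    """
    if perturbed.values.shape != control.values.shape:
        raise ValueError("condition matrices have mismatched shapes")
    if perturbed.gene_ids != control.gene_ids:
        raise ValueError("gene lists differ between conditions")
    if perturbed.time_min != control.time_min:
        raise ValueError("time grids differ between conditions")
    if drop_preinduction:
        perturbed = perturbed.drop_first_timepoint()
        control = control.drop_first_timepoint()
    z = (perturbed.values + 1.0) / (control.values + 1.0)
    return z, perturbed, control


def standardize(
    z: np.ndarray,
    gene_ids: list[str] | None = None,
    n_replicates: int = 1,
    time_min: list[float] | None = None,
    ddof: int = 0,
) -> FoldChangeState:
    """Standardize each gene's fold change to zero mean and unit variance.

    The mean and standard deviation are pooled across all columns (all time
    points of all replicates), so a single standardization applies to every
    trajectory of the gene.  The population convention (``ddof=0``) is the
    default.  Genes with zero variance carry no dynamic information and are
    dropped with a warning.
    """
    z = np.asarray(z, dtype=float)
    n, cols = z.shape
    if cols % n_replicates:
        raise ValueError("column count not divisible by replicate count")
    if cols // n_replicates < 2:
        raise ValueError("need at least 2 time points per replicate")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    mu = z.mean(axis=1)
    sigma = z.std(axis=1, ddof=ddof)
    keep = np.flatnonzero(sigma > 0)
    if keep.size == 0:
        raise ValueError("all genes are constant in time; nothing to model")
    if keep.size < n:
        dropped = [gene_ids[i] for i in np.flatnonzero(sigma == 0)]
        warnings.warn(
            f"dropping {len(dropped)} constant gene(s): {dropped[:5]}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
    zk = z[keep]
    zbar = (zk - mu[keep, None]) / sigma[keep, None]
    return FoldChangeState(
        zbar=zbar,
        mu=mu[keep],
        sigma=sigma[keep],
        raw_z=zk,
        gene_ids=[gene_ids[i] for i in keep],
        n_timepoints=cols // n_replicates,
        n_replicates=n_replicates,
        time_min=list(time_min) if time_min is not None else [],
    )


def destandardize(state: FoldChangeState, zbar: np.ndarray | None = None) -> np.ndarray:
    """Invert :func:`standardize`: return sigma * zbar + mu per gene."""
    if zbar is None:
        zbar = state.zbar
    return zbar * state.sigma[:, None] + state.mu[:, None]


def background_subtract(
    perturbed: ExpressionTimeSeries, control: ExpressionTimeSeries
) -> np.ndarray:
    """Elementwise perturbed - control TPM, for display and reporting."""
    if perturbed.values.shape != control.values.shape:
        raise ValueError("condition matrices have mismatched shapes")
    return perturbed.values - control.values


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Column headers encode condition:time_min:replicate.
# ---------------------------------------------------------------------------

def read_expression_tsv(path, unit: str = "TPM") -> ExpressionTimeSeries:
    """Read a gene x (time x replicate) matrix from TSV.

    The first column holds gene ids; remaining column headers follow the
    ``condition:time_min:replicate`` convention.  Columns are reordered
    replicate-major with time ascending.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    parsed = []
    for col in df.columns:
        cond, t, rep = str(col).split(":")
        parsed.append((cond, float(t), rep))
    conditions = {c for c, _, _ in parsed}
    if len(conditions) != 1:
        raise ValueError(f"file mixes conditions: {sorted(conditions)}")
    condition = parsed[0][0]
    reps = sorted({rep for _, _, rep in parsed})
    times = sorted({t for _, t, _ in parsed})
    order = []
    for rep in reps:
        for t in times:
            matches = [
                c for c, (cond, tt, rr) in zip(df.columns, parsed)
                if tt == t and rr == rep
            ]
            if len(matches) != 1:
                raise ValueError(f"expected one column for t={t}, rep={rep}")
            order.append(matches[0])
    return ExpressionTimeSeries(
        values=df[order].to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        time_min=times,
        replicate_ids=reps,
        condition=condition,
        unit=unit,
    )


def write_expression_tsv(ts: ExpressionTimeSeries, path) -> None:
    """Write an expression matrix with ``condition:time_min:replicate`` headers."""
    cols = [
        f"{ts.condition}:{t:g}:{rep}"
        for rep in ts.replicate_ids
        for t in ts.time_min
    ]
    pd.DataFrame(ts.values, index=ts.gene_ids, columns=cols).to_csv(
        path, sep="\t", index_label="gene_id"
    )


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column (gene_id, length_bp) table."""
    df = pd.read_csv(path, sep=None, engine="python")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))


def write_fold_change_state(state: FoldChangeState, path) -> None:
    cols = [
        f"z:{state.time_min[t] if state.time_min else t}:{j}"
        for j in range(state.n_replicates)
        for t in range(state.n_timepoints)
    ]
    df = pd.DataFrame(state.zbar, index=state.gene_ids, columns=cols)
    df.insert(0, "sigma", state.sigma)
    df.insert(0, "mu", state.mu)
    df.to_csv(path, sep="\t", index_label="gene_id")
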