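"""Ground-truth-known data generators for every pipeline stage.

The generators emulate the study design this package targets: a perturbed
and a control bacterial culture sampled at ~9 time points in 2 biological
replicates, with bulk RNA-seq counts, where a known subset of genes
responds to the perturbation through a low-rank linear fold-change
dynamical system.  Truth labels (which genes respond, the planted operator
and its spectrum) are returned alongside, so ranking and reconstruction
accuracy can be scored against a known answer.  All generators are pure
functions of their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ExpressionTimeSeries
from .reporters import HillFit, hill

__all__ = [
    "PlantedSystem",
    "planted_system",
    "simulate_linear_system",
    "generate_two_condition_experiment",
    "generate_dose_response",
]


@dataclass
class PlantedSystem:
    """A known linear fold-change system with a planted responsive gene set."""

    K_true: np.ndarray
    spectrum: np.ndarray
    responsive_set: np.ndarray
    z0_true: np.ndarray  # genes x replicates
    noise_sd: float
    seed: int
    latent_modes: np.ndarray | None = field(default=None, repr=False)


def planted_system(
    n_genes: int,
    n_latent: int = 3,
    frac_responsive: float = 0.1,
    n_replicates: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
    eig_range: tuple[float, float] = (0.55, 0.9),
    replicate_jitter: float = 0.1,
) -> PlantedSystem:
    """Construct a stable low-rank operator acting on a responsive gene block.

    The dynamics live in an ``n_latent``-dimensional latent space with real
    eigenvalues drawn in ``eig_range`` (decaying response components); the
    latent modes load only on the planted responsive genes, so rows and
    columns of K outside the responsive set are exactly zero and
    non-responsive genes have neutral dynamics.  Loading rows are rescaled
    so every responsive gene carries a comparable share of the response,
    and replicate initial conditions are the same response up to
    ``replicate_jitter`` relative variation — biological replicates of one
    condition respond in the same direction.
    """
    rng = np.random.default_rng(seed)
    n_resp = max(int(round(frac_responsive * n_genes)), n_latent)
    responsive = np.sort(rng.choice(n_genes, size=n_resp, replace=False))
    eigs = rng.uniform(*eig_range, size=n_latent)
    # loading matrix: responsive genes x latent modes; orthonormal columns,
    # then rows rescaled so no responsive gene is silent
    L = rng.normal(size=(n_resp, n_latent))
    L, _ = np.linalg.qr(L)
    row_norm = np.linalg.norm(L, axis=1)
    target = rng.uniform(0.6, 1.4, size=n_resp) / np.sqrt(n_resp / n_latent)
    L = L * (target / np.maximum(row_norm, 1e-12))[:, None]
    # K_block L = L diag(eigs): the planted spectrum survives row scaling
    K_block = L @ np.diag(eigs) @ np.linalg.pinv(L)
    K = np.zeros((n_genes, n_genes))
    K[np.ix_(responsive, responsive)] = K_block
    # shared response direction; replicates differ only by small jitter
    z0 = np.zeros((n_genes, n_replicates))
    amp_base = rng.uniform(1.0, 2.0, size=n_latent) * rng.choice(
        [-1.0, 1.0], size=n_latent
    )
    amp = amp_base[:, None] * (
        1.0 + replicate_jitter * rng.normal(size=(n_latent, n_replicates))
    )
    z0[responsive] = L @ amp
    return PlantedSystem(
        K_true=K,
        spectrum=np.sort(eigs)[::-1].astype(complex),
        responsive_set=responsive,
        z0_true=z0,
        noise_sd=noise_sd,
        seed=seed,
        latent_modes=L,
    )


def simulate_linear_system(
    system: PlantedSystem, m: int, r_reps: int | None = None
) -> np.ndarray:
    """Roll the planted system forward: z_t = K^t z0 (+ Gaussian noise).

    Returns a (n_genes, m * r_reps) matrix with replicate-major column
    blocks, matching the layout of the standardized fold-change state.
    """
    if r_reps is None:
        r_reps = system.z0_true.shape[1]
    rng = np.random.default_rng([system.seed, 1])
    blocks = []
    for j in range(r_reps):
        x = system.z0_true[:, j % system.z0_true.shape[1]].copy()
        cols = []
        for _ in range(m):
            cols.append(x.copy())
            x = system.K_true @ x
        block = np.column_stack(cols)
        if system.noise_sd > 0:
            block = block + rng.normal(scale=system.noise_sd, size=block.shape)
        blocks.append(block)
    return np.hstack(blocks)


def generate_two_condition_experiment(
    n_genes: int = 624,
    m: int = 9,
    r_reps: int = 2,
    frac_responsive: float = 0.1,
    effect_size: float = 2.0,
    dispersion: float = 0.05,
    depth: int = 2_000_000,
    seed: int = 0,
) -> dict:
    """Paired perturbed/control count matrices with planted responders.

    Control counts are negative-binomial draws around gene-specific
    baseline abundances (log-normal across genes, centered so most genes
    clear a TPM-100 filter at the default depth).  Perturbed counts
    multiply the baseline of each responsive gene by exp(trajectory), where
    trajectories come from a planted stable low-rank linear system whose
    log-fold-change amplitude is set by ``effect_size``.  Non-responsive
    genes share the same baseline in both conditions, so their fold change
    is statistically neutral.

    Parameters
    ----------
    effect_size
        Peak |log fold change| scale of responsive genes (2.0 emulates the
        strong responders the modeled perturbation elicits).
    dispersion
        Negative-binomial dispersion (var = mu + dispersion * mu^2).

    Returns
    -------
    dict
        ``perturbed``/``control`` (:class:`ExpressionTimeSeries`, counts),
        ``gene_lengths_bp``, ``responsive`` (bool truth labels),
        ``system`` (the planted operator) and ``log_fc`` (planted
        log-fold-change trajectories, genes x (m * r_reps)).
    """
    rng = np.random.default_rng([seed, 0])
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    lengths = rng.uniform(500, 3000, size=n_genes)
    # baseline TPM-scale abundances, log-normal across genes
    base_tpm = rng.lognormal(mean=np.log(600.0), sigma=0.9, size=n_genes)

    system = planted_system(
        n_genes,
        frac_responsive=frac_responsive,
        n_replicates=r_reps,
        seed=seed + 1,
    )
    traj = simulate_linear_system(system, m, r_reps)
    # scale so the median responsive gene peaks at |log fold change| =
    # effect_size; individual genes keep their heterogeneous amplitudes
    if system.responsive_set.size and effect_size > 0:
        peaks = np.abs(traj[system.responsive_set]).max(axis=1)
        log_fc = traj * (effect_size / np.median(peaks))
        # balance transcript mass within the responsive set per column, so
        # the compositional TPM normalization leaves non-responsive genes'
        # fold change neutral (TPM is relative: unbalanced perturbations
        # would bleed a coherent artifact trend into every other gene)
        resp = system.responsive_set
        base_resp = base_tpm[resp]
        mass = base_resp @ np.exp(log_fc[resp])
        log_fc[resp] += np.log(base_resp.sum() / mass)[None, :]
    else:
        log_fc = np.zeros_like(traj)

    def draw_counts(mean_tpm_matrix: np.ndarray, stream: int) -> np.ndarray:
        nb_rng = np.random.default_rng([seed, 2, stream])
        # expected read count proportional to abundance x length at fixed depth
        rate = mean_tpm_matrix * lengths[:, None]
        mu = depth * rate / rate.sum(axis=0)
        if dispersion > 0:
            # NB via gamma-Poisson mixture: shape = 1/dispersion
            shape = 1.0 / dispersion
            lam = nb_rng.gamma(shape, mu / shape)
        else:
            lam = mu
        return nb_rng.poisson(lam).astype(float)

    control_mean = np.tile(base_tpm[:, None], (1, m * r_reps))
    perturbed_mean = control_mean * np.exp(log_fc)
    time_min = [float(10 * (t + 1)) for t in range(m)]
    rep_ids = [f"rep{j + 1}" for j in range(r_reps)]
    control = ExpressionTimeSeries(
        values=draw_counts(control_mean, 0),
        gene_ids=gene_ids,
        time_min=time_min,
        replicate_ids=rep_ids,
        condition="control",
        unit="counts",
    )
    perturbed = ExpressionTimeSeries(
        values=draw_counts(perturbed_mean, 1),
        gene_ids=gene_ids,
        time_min=time_min,
        replicate_ids=rep_ids,
        condition="perturbed",
        unit="counts",
    )
    responsive = np.zeros(n_genes, dtype=bool)
    responsive[system.responsive_set] = True
    return {
        "perturbed": perturbed,
        "control": control,
        "gene_lengths_bp": lengths,
        "responsive": responsive,
        "system": system,
        "log_fc": log_fc,
    }


def generate_dose_response(
    fit: HillFit,
    concentrations: np.ndarray,
    noise_cv: float = 0.05,
    reps: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Noisy Hill-shaped dose-response draws, shape (reps, n_concentrations).

    Multiplicative Gaussian noise with coefficient of variation
    ``noise_cv`` emulates well-to-well variation; ``noise_cv=0`` returns
    exact Hill values in every replicate.
    """
    c = np.asarray(concentrations, dtype=float)
    y = hill(c, fit.y_min, fit.y_max, fit.K_M, fit.n)
    rng = np.random.default_rng(seed)
    noise = rng.normal(1.0, noise_cv, size=(reps, c.size)) if noise_cv > 0 else np.ones((reps, c.size))
    return y[None, :] * noise
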