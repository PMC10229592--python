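"""End-to-end orchestration: preprocess -> DMD -> rank -> reconstruct -> select.

A single :class:`RunConfig` drives the whole analysis reproducibly; every
stochastic stage takes an explicit seed and the run manifest records
versions, seeds, parameters, and per-stage summary statistics.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import dmd as dmd_mod
from . import observability as obs_mod
from . import preprocess as pre_mod
from . import selection as sel_mod

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    perturbed_path: str | None = None
    control_path: str | None = None
    lengths_path: str | None = None
    output_dir: str = "obsight_run"
    tpm_threshold: float = 100.0
    drop_preinduction: bool = True
    rank_r: int = 10
    horizon: int | None = None  # default: number of modeled time points
    n_ics: int | None = None  # default: number of kept genes
    seed: int = 0
    selection_strategy: str = "corr"  # {top, corr, search}
    selection_k: int = 15
    corr_threshold: float = 0.5
    search_trials: int = 1000
    recon_T: int = 8
    rank_normalized: bool = False
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = unknown
        return cfg


def run_pipeline(
    config: RunConfig,
    perturbed: pre_mod.ExpressionTimeSeries | None = None,
    control: pre_mod.ExpressionTimeSeries | None = None,
    gene_lengths: np.ndarray | None = None,
) -> dict:
    """Execute the full analysis and write all stage outputs plus a manifest.

    Inputs may be passed in memory or read from the paths in ``config``.
    Returns the manifest dictionary.  Any stage failure raises with the
    stage name; outputs written before the failure are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "obsight_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "stages": {},
    }
    stage = "load"
    try:
        if perturbed is None:
            perturbed = pre_mod.read_expression_tsv(
                config.perturbed_path,
                unit="counts" if config.lengths_path else "TPM",
            )
        if control is None:
            control = pre_mod.read_expression_tsv(
                config.control_path,
                unit="counts" if config.lengths_path else "TPM",
            )
        if gene_lengths is None and config.lengths_path:
            lengths = pre_mod.read_gene_lengths(config.lengths_path)
            gene_lengths = lengths.reindex(perturbed.gene_ids).to_numpy()

        stage = "preprocess"
        if perturbed.unit == "counts":
            if gene_lengths is None:
                raise ValueError("counts input requires gene lengths for TPM")
            perturbed = pre_mod.counts_to_tpm(perturbed, gene_lengths)
            control = pre_mod.counts_to_tpm(control, gene_lengths)
        perturbed, control, kept = pre_mod.filter_low_expression(
            perturbed, control, config.tpm_threshold
        )
        z, perturbed_used, control_used = pre_mod.fold_change(
            perturbed, control, drop_preinduction=config.drop_preinduction
        )
        state = pre_mod.standardize(
            z,
            gene_ids=perturbed_used.gene_ids,
            n_replicates=perturbed_used.n_replicates,
            time_min=perturbed_used.time_min,
        )
        pre_mod.write_expression_tsv(perturbed, out / "perturbed_tpm_filtered.tsv")
        pre_mod.write_expression_tsv(control, out / "control_tpm_filtered.tsv")
        pre_mod.write_fold_change_state(state, out / "fold_change_state.tsv")
        (out / "kept_genes.txt").write_text("\n".join(state.gene_ids) + "\n")
        manifest["stages"]["preprocess"] = {
            "n_genes_input": len(kept),
            "n_genes_modeled": state.n_genes,
            "n_timepoints": state.n_timepoints,
            "n_replicates": state.n_replicates,
            "tpm_threshold": config.tpm_threshold,
        }

        stage = "dmd"
        model = dmd_mod.fit_from_state(state, config.rank_r)
        r2 = dmd_mod.predict_state(model, state)
        model.save(out / "dmd_model.json")
        dmd_mod.mode_table(model).to_csv(out / "modes.tsv", sep="\t", index=False)
        n_unstable = int(np.sum(np.abs(model.eigenvalues) > 1 + 1e-9))
        manifest["stages"]["dmd"] = {
            "rank_r": config.rank_r,
            "r2_full_horizon": r2,
            "n_unstable_modes": n_unstable,
        }

        stage = "rank"
        horizon = config.horizon if config.horizon is not None else state.n_timepoints
        weights = obs_mod.rank_genes(
            model,
            state.initial_conditions(),
            gene_sigma=state.sigma,
            gene_ids=state.gene_ids,
            horizon_m=horizon,
            n_ics=config.n_ics,
            seed=config.seed,
        )
        obs_mod.weight_table(weights).to_csv(out / "gene_weights.tsv", sep="\t", index=False)
        np.savetxt(out / "gram_spectrum.tsv", weights.gram_eigenvalues, delimiter="\t")
        manifest["stages"]["rank"] = {
            "horizon_m": horizon,
            "n_synthetic_ics": weights.n_synthetic_ics,
            "seed": config.seed,
            "gram_spectrum_head": weights.gram_eigenvalues[:5].tolist(),
        }

        stage = "select"
        K = model.full_operator()
        z0 = state.initial_conditions().mean(axis=1)
        if config.selection_strategy == "top":
            chosen = sel_mod.select_top_k(
                weights, state.zbar, k=config.selection_k,
                normalized=config.rank_normalized,
            )
        elif config.selection_strategy == "corr":
            chosen = sel_mod.select_correlation_threshold(
                weights, state.zbar, threshold=config.corr_threshold,
                k=config.selection_k, normalized=config.rank_normalized,
            )
        elif config.selection_strategy == "search":
            trials = sel_mod.random_set_search(
                weights, state.zbar, K, z0, k=config.selection_k,
                trials=config.search_trials, T=config.recon_T, seed=config.seed,
                normalized=config.rank_normalized,
            )
            trials.to_csv(out / "search_trials.tsv", sep="\t", index=False)
            best_idx = trials["recon_r2"].idxmax()
            best_genes = [
                state.gene_ids.index(g) if g in state.gene_ids else int(g)
                for g in trials.loc[best_idx, "genes"].split(",")
            ]
            chosen = sel_mod.evaluate_gene_set(
                weights, state.zbar, K, z0,
                np.asarray(best_genes), T=config.recon_T, strategy="random_search",
            )
        else:
            raise ValueError(f"unknown selection strategy {config.selection_strategy!r}")
        evaluated = sel_mod.evaluate_gene_set(
            weights, state.zbar, K, z0, chosen.gene_index,
            T=config.recon_T, strategy=chosen.strategy,
        )
        with open(out / "selected_genes.tsv", "w") as fh:
            fh.write("gene_id\trank_percentile\n")
            for g, p in zip(evaluated.gene_ids, evaluated.rank_percentiles):
                fh.write(f"{g}\t{p:.2f}\n")
        manifest["stages"]["select"] = {
            "strategy": evaluated.strategy,
            "k": len(evaluated.gene_ids),
            "C_metric": evaluated.C_metric,
            "recon_r2_at_T": evaluated.recon_r2,
            "recon_T": config.recon_T,
            "selected": list(map(str, evaluated.gene_ids)),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
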