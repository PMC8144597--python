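"""End-to-end survival analysis: studbooks in, pooled estimate tables out.

Composes the full workflow: truncation and exclusion filters, offspring
table assembly, independent litter sampling (five replicates by default),
within-species standardization, optional restriction to G2+ offspring
(both parents captive-born), all-subsets AICc selection with conditional
averaging per replicate, pooling across replicates, species-level
random-slope models on a representative replicate, and Pagel's lambda on
the species-level effects.

Every stage writes its counts and seeds into a run manifest so each number
in the output tables is traceable; re-running with the same configuration
and seed produces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import dataset, pedigree, phylo, selection
from .dataset import PREDICTORS
from .glmm import (BinomialMixedModel, ConvergenceError, fit_random_slope,
                   residual_diagnostics, variance_inflation)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "extended_dataset_run"]

#: predictors given random-slope models per analysis mode (the G2+ run
#: targets the generation effects, which is where first- vs
#: multi-generation differences appear)
SLOPE_PREDICTORS = {
    "all_offspring": PREDICTORS,
    "g2plus": ("dam_generation", "sire_generation"),
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    studbook_paths: tuple = ()
    species_config_path: Optional[str] = None
    tree_path: Optional[str] = None
    out_dir: Optional[str] = None
    n_replicates: int = 5
    base_seed: int = 0
    delta_cutoff: float = 2.0
    mode: str = "both"  # all_offspring | g2plus | both
    # programmatic alternatives to the file inputs:
    pedigree: Optional[pedigree.Pedigree] = None
    species_configs: Optional[dict] = None
    tree: object = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.delta_cutoff <= 0:
            raise ValueError("delta_cutoff must be > 0")
        if self.mode not in ("all_offspring", "g2plus", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def modes(self) -> tuple[str, ...]:
        return (("all_offspring", "g2plus") if self.mode == "both"
                else (self.mode,))


@dataclass
class PipelineResult:
    """Bundle of everything a run produced."""

    pooled: dict  # mode -> pooled estimate DataFrame (Table-2 layout)
    averaged: dict  # mode -> list of per-replicate AveragedEstimates
    species_effects: dict  # mode -> species x predictor DataFrame
    lambda_tables: dict  # mode -> DataFrame of lambda fits
    diagnostics: dict  # mode -> DiagnosticsReport
    vif: Optional[pd.Series]
    manifest: dict
    representative: dict = field(default_factory=dict)  # mode -> index


def _load_inputs(cfg: RunConfig):
    if cfg.pedigree is not None:
        ped = cfg.pedigree
    else:
        if not cfg.studbook_paths:
            raise ValueError("no studbook input (paths or pedigree)")
        records = []
        for path in cfg.studbook_paths:
            records.extend(
                pedigree.read_studbook(path).records.values())
        ped = pedigree.Pedigree(records)
    if cfg.species_configs is not None:
        configs = cfg.species_configs
    elif cfg.species_config_path:
        configs = dataset.load_species_configs(cfg.species_config_path)
    else:
        raise ValueError("no species configuration provided")
    tree = cfg.tree
    if tree is None and cfg.tree_path:
        tree = phylo.read_newick(cfg.tree_path)
    return ped, configs, tree


def _representative_index(averaged, pooled) -> int:
    """Replicate whose averaged estimates sit closest to the pooled means."""
    best, best_dev = 0, np.inf
    for r, avg in enumerate(averaged):
        joined = avg.table["estimate"].reindex(pooled.index)
        dev = float((joined - pooled["mean_estimate"]).abs().sum())
        if np.isfinite(dev) and dev < best_dev:
            best, best_dev = r, dev
    return best


def _species_effect_matrix(std_table, predictors, manifest_notes):
    """Random-slope fits per predictor -> species x predictor matrix."""
    species = sorted(std_table.data["species"].unique())
    mat = pd.DataFrame(index=species, columns=list(predictors), dtype=float)
    for pred in predictors:
        try:
            res = fit_random_slope(pred, std_table)
        except ConvergenceError as exc:
            manifest_notes.append(
                f"random-slope model for {pred} not fitted: {exc}")
            continue
        eff = res.species_effects(pred)
        mat.loc[eff.index, pred] = eff.to_numpy()
    return mat


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis; returns (and optionally writes) results."""
    stage = "load_inputs"
    manifest: dict = {"seeds": {"base_seed": cfg.base_seed},
                      "notes": [], "stages": {}}
    try:
        ped, configs, tree = _load_inputs(cfg)
        stage = "build_table"
        table, build_manifest = dataset.build_offspring_table(ped, configs)
        manifest["stages"]["build"] = build_manifest
        if len(table) == 0:
            raise ValueError("no analysis rows after exclusions")

        stage = "litter_sampling"
        replicates = dataset.make_replicates(
            table, cfg.n_replicates, cfg.base_seed)
        manifest["seeds"]["replicates"] = [
            cfg.base_seed + r for r in range(1, cfg.n_replicates + 1)]

        pooled, averaged_all, species_eff, lambda_tabs = {}, {}, {}, {}
        diagnostics, representative = {}, {}
        vif_series = None

        for mode in cfg.modes:
            stage = f"{mode}:standardize"
            std_reps = []
            sizes = []
            for rep in replicates:
                std = dataset.standardize_within_species(rep)
                if mode == "g2plus":
                    std = dataset.StandardizedTable(
                        data=dataset.subset_g2plus(std.data),
                        scaling=std.scaling)
                std_reps.append(std)
                sizes.append(len(std.data))
            manifest["stages"][f"{mode}:replicate_sizes"] = sizes

            stage = f"{mode}:model_selection"
            averaged = []
            for std in std_reps:
                ms = selection.dredge(std)
                averaged.append(
                    selection.retain_and_average(ms, cfg.delta_cutoff))
            pooled_tab = selection.pool_replicates(averaged)
            pooled[mode] = pooled_tab
            averaged_all[mode] = averaged

            stage = f"{mode}:representative"
            rep_idx = _representative_index(averaged, pooled_tab)
            representative[mode] = rep_idx
            rep_std = std_reps[rep_idx]

            stage = f"{mode}:diagnostics"
            global_fit = BinomialMixedModel.from_table(rep_std).fit()
            diag = residual_diagnostics(
                global_fit, n_sims=250, seed=cfg.base_seed + 1000)
            vif_series = variance_inflation(rep_std)
            diag.vif = vif_series
            diagnostics[mode] = diag

            stage = f"{mode}:random_slopes"
            species_eff[mode] = _species_effect_matrix(
                rep_std, SLOPE_PREDICTORS[mode], manifest["notes"])

            stage = f"{mode}:phylogenetic_signal"
            if tree is not None:
                rows = phylo.signal_for_random_slopes(
                    species_eff[mode], tree)
                surv = rep_std.data.groupby("species")["survival"].mean()
                try:
                    res = phylo.fit_lambda(tree, surv)
                    row = {"lambda": res.lambda_hat,
                           "loglik": res.loglik_ml, "lrt": res.lrt_stat,
                           "p_value": res.p_value,
                           "note": "" if res.identifiable
                           else "unidentifiable"}
                except (ValueError, np.linalg.LinAlgError) as exc:
                    row = {"lambda": np.nan, "loglik": np.nan,
                           "lrt": np.nan, "p_value": np.nan,
                           "note": f"not estimable: {exc}"}
                extra = pd.DataFrame([row], index=["mean_survival"])
                extra.index.name = "predictor"
                lambda_tabs[mode] = pd.concat([extra, rows])
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted at stage {stage!r}: {exc}\n"
            f"manifest so far: {json.dumps(manifest, default=str)}"
        ) from exc

    manifest["stages"]["significant"] = {
        mode: sorted(pooled[mode].index[pooled[mode]["significant"]])
        for mode in pooled}
    result = PipelineResult(
        pooled=pooled, averaged=averaged_all, species_effects=species_eff,
        lambda_tables=lambda_tabs, diagnostics=diagnostics,
        vif=vif_series, manifest=manifest, representative=representative)
    if cfg.out_dir:
        _write_outputs(result, cfg)
    return result


def extended_dataset_run(cfg: RunConfig) -> PipelineResult:
    """Sensitivity analysis without litter sampling (all offspring kept).

    Litter-mates are not statistically independent, so this run does not
    account for that dependence; it serves as a qualitative check that
    litter sampling did not bias the main analysis.  Single dataset, so no
    pooling: the 'pooled' table is the single averaged result.
    """
    stage = "load_inputs"
    manifest: dict = {"seeds": {"base_seed": cfg.base_seed},
                      "label": "extended_no_litter_sampling",
                      "notes": [], "stages": {}}
    try:
        ped, configs, tree = _load_inputs(cfg)
        stage = "build_table"
        table, build_manifest = dataset.build_offspring_table(ped, configs)
        manifest["stages"]["build"] = build_manifest
        pooled, averaged_all = {}, {}
        for mode in cfg.modes:
            stage = f"{mode}:model_selection"
            std = dataset.standardize_within_species(table)
            if mode == "g2plus":
                std = dataset.StandardizedTable(
                    data=dataset.subset_g2plus(std.data),
                    scaling=std.scaling)
            manifest["stages"][f"{mode}:n_rows"] = len(std.data)
            ms = selection.dredge(std)
            avg = selection.retain_and_average(ms, cfg.delta_cutoff)
            averaged_all[mode] = [avg]
            pooled[mode] = selection.pool_replicates([avg])
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted at stage {stage!r}: {exc}\n"
            f"manifest so far: {json.dumps(manifest, default=str)}"
        ) from exc
    result = PipelineResult(
        pooled=pooled, averaged=averaged_all, species_effects={},
        lambda_tables={}, diagnostics={}, vif=None, manifest=manifest)
    if cfg.out_dir:
        _write_outputs(result, cfg, prefix="extended_")
    return result


def _write_outputs(result: PipelineResult, cfg: RunConfig,
                   prefix: str = "") -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mode, tab in result.pooled.items():
        tab.to_csv(out / f"{prefix}pooled_estimates_{mode}.csv")
    for mode, mat in result.species_effects.items():
        mat.to_csv(out / f"{prefix}species_effects_{mode}.csv")
    for mode, tab in result.lambda_tables.items():
        tab.to_csv(out / f"{prefix}lambda_{mode}.csv")
    diag = {mode: d.to_dict() for mode, d in result.diagnostics.items()}
    with open(out / f"{prefix}diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2, sort_keys=True)
    manifest = dict(result.manifest)
    manifest["representative_replicate"] = result.representative
    with open(out / f"{prefix}manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
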