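"""From validated pedigree to analysis table.

Implements the dataset-construction rules of the survival analysis:
truncation of the most recent 364 days, survival-to-maturity labelling,
exclusion filters (too young, hybrid, wild-born / released, unknown
parents), assembly of the seven per-offspring predictors, litter
identification, independent one-per-litter sampling, within-species
standardization and the G2+ (no wild-born parent) subset.

Excluded individuals are removed from the *analysis table only*: they stay
in the pedigree as ancestors, otherwise inbreeding and generation values of
retained offspring would be corrupted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree, PedigreeMetrics, compute_metrics

__all__ = [
    "PREDICTORS",
    "SpeciesConfig",
    "StandardizedTable",
    "ExclusionResult",
    "EXCLUDE_TOO_YOUNG",
    "truncate_recent",
    "label_survival",
    "apply_exclusions",
    "assemble_offspring_table",
    "sample_one_per_litter",
    "make_replicates",
    "standardize_within_species",
    "subset_g2plus",
    "build_offspring_table",
    "load_species_configs",
]

#: the seven fixed-effect predictors of the global survival model
PREDICTORS = (
    "dam_generation",
    "sire_generation",
    "dam_age",
    "sire_age",
    "dam_f",
    "sire_f",
    "offspring_f",
)

#: sentinel label for individuals too young to have reached maturity
EXCLUDE_TOO_YOUNG = "EXCLUDE_TOO_YOUNG"

#: days truncated from the end of the studbook (recent deaths may not yet
#: have been entered)
TRUNCATION_DAYS = 364


@dataclass
class SpeciesConfig:
    """Per-species analysis configuration.

    Maturity ages are in days (sex-specific); ``litter_rule`` is
    ``"same_day"`` for mammals (litter = same dam, same day) or
    ``"same_year"`` for clutch layers (same dam, same calendar year).
    """

    species: str
    maturity_female_days: int
    maturity_male_days: int
    litter_rule: str = "same_day"
    first_record_year: Optional[int] = None

    def __post_init__(self):
        if self.maturity_female_days <= 0 or self.maturity_male_days <= 0:
            raise ValueError("maturity ages must be positive (days)")
        if self.litter_rule not in ("same_day", "same_year"):
            raise ValueError("litter_rule must be same_day or same_year")

    def maturity_days(self, sex: str) -> int:
        if sex == "female":
            return self.maturity_female_days
        if sex == "male":
            return self.maturity_male_days
        # unknown sex: the shorter of the two maturity ages
        return min(self.maturity_female_days, self.maturity_male_days)


def load_species_configs(path) -> dict[str, SpeciesConfig]:
    """Read the YAML species-configuration file (see README for schema)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, entry in raw.items():
        out[name] = SpeciesConfig(
            species=name,
            maturity_female_days=int(entry["maturity_female_days"]),
            maturity_male_days=int(entry["maturity_male_days"]),
            litter_rule=entry.get("litter_rule", "same_day"),
            first_record_year=entry.get("first_record_year"),
        )
    return out


# ---------------------------------------------------------------------------
# truncation and survival labels
# ---------------------------------------------------------------------------

def truncate_recent(ped: Pedigree) -> tuple[Pedigree, date]:
    """Drop individuals born in the last 364 days of the studbook.

    Returns the truncated pedigree and the new reference ("current") date,
    the original latest record date minus 364 days.  All downstream age
    arithmetic uses the returned cutoff.
    """
    if len(ped) == 0:
        return ped, date.today()
    cutoff = ped.current_date - timedelta(days=TRUNCATION_DAYS)
    kept = [r for r in ped.records.values() if r.birth_date <= cutoff]
    return Pedigree(kept, wild_ancestry=ped.wild_ancestry), cutoff


def label_survival(rec, cfg: SpeciesConfig, cutoff_date: date):
    """Survival-to-maturity label: 1, 0 or :data:`EXCLUDE_TOO_YOUNG`.

    An individual born within its maturity age of the cutoff date has not
    had the opportunity to reach reproductive maturity and is excluded
    regardless of whether it has died.  Otherwise the label is 1 if it
    survived to the sex-appropriate maturity age (unknown sex: the shorter
    of the two), 0 if it died younger.
    """
    if rec.birth_date is None:  # pragma: no cover - read_studbook enforces
        raise ValueError(f"individual {rec.id!r} has no birth date")
    maturity = cfg.maturity_days(rec.sex)
    if (cutoff_date - rec.birth_date).days < maturity:
        return EXCLUDE_TOO_YOUNG
    age_at_death = rec.age_at_death_days()
    if age_at_death is None:
        return 1
    return 1 if age_at_death >= maturity else 0


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

@dataclass
class ExclusionResult:
    """Retained analysis offspring plus a tally per exclusion reason.

    ``retained`` holds ids eligible as analysis rows; the pedigree itself is
    untouched (ancestors must remain available for f and G).
    """

    retained: list[str]
    survival: dict[str, int]
    tally: dict[str, int] = field(default_factory=dict)


def apply_exclusions(ped: Pedigree, configs: dict[str, SpeciesConfig],
                     cutoff_date: date) -> ExclusionResult:
    """Apply the analysis exclusion filters, in order, counting each reason.

    1. too young to have reached maturity by the cutoff,
    2. flagged hybrids,
    3. wild-born offspring, and those released to the wild before maturity,
    4. offspring with an unknown sire or dam (or both).

    Idempotent: re-applying to the retained set removes nothing further.
    """
    tally = {"too_young": 0, "hybrid": 0, "wild_or_released": 0,
             "unknown_parent": 0}
    retained: list[str] = []
    survival: dict[str, int] = {}
    for iid in ped.topological_order():
        rec = ped[iid]
        cfg = configs[rec.species]
        label = label_survival(rec, cfg, cutoff_date)
        if label == EXCLUDE_TOO_YOUNG:
            tally["too_young"] += 1
            continue
        if rec.hybrid:
            tally["hybrid"] += 1
            continue
        released_young = (
            rec.release_date is not None
            and (rec.release_date - rec.birth_date).days
            < cfg.maturity_days(rec.sex))
        if rec.origin == "wild" or released_young:
            tally["wild_or_released"] += 1
            continue
        if rec.sire_id is None or rec.dam_id is None:
            tally["unknown_parent"] += 1
            continue
        retained.append(iid)
        survival[iid] = label
    return ExclusionResult(retained=retained, survival=survival, tally=tally)


# ---------------------------------------------------------------------------
# analysis table
# ---------------------------------------------------------------------------

def _litter_key(rec, cfg: SpeciesConfig) -> str:
    if cfg.litter_rule == "same_day":
        return f"{rec.species}|{rec.dam_id}|{rec.birth_date.isoformat()}"
    return f"{rec.species}|{rec.dam_id}|{rec.birth_date.year}"


def assemble_offspring_table(ped: Pedigree, metrics: PedigreeMetrics,
                             excl: ExclusionResult,
                             configs: dict[str, SpeciesConfig],
                             ) -> pd.DataFrame:
    """One analysis row per retained offspring.

    Predictors: parental inbreeding and captive generations from the full
    (untruncated-ancestry) pedigree metrics, parental ages at the
    offspring's birth in days, offspring inbreeding.  A record whose parent
    age comes out non-positive is rejected with a diagnostic rather than
    silently kept.
    """
    rows = []
    for iid in excl.retained:
        rec = ped[iid]
        cfg = configs[rec.species]
        sire = ped[rec.sire_id]
        dam = ped[rec.dam_id]
        dam_age = (rec.birth_date - dam.birth_date).days
        sire_age = (rec.birth_date - sire.birth_date).days
        if dam_age <= 0 or sire_age <= 0:
            warnings.warn(
                f"rejecting offspring {iid!r}: non-positive parental age "
                f"(dam {dam_age} d, sire {sire_age} d)")
            continue
        rows.append({
            "offspring_id": iid,
            "species": rec.species,
            "survival": excl.survival[iid],
            "dam_generation": metrics.generation[rec.dam_id],
            "sire_generation": metrics.generation[rec.sire_id],
            "dam_age": float(dam_age),
            "sire_age": float(sire_age),
            "dam_f": metrics.f[rec.dam_id],
            "sire_f": metrics.f[rec.sire_id],
            "offspring_f": metrics.f[iid],
            "birth_program": rec.birth_program,
            "birth_year": rec.birth_date.year,
            "litter_key": _litter_key(rec, cfg),
        })
    return pd.DataFrame(rows)


def build_offspring_table(ped: Pedigree, configs: dict[str, SpeciesConfig],
                          ) -> tuple[pd.DataFrame, dict]:
    """Full construction: truncate, label, exclude, assemble.

    Metrics (f, G) are computed on the *untruncated* pedigree so that
    ancestors removed by filters still contribute pedigree paths.  Returns
    the analysis table and a manifest of counts at each stage.
    """
    metrics = compute_metrics(ped, ne=False)
    truncated, cutoff = truncate_recent(ped)
    excl = apply_exclusions(truncated, configs, cutoff)
    table = assemble_offspring_table(ped, metrics, excl, configs)
    manifest = {
        "n_input": len(ped),
        "n_after_truncation": len(truncated),
        "cutoff_date": cutoff.isoformat(),
        "exclusions": excl.tally,
        "n_analysis_rows": len(table),
    }
    return table, manifest


# ---------------------------------------------------------------------------
# litter sampling
# ---------------------------------------------------------------------------

def sample_one_per_litter(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Select one offspring per litter, uniformly at random.

    Litter-mates (same ``litter_key``) are statistically non-independent;
    sampling one breaks the dependence.  Singleton litters are always
    retained.  Deterministic under ``seed`` and invariant to row order.
    """
    if len(table) == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    ordered = table.sort_values(["litter_key", "offspring_id"],
                                kind="mergesort")
    keep_idx = []
    for _, grp in ordered.groupby("litter_key", sort=True):
        keep_idx.append(grp.index[rng.integers(0, len(grp))])
    return table.loc[sorted(keep_idx)].copy()


def make_replicates(table: pd.DataFrame, n_replicates: int = 5,
                    base_seed: int = 0) -> list[pd.DataFrame]:
    """``n_replicates`` independent one-per-litter samples.

    Replicate r uses the derived seed ``base_seed + r`` (r = 1..n); the
    analyses of the replicates are pooled downstream.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [sample_one_per_litter(table, base_seed + r)
            for r in range(1, n_replicates + 1)]


# ---------------------------------------------------------------------------
# standardization and subsets
# ---------------------------------------------------------------------------

@dataclass
class StandardizedTable:
    """Analysis table with predictors centered/scaled within species.

    ``data`` carries the standardized predictors plus the raw values under
    ``<name>_raw``; ``scaling[(species, predictor)] = (mean, sd)`` allows
    exact back-transformation (sd stored as 1.0 for a constant column,
    which is centered only).
    """

    data: pd.DataFrame
    scaling: dict[tuple[str, str], tuple[float, float]]

    def back_transform(self, predictor: str) -> pd.Series:
        mean = self.data["species"].map(
            {s: m for (s, p), (m, _) in self.scaling.items()
             if p == predictor})
        sd = self.data["species"].map(
            {s: sd_ for (s, p), (_, sd_) in self.scaling.items()
             if p == predictor})
        return self.data[predictor] * sd + mean


def standardize_within_species(table: pd.DataFrame) -> StandardizedTable:
    """Center and scale the seven predictors within each species.

    Uses the sample standard deviation (n-1 denominator).  A predictor that
    is constant within a species (e.g. parental f identically 0 in a
    species with no pedigree inbreeding) is centered to zero and left
    unscaled, with a warning - dropping the species would silently change
    the model.
    """
    data = table.copy()
    scaling: dict[tuple[str, str], tuple[float, float]] = {}
    for pred in PREDICTORS:
        data[pred + "_raw"] = data[pred].astype(float)
    for species, grp in table.groupby("species", sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"species {species!r} has fewer than 2 analysis rows")
        for pred in PREDICTORS:
            x = grp[pred].astype(float)
            mean = float(x.mean())
            sd = float(x.std(ddof=1))
            if sd == 0.0 or not np.isfinite(sd):
                warnings.warn(
                    f"predictor {pred!r} constant within species "
                    f"{species!r}; centered only")
                sd_use = 1.0
            else:
                sd_use = sd
            scaling[(species, pred)] = (mean, sd_use)
            data.loc[grp.index, pred] = (x - mean) / sd_use
    return StandardizedTable(data=data, scaling=scaling)


def subset_g2plus(table: pd.DataFrame) -> pd.DataFrame:
    """Retain offspring both of whose parents are captive-born (G >= 1).

    Works on raw parental generations (``*_raw`` columns if present, i.e.
    after standardization, else the plain columns).
    """
    dam = table.get("dam_generation_raw", table["dam_generation"])
    sire = table.get("sire_generation_raw", table["sire_generation"])
    return table[(dam >= 1.0) & (sire >= 1.0)].copy()


def write_analysis_table(table: pd.DataFrame, path,
                         manifest: Optional[dict] = None) -> None:
    """CSV writer for the analysis table (+ JSON exclusion-tally sidecar)."""
    table.to_csv(path, index=False)
    if manifest is not None:
        with open(str(path) + ".manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def read_analysis_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
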