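"""Synthetic studbooks, species trees and toy pedigrees with known truth.

The real studbooks behind multi-species captive-breeding analyses are held
by zoo associations, so every stage of this package is exercised against a
forward-in-time breeding-program simulator with fully known generative
parameters:

* multiple species with wild founders and continuing wild intakes,
* yearly pairing and litters/clutches (same-day litters for mammal-style
  species, same-year clutches for reptile-style species),
* pedigree bookkeeping (inbreeding accumulates; generations in captivity
  follow the parental-mean-plus-one rule),
* Bernoulli survival to reproductive maturity whose logit is linear in the
  seven standardized predictors, with species-level random intercepts and
  slopes plus region-within-species and year-within-species effects.

Default generative parameters mirror the captive-breeding setting the
package targets: 15 species (three clutch-laying), pooled-analysis-scale
effect sizes (strong negative offspring-inbreeding effect, small
generation effects, opposite-signed parental-age effects) and modest
random-effect standard deviations.

Because the predictors (f, G, parental age) emerge from the pedigree
dynamics, their moments are not known a priori.  To make the true
coefficients interpretable per 1 SD - the scale on which the analysis
reports estimates - the simulator runs twice: a calibration pass measures
realized per-species moments, then the definitive pass re-runs the same
forward process standardizing against those frozen moments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import PREDICTORS, SpeciesConfig
from .pedigree import IndividualRecord, Pedigree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_studbook",
    "simulate_species_tree",
    "simulate_glmm_table",
    "toy_fixtures",
    "toy_configs",
]

#: paper-scale default coefficients (logit, per 1 SD within species)
DEFAULT_BETA = {
    "dam_generation": 0.005,
    "sire_generation": 0.022,
    "dam_age": -0.062,
    "sire_age": 0.058,
    "dam_f": 0.002,
    "sire_f": 0.009,
    "offspring_f": -0.163,
}

DEFAULT_PROGRAMS = ("Africa", "Australasia", "Europe", "North America")


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic studbook.

    ``true_beta`` are logit-scale coefficients per 1 (realized, within
    species) SD of each predictor; ``species_slope_sd`` gives the SD of
    species-level deviations around each coefficient.  Rates and sizes
    are per species unless stated.
    """

    n_species: int = 15
    n_reptile: int = 3  # clutch layers: same-year litter rule
    founders_per_species: int = 20
    n_years: int = 50
    start_year: int = 1970
    litter_mean: float = 2.5
    litter_max: int = 8
    breed_prob: float = 0.6  # per mature female per year
    max_breeding_females: int = 30  # managed-program carrying capacity
    wild_intake_rate: float = 0.5  # expected new wild founders / year
    migration_prob: float = 0.1  # offspring born outside dam's region
    intercept: float = 0.46
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    species_slope_sd: dict = field(
        default_factory=lambda: {p: 0.15 for p in PREDICTORS})
    intercept_sd_species: float = 0.5
    sd_program: float = 0.3
    sd_year: float = 0.3
    programs: tuple = DEFAULT_PROGRAMS
    mating_policy: str = "random"  # random | avoid_kin | prefer_kin
    seed: int = 0

    def __post_init__(self):
        if self.mating_policy not in ("random", "avoid_kin", "prefer_kin"):
            raise ValueError(f"unknown mating policy {self.mating_policy!r}")
        for name, val in (("intercept_sd_species", self.intercept_sd_species),
                          ("sd_program", self.sd_program),
                          ("sd_year", self.sd_year)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.wild_intake_rate:
            raise ValueError("wild_intake_rate must be >= 0")
        if self.litter_max < 1:
            raise ValueError("litter_max must be >= 1")


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analyst would estimate."""

    true_beta: dict
    intercept: float
    species_intercepts: dict
    species_slopes: dict  # {predictor: {species: deviation}}
    program_effects: dict  # {(species, program): effect}
    year_effects: dict  # {(species, year): effect}
    moments: dict  # {(species, predictor): (mean, sd)} used in the final run
    eta: dict  # per-offspring linear predictor
    prob: dict  # per-offspring survival probability
    f: dict  # simulator-internal inbreeding bookkeeping
    generation: dict
    configs: dict  # species name -> SpeciesConfig

    def species_effect(self, predictor: str, species: str) -> float:
        return self.true_beta[predictor] + \
            self.species_slopes[predictor][species]

    def to_jsonable(self) -> dict:
        return {
            "true_beta": self.true_beta,
            "intercept": self.intercept,
            "species_intercepts": self.species_intercepts,
            "species_slopes": self.species_slopes,
            "program_effects": {f"{s}|{p}": v for (s, p), v
                                in self.program_effects.items()},
            "year_effects": {f"{s}|{y}": v for (s, y), v
                             in self.year_effects.items()},
            "moments": {f"{s}|{p}": list(v) for (s, p), v
                        in self.moments.items()},
        }


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

class _SimPedigree:
    """Lightweight incremental pedigree used inside the simulator.

    The kinship recursion is the same recurrence as the analysis-side
    implementation (wild founders mutually unrelated and non-inbred), so
    the simulator's internal f bookkeeping agrees with pedigree-derived f
    exactly.
    """

    def __init__(self):
        self.parents: dict[str, Optional[tuple[str, str]]] = {}
        self.depth: dict[str, int] = {}
        self.memo: dict[tuple[str, str], float] = {}

    def add(self, iid, sire=None, dam=None):
        if sire is None or dam is None:
            self.parents[iid] = None
            self.depth[iid] = 0
        else:
            self.parents[iid] = (sire, dam)
            self.depth[iid] = 1 + max(self.depth[sire], self.depth[dam])

    def kinship(self, i, j):
        key = (i, j) if i <= j else (j, i)
        if key in self.memo:
            return self.memo[key]
        if i == j:
            par = self.parents[i]
            val = 0.5 if par is None else 0.5 * (1.0 + self.kinship(*par))
        else:
            if self.depth[i] < self.depth[j]:
                i, j = j, i
            par = self.parents[i]
            if par is None:
                val = 0.0
            else:
                val = 0.5 * (self.kinship(par[0], j)
                             + self.kinship(par[1], j))
        self.memo[key] = val
        return val

    def inbreeding(self, i):
        par = self.parents[i]
        return 0.0 if par is None else self.kinship(*par)


def _species_names(cfg: SimulationConfig) -> list[str]:
    return [f"species_{i + 1:02d}" for i in range(cfg.n_species)]


def _species_configs(cfg: SimulationConfig,
                     rng: np.random.Generator) -> dict[str, SpeciesConfig]:
    out = {}
    for i, name in enumerate(_species_names(cfg)):
        reptile = i < cfg.n_reptile
        if reptile:
            fem = int(rng.integers(900, 1600))
            male = int(rng.integers(900, 1600))
        else:
            fem = int(rng.integers(300, 750))
            male = int(rng.integers(300, 750))
        out[name] = SpeciesConfig(
            species=name, maturity_female_days=fem, maturity_male_days=male,
            litter_rule="same_year" if reptile else "same_day",
            first_record_year=cfg.start_year)
    return out


def simulate_studbook(cfg: SimulationConfig,
                      ) -> tuple[Pedigree, GroundTruth]:
    """Forward-simulate a multi-species studbook with known ground truth.

    Runs the forward process twice (calibration pass for realized predictor
    moments, then the definitive pass with frozen moments; see module
    docstring).  Deterministic under ``cfg.seed``.  If a species dies out
    the studbook is returned as-is with a warning.
    """
    moments = _run_forward(cfg, moments=None)[2]
    records, truth, _ = _run_forward(cfg, moments=moments)
    ped = Pedigree(records)
    return ped, truth


def _run_forward(cfg: SimulationConfig, moments):
    rng = np.random.default_rng(cfg.seed)
    names = _species_names(cfg)
    configs = _species_configs(cfg, rng)
    species_int = {s: cfg.intercept
                   + rng.normal(0.0, cfg.intercept_sd_species)
                   for s in names}
    slopes = {p: {s: rng.normal(0.0, cfg.species_slope_sd.get(p, 0.0))
                  for s in names} for p in PREDICTORS}
    prog_eff = {(s, p): rng.normal(0.0, cfg.sd_program)
                for s in names for p in cfg.programs}
    year_eff = {(s, cfg.start_year + y): rng.normal(0.0, cfg.sd_year)
                for s in names for y in range(cfg.n_years + 1)}

    sim = _SimPedigree()
    records: list[IndividualRecord] = []
    state: dict[str, dict] = {s: {} for s in names}  # per-species roster
    truth_eta, truth_p, truth_f, truth_g = {}, {}, {}, {}
    running: dict[tuple[str, str], list] = {}  # Welford accumulators
    end_date = date(cfg.start_year + cfg.n_years, 1, 1)
    counter = [0]

    def new_id(species_idx):
        counter[0] += 1
        return f"S{species_idx:02d}-{counter[0]:06d}"

    def standardize(species, pred, value):
        if moments is not None:
            mean, sd = moments[(species, pred)]
            return (value - mean) / sd
        acc = running.setdefault((species, pred), [0, 0.0, 0.0])
        if acc[0] < 2:
            return 0.0
        mean = acc[1]
        var = acc[2] / (acc[0] - 1)
        return (value - mean) / math.sqrt(var) if var > 0 else 0.0

    def update_moments(species, pred, value):
        acc = running.setdefault((species, pred), [0, 0.0, 0.0])
        acc[0] += 1
        d = value - acc[1]
        acc[1] += d / acc[0]
        acc[2] += d * (value - acc[1])

    def add_wild(species_idx, species, year, n):
        spc = configs[species]
        for _ in range(n):
            iid = new_id(species_idx)
            sex = "female" if rng.random() < 0.5 else "male"
            mat = spc.maturity_days(sex)
            back = int(mat + rng.integers(0, 5 * 365))
            birth = date(year, 1, 1) + timedelta(
                days=int(rng.integers(0, 360))) - timedelta(days=back)
            lifespan = mat + int(rng.exponential(3.0 * mat))
            death = birth + timedelta(days=lifespan)
            rec = IndividualRecord(
                id=iid, sire_id=None, dam_id=None, sex=sex,
                birth_date=birth,
                death_date=death if death <= end_date else None,
                birth_program=str(rng.choice(cfg.programs)),
                origin="wild", hybrid=False, species=species)
            records.append(rec)
            sim.add(iid)
            truth_f[iid], truth_g[iid] = 0.0, 0.0
            state[species][iid] = rec

    # founders
    for si, s in enumerate(names):
        add_wild(si, s, cfg.start_year, cfg.founders_per_species)

    for year in range(cfg.start_year, cfg.start_year + cfg.n_years):
        for si, s in enumerate(names):
            spc = configs[s]
            intake = rng.poisson(cfg.wild_intake_rate)
            if intake:
                add_wild(si, s, year, intake)
            roster = state[s]
            breeding_day = date(year, 1, 1) + timedelta(
                days=int(rng.integers(0, 300)))

            def eligible(sex):
                out = []
                for iid, rec in roster.items():
                    if rec.sex != sex:
                        continue
                    mat = spc.maturity_days(sex)
                    if (breeding_day - rec.birth_date).days < mat:
                        continue
                    if rec.death_date is not None and \
                            rec.death_date <= breeding_day:
                        continue
                    out.append(iid)
                return sorted(out)

            dams = eligible("female")
            sires = eligible("male")
            if not dams or not sires:
                continue
            if len(dams) > cfg.max_breeding_females:
                # managed programs pair a limited number of females a year
                chosen = rng.choice(len(dams), size=cfg.max_breeding_females,
                                    replace=False)
                dams = [dams[c] for c in sorted(chosen)]
            for dam_id in dams:
                if rng.random() >= cfg.breed_prob:
                    continue
                if cfg.mating_policy == "random":
                    sire_id = sires[rng.integers(0, len(sires))]
                else:
                    k = min(6, len(sires))
                    cand = [sires[c] for c in
                            rng.choice(len(sires), size=k, replace=False)]
                    kin = [sim.kinship(dam_id, c) for c in cand]
                    pick = (int(np.argmin(kin))
                            if cfg.mating_policy == "avoid_kin"
                            else int(np.argmax(kin)))
                    sire_id = cand[pick]
                litter = 1 + int(rng.poisson(max(cfg.litter_mean - 1.0, 0.0)))
                litter = min(litter, cfg.litter_max)
                litter_day = breeding_day + timedelta(
                    days=int(rng.integers(0, 60)))
                dam_rec, sire_rec = roster[dam_id], roster[sire_id]
                off_f = sim.kinship(dam_id, sire_id)
                for o in range(litter):
                    if spc.litter_rule == "same_day":
                        birth = litter_day
                    else:  # clutch spread over weeks within the year
                        birth = min(litter_day + timedelta(days=10 * o),
                                    date(year, 12, 31))
                    if birth > end_date:
                        continue
                    iid = new_id(si)
                    sex = "female" if rng.random() < 0.5 else "male"
                    sim.add(iid, sire_id, dam_id)
                    g = 0.5 * (truth_g[sire_id] + truth_g[dam_id]) + 1.0
                    raw = {
                        "dam_generation": truth_g[dam_id],
                        "sire_generation": truth_g[sire_id],
                        "dam_age": float((birth - dam_rec.birth_date).days),
                        "sire_age": float(
                            (birth - sire_rec.birth_date).days),
                        "dam_f": truth_f[dam_id],
                        "sire_f": truth_f[sire_id],
                        "offspring_f": off_f,
                    }
                    eta = species_int[s] + year_eff[(s, year)]
                    program = dam_rec.birth_program
                    if rng.random() < cfg.migration_prob:
                        program = str(rng.choice(cfg.programs))
                    eta += prog_eff[(s, program)]
                    for pred in PREDICTORS:
                        x = standardize(s, pred, raw[pred])
                        eta += (cfg.true_beta.get(pred, 0.0)
                                + slopes[pred][s]) * x
                    for pred in PREDICTORS:
                        update_moments(s, pred, raw[pred])
                    p = 1.0 / (1.0 + math.exp(-eta))
                    survive = rng.random() < p
                    mat = spc.maturity_days(sex)
                    if survive:
                        lifespan = mat + int(rng.exponential(3.0 * mat))
                    else:
                        lifespan = int(rng.integers(1, mat))
                    death = birth + timedelta(days=lifespan)
                    rec = IndividualRecord(
                        id=iid, sire_id=sire_id, dam_id=dam_id, sex=sex,
                        birth_date=birth,
                        death_date=death if death <= end_date else None,
                        birth_program=program, origin="captive",
                        hybrid=False, species=s)
                    records.append(rec)
                    roster[iid] = rec
                    truth_eta[iid], truth_p[iid] = eta, p
                    truth_f[iid], truth_g[iid] = off_f, g

    alive_by_species = {
        s: sum(1 for r in state[s].values()
               if r.death_date is None or r.death_date > end_date)
        for s in names}
    extinct = [s for s, n in alive_by_species.items() if n == 0]
    if extinct:
        warnings.warn(
            f"population extinct for species: {', '.join(extinct)}; "
            "returning partial studbook")

    final_moments = {}
    for (s, pred), acc in running.items():
        n, mean, m2 = acc
        sd = math.sqrt(m2 / (n - 1)) if n > 1 and m2 > 0 else 1.0
        final_moments[(s, pred)] = (mean, sd)
    truth = GroundTruth(
        true_beta=dict(cfg.true_beta), intercept=cfg.intercept,
        species_intercepts={s: v - cfg.intercept
                            for s, v in species_int.items()},
        species_slopes=slopes, program_effects=prog_eff,
        year_effects=year_eff,
        moments=(moments if moments is not None else final_moments),
        eta=truth_eta, prob=truth_p, f=truth_f, generation=truth_g,
        configs=configs)
    return records, truth, final_moments


# ---------------------------------------------------------------------------
# species trees with known phylogenetic signal
# ---------------------------------------------------------------------------

def simulate_species_tree(n_species: int, seed: int = 0, lam: float = 1.0,
                          rate: float = 1.0, mean: float = 0.0,
                          names: Optional[list[str]] = None,
                          trait_seed: Optional[int] = None):
    """Random coalescent-style ultrametric tree + trait with chosen lambda.

    The trait vector is drawn from N(mean, rate * C_lambda) where C is the
    tree's Brownian covariance and C_lambda its lambda transform; returns
    ``(dendropy tree, pandas Series of traits)``.  ``trait_seed`` draws a
    fresh trait realization on the same (seed-determined) tree.
    """
    from .phylo import lambda_covariance, read_newick, tree_covariance
    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"species_{i + 1:02d}" for i in range(n_species)]
    nodes = [(name, 0.0) for name in names]  # (newick, height)
    k = len(nodes)
    height = 0.0
    while len(nodes) > 1:
        height += rng.exponential(1.0 / math.comb(len(nodes), 2))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_i, h_i), (nwk_j, h_j) = nodes[i], nodes[j]
        merged = (f"({nwk_i}:{height - h_i:.10f},"
                  f"{nwk_j}:{height - h_j:.10f})", height)
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    newick = nodes[0][0] + ";"
    tree = read_newick(newick, is_path=False)
    labels, C = tree_covariance(tree)
    C = C / np.diag(C).mean()  # unit-height scaling for interpretability
    V = rate * lambda_covariance(C, lam)
    # order traits as 'names'
    order = [labels.index(n) for n in names]
    V = V[np.ix_(order, order)]
    if trait_seed is not None:
        rng = np.random.default_rng(trait_seed)
    z = rng.standard_normal(len(names))
    traits = mean + np.linalg.cholesky(
        V + 1e-12 * np.eye(len(names))) @ z
    return tree, pd.Series(traits, index=names)


# ---------------------------------------------------------------------------
# direct design-matrix simulator (for model-level tests)
# ---------------------------------------------------------------------------

def simulate_glmm_table(n: int, beta: dict, intercept: float = 0.0,
                        n_species: int = 6, n_programs: int = 3,
                        n_years: int = 10, sd_species: float = 0.3,
                        sd_program: float = 0.2, sd_year: float = 0.2,
                        slope_sd: Optional[dict] = None,
                        seed: int = 0):
    """Bernoulli responses from the survival GLMM with i.i.d. predictors.

    Bypasses the pedigree machinery: the seven predictors are standard
    normal, grouping factors are balanced-random, and the logit is
    ``intercept + sum (beta_j + species_dev_j) x_j + species + program
    + year effects``.  Returns ``(DataFrame, truth dict)``.  Useful when a
    test needs exact control of the design.
    """
    rng = np.random.default_rng(seed)
    slope_sd = slope_sd or {}
    species = rng.integers(0, n_species, size=n)
    program = rng.integers(0, n_programs, size=n)
    year = rng.integers(0, n_years, size=n)
    X = {p: rng.standard_normal(n) for p in PREDICTORS}
    a_species = rng.normal(0.0, sd_species, size=n_species)
    a_program = rng.normal(0.0, sd_program, size=(n_species, n_programs))
    a_year = rng.normal(0.0, sd_year, size=(n_species, n_years))
    devs = {p: rng.normal(0.0, slope_sd.get(p, 0.0), size=n_species)
            for p in PREDICTORS}
    eta = np.full(n, float(intercept))
    eta += a_species[species] + a_program[species, program] \
        + a_year[species, year]
    for p in PREDICTORS:
        eta += (beta.get(p, 0.0) + devs[p][species]) * X[p]
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < prob).astype(int)
    df = pd.DataFrame({
        "survival": y,
        "species": [f"sp{int(s) + 1:02d}" for s in species],
        "birth_program": [f"prog{int(p) + 1}" for p in program],
        "birth_year": 2000 + year,
        **{p: X[p] for p in PREDICTORS},
    })
    truth = {
        "beta": {p: beta.get(p, 0.0) for p in PREDICTORS},
        "intercept": intercept,
        "species_devs": {p: {f"sp{i + 1:02d}": float(devs[p][i])
                             for i in range(n_species)}
                         for p in PREDICTORS},
        "eta": eta, "prob": prob,
    }
    return df, truth


# ---------------------------------------------------------------------------
# toy pedigrees with analytically known f, kinship, G
# ---------------------------------------------------------------------------

def _rec(iid, sire, dam, sex, birth, death=None, program="Europe",
         origin="captive", hybrid=False, species="toy", release=None):
    return IndividualRecord(
        id=iid, sire_id=sire, dam_id=dam, sex=sex,
        birth_date=birth, death_date=death, birth_program=program,
        origin=origin, hybrid=hybrid, species=species,
        release_date=release)


def toy_configs() -> dict[str, SpeciesConfig]:
    """Species configs matching the toy fixtures (maturity 365 d)."""
    return {
        "toy": SpeciesConfig("toy", 365, 365, "same_day"),
        "tortoise": SpeciesConfig("tortoise", 365, 365, "same_year"),
    }


def toy_fixtures() -> dict[str, Pedigree]:
    """Hand-constructed pedigrees with analytically known quantities.

    * ``founders``: four unrelated wild founders (all f = 0, G = 0).
    * ``fullsib``: offspring of a full-sib mating, f = 1/4.
    * ``parent_offspring``: offspring of a parent-offspring mating, f = 1/4.
    * ``g_mix``: offspring of a G0 x G1 pairing, G = 1.5.
    * ``litters_mixed``: a same-day mammal litter and a same-year clutch.
    * ``exclusions``: forced exclusion tally (1 too-young, 2 hybrids,
      2 wild-born, 1 unknown-sire; 6 analysis rows retained).
    """
    d = date
    fixtures = {}

    fixtures["founders"] = Pedigree([
        _rec("F1", None, None, "female", d(1990, 1, 1), origin="wild"),
        _rec("F2", None, None, "male", d(1990, 1, 1), origin="wild"),
        _rec("F3", None, None, "female", d(1991, 1, 1), origin="wild"),
        _rec("F4", None, None, "male", d(1991, 1, 1), origin="wild"),
    ])

    fixtures["fullsib"] = Pedigree([
        _rec("A", None, None, "male", d(1990, 1, 1), origin="wild"),
        _rec("B", None, None, "female", d(1990, 1, 1), origin="wild"),
        _rec("C", "A", "B", "male", d(1993, 1, 1)),
        _rec("D", "A", "B", "female", d(1994, 1, 1)),
        _rec("E", "C", "D", "female", d(1997, 1, 1)),
    ])

    fixtures["parent_offspring"] = Pedigree([
        _rec("A", None, None, "male", d(1990, 1, 1), origin="wild"),
        _rec("B", None, None, "female", d(1990, 1, 1), origin="wild"),
        _rec("C", "A", "B", "female", d(1993, 1, 1)),
        _rec("E", "A", "C", "male", d(1996, 1, 1)),
    ])

    fixtures["g_mix"] = Pedigree([
        _rec("W1", None, None, "male", d(1985, 1, 1), origin="wild"),
        _rec("W2", None, None, "female", d(1985, 1, 1), origin="wild"),
        _rec("A", None, None, "female", d(1988, 1, 1), origin="wild"),
        _rec("B", "W1", "W2", "male", d(1990, 1, 1)),  # G1
        _rec("C", "B", "A", "female", d(1994, 1, 1)),  # (0+1)/2+1 = 1.5
    ])

    fixtures["litters_mixed"] = Pedigree([
        _rec("M1", None, None, "male", d(1990, 1, 1), origin="wild"),
        _rec("M2", None, None, "female", d(1990, 1, 1), origin="wild"),
        _rec("L1", "M1", "M2", "female", d(1995, 3, 1)),
        _rec("L2", "M1", "M2", "male", d(1995, 3, 1)),
        _rec("L3", "M1", "M2", "male", d(1995, 3, 1)),
        _rec("T1", None, None, "male", d(1990, 1, 1), origin="wild",
             species="tortoise"),
        _rec("T2", None, None, "female", d(1990, 1, 1), origin="wild",
             species="tortoise"),
        _rec("C1", "T1", "T2", "female", d(1996, 2, 1),
             species="tortoise"),
        _rec("C2", "T1", "T2", "male", d(1996, 5, 10),
             species="tortoise"),
        _rec("C3", "T1", "T2", "female", d(1997, 4, 1),
             species="tortoise"),
        # late guard founder so truncation leaves the litters intact
        _rec("G1", None, None, "male", d(2000, 1, 1), origin="wild"),
    ])

    # exclusion-tally fixture; latest record 2020-01-01, so the analysis
    # cutoff after 364-day truncation is 2019-01-03 and maturity is 365 d
    retained_birth = d(2015, 6, 1)
    fixtures["exclusions"] = Pedigree([
        _rec("P1", None, None, "male", d(2000, 1, 1), origin="wild"),
        _rec("P2", None, None, "female", d(2000, 1, 1), origin="wild",
             death=d(2020, 1, 1)),
        _rec("K1", "P1", "P2", "male", retained_birth),
        _rec("K2", "P1", "P2", "female", retained_birth),
        _rec("K3", "P1", "P2", "male", retained_birth,
             death=d(2015, 9, 1)),  # died young: survival 0, retained
        _rec("K4", "P1", "P2", "female", d(2016, 6, 1)),
        _rec("K5", "P1", "P2", "male", d(2016, 6, 1)),
        _rec("K6", "P1", "P2", "female", d(2016, 6, 1)),
        _rec("H1", "P1", "P2", "male", d(2016, 6, 1), hybrid=True),
        _rec("H2", "P1", "P2", "female", d(2016, 6, 1), hybrid=True),
        _rec("U1", None, "P2", "male", d(2016, 6, 1)),  # unknown sire
        _rec("Y1", "P1", "P2", "female", d(2018, 8, 1)),  # too young
    ])
    return fixtures
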