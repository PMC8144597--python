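"""All-subsets AICc model selection, conditional averaging and pooling.

The inference workflow is information-theoretic: every subset of the seven
fixed predictors is fitted with the random structure held constant
("dredge"), models are ranked by small-sample AICc, the set within 2 AICc
units of the best model is retained, and the retained models are combined
by the *conditional* average - each predictor is averaged only over the
retained models that contain it, weighted by renormalized Akaike weights.
Because litter sampling is repeated (default five times), the averaged
estimates of the replicates are pooled to a mean estimate, mean SE and a
normal 95% CI.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import PREDICTORS
from .glmm import BinomialMixedModel, ConvergenceError, MixedModelResults

__all__ = [
    "aicc",
    "ModelSet",
    "AveragedEstimates",
    "dredge",
    "retain_and_average",
    "pool_replicates",
]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    ``AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)``; requires ``n > k + 1``.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n <= k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class ModelSet:
    """Ranked collection of fitted subset models.

    ``table`` has one row per converged model: the included terms, log
    likelihood, parameter count, AICc, delta (AICc above the best model)
    and Akaike weight (normalized over converged models).
    """

    table: pd.DataFrame
    results: list[MixedModelResults]
    failed: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


def dredge(data, fixed: Sequence[str] = PREDICTORS,
           random_intercepts=None, progress: bool = False) -> ModelSet:
    """Fit all subsets of the fixed predictors (intercept always included).

    With the seven survival predictors this is 2^7 = 128 candidate models,
    all sharing the random-intercept structure.  Sub-model fits are
    warm-started from the global model's variance estimates.  A sub-model
    that fails to converge is recorded and excluded from the weights; a
    failure of the global model itself aborts.
    """
    from .glmm import DEFAULT_RANDOM_INTERCEPTS
    if random_intercepts is None:
        random_intercepts = DEFAULT_RANDOM_INTERCEPTS
    fixed = tuple(fixed)

    def fit_subset(terms, start_sd=None, outer_maxiter=200):
        model = BinomialMixedModel.from_table(
            data, fixed=terms, random_intercepts=random_intercepts)
        return model.fit(start_sd=start_sd, outer_maxiter=outer_maxiter)

    global_res = fit_subset(fixed)  # ConvergenceError propagates: abort
    start = global_res.vc_sd.to_numpy()

    rows = []
    results = []
    failed = []
    subsets = sorted(
        (tuple(c) for r in range(len(fixed) + 1)
         for c in itertools.combinations(fixed, r)),
        key=len, reverse=True)
    for terms in subsets:
        if terms == fixed:
            res = global_res
        else:
            try:
                # warm start at the global variance estimates with a capped
                # number of refinement iterations: near the optimum the
                # profiled deviance is flat in the variance parameters, so
                # the residual AICc error is far below the 2-unit retention
                # granularity
                res = fit_subset(terms, start_sd=start, outer_maxiter=8)
            except ConvergenceError as exc:
                warnings.warn(
                    f"sub-model {terms or '(intercept only)'} failed to "
                    f"converge; excluded from the model set")
                failed.append((terms, str(exc)))
                continue
        rows.append({
            "terms": terms,
            "loglik": res.llf,
            "k": res.k_params,
            "n": res.n_obs,
            "aicc": aicc(res.llf, res.k_params, res.n_obs),
        })
        results.append(res)

    table = pd.DataFrame(rows)
    order = np.argsort(table["aicc"].to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    results = [results[i] for i in order]
    table["delta"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = rel / rel.sum()
    return ModelSet(table=table, results=results, failed=failed)


@dataclass
class AveragedEstimates:
    """Conditionally model-averaged coefficients over a retained model set.

    ``table`` rows are predictors (plus the intercept) with columns
    ``estimate`` (weighted mean over retained models containing the term),
    ``se`` (the revised model-averaging estimator, which folds in
    between-model spread), ``ci_low``/``ci_high`` and
    ``relative_importance`` (sum of renormalized retained weights of models
    containing the term).
    """

    table: pd.DataFrame
    retained: pd.DataFrame
    delta_cutoff: float

    @property
    def predictors(self) -> list[str]:
        return list(self.table.index)


def retain_and_average(ms: ModelSet, delta_cutoff: float = 2.0,
                       ) -> AveragedEstimates:
    """Retain models with delta <= cutoff and conditionally average them.

    Weights are renormalized over the retained set.  For each term the
    average runs only over retained models containing it (weights again
    renormalized over those); the SE uses the revised unconditional-variance
    estimator  ``se = sum_m w_m sqrt(se_m^2 + (b_m - b_avg)^2)``.
    A term present in every retained model has relative importance 1.
    """
    if len(ms) == 0:
        raise ValueError("empty model set")
    keep = ms.table["delta"] <= delta_cutoff
    retained = ms.table[keep].copy()
    res_kept = [r for r, k in zip(ms.results, keep) if k]
    w = retained["weight"].to_numpy()
    w = w / w.sum()
    retained["weight_renorm"] = w

    global_terms = max(ms.table["terms"], key=len)
    all_terms = ["intercept"] + list(global_terms)
    rows = {}
    for term in all_terms:
        est, se, imp = _average_term(term, retained, res_kept)
        if est is None:
            # term absent from every retained model: no conditional
            # average exists; keep the row (NaN) so replicates stay aligned
            est, se = np.nan, np.nan
        rows[term] = {
            "estimate": est, "se": se,
            "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
            "relative_importance": imp,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return AveragedEstimates(table=table, retained=retained,
                             delta_cutoff=delta_cutoff)


def _average_term(term, retained, res_kept):
    present = []
    for i, (terms, wr) in enumerate(
            zip(retained["terms"], retained["weight_renorm"])):
        if term == "intercept" or term in terms:
            present.append((i, wr))
    if not present:
        return None, None, 0.0
    importance = float(sum(wr for _, wr in present))
    wsub = np.array([wr for _, wr in present])
    wsub = wsub / wsub.sum()
    b = np.array([float(res_kept[i].params[term]) for i, _ in present])
    se = np.array([float(res_kept[i].bse[term]) for i, _ in present])
    b_avg = float(wsub @ b)
    se_avg = float(wsub @ np.sqrt(se ** 2 + (b - b_avg) ** 2))
    return b_avg, se_avg, importance


def pool_replicates(results: Sequence[AveragedEstimates]) -> pd.DataFrame:
    """Pool averaged estimates across litter-sampling replicates.

    Per predictor: mean of replicate estimates, mean of replicate SEs, and
    CI = mean estimate +/- 1.96 x mean SE.  ``significant`` flags a pooled
    CI that excludes zero.  All replicates must share the same predictor
    set.
    """
    if len(results) == 0:
        raise ValueError("no replicates to pool")
    terms = list(results[0].table.index)
    for r in results[1:]:
        if list(r.table.index) != terms:
            raise ValueError(
                "replicates have mismatched predictor sets: "
                f"{terms} vs {list(r.table.index)}")
    with warnings.catch_warnings():
        # a term absent from every retained model of a replicate is NaN
        # there; pool over the replicates where it was averaged
        warnings.simplefilter("ignore", RuntimeWarning)
        est = np.nanmean([r.table["estimate"].to_numpy()
                          for r in results], axis=0)
        se = np.nanmean([r.table["se"].to_numpy() for r in results], axis=0)
    imp = np.mean([r.table["relative_importance"].to_numpy()
                   for r in results], axis=0)
    out = pd.DataFrame({
        "mean_estimate": est,
        "mean_se": se,
        "ci_low": est - 1.96 * se,
        "ci_high": est + 1.96 * se,
        "relative_importance": imp,
    }, index=terms)
    out["significant"] = (out["ci_low"] > 0.0) | (out["ci_high"] < 0.0)
    return out


def model_selection_report(ms: ModelSet, path) -> None:
    """CSV of the full ranked model table (terms, loglik, k, AICc, ...)."""
    tab = ms.table.copy()
    tab["terms"] = tab["terms"].map(lambda t: "+".join(t) or "(intercept)")
    tab.to_csv(path, index=False)
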