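"""Binomial (Bernoulli-logit) mixed models by Laplace approximation.

The survival analysis needs generalized linear mixed models with the random
structure ``(1|Species/BirthProgram) + (1|Species:Year)`` - expanded to
three independent Gaussian random-intercept terms (Species,
Species:BirthProgram, Species:Year) - plus, for species-level effect
estimates, an uncorrelated species-level random slope on one predictor.

Estimation follows the standard Laplace scheme: for a given vector of
random-effect standard deviations ``sigma`` the fixed effects and the
conditional modes of the (spherical) random effects are found jointly by
penalized iteratively reweighted least squares (PIRLS); the profiled
Laplace deviance

    dev(sigma) = -2 l_y(beta_hat, u_hat) + ||s_hat||^2
                 + log det(Lambda' Z' W Z Lambda + I)

is then minimized over ``sigma >= 0`` by a quasi-Newton bounded optimizer.
Starting values are deterministic (beta/s at zero, sigma at 0.5), so a fit
is reproducible with no randomness.  Fixing all standard deviations at zero
reduces the objective exactly to the plain logistic-regression likelihood.

The module follows the Model -> fit() -> Results pattern:

>>> model = BinomialMixedModel.from_table(data, fixed=PREDICTORS)
>>> res = model.fit()
>>> res.summary()
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .dataset import PREDICTORS, StandardizedTable

__all__ = [
    "ModelSpec",
    "RandomTerm",
    "BinomialMixedModel",
    "MixedModelResults",
    "DiagnosticsReport",
    "ConvergenceError",
    "fit_random_slope",
    "residual_diagnostics",
    "variance_inflation",
]

#: default random-intercept structure of the global survival model
DEFAULT_RANDOM_INTERCEPTS = ("species", "species:birth_program",
                             "species:year")

#: |standardized beta| beyond which quasi-complete separation is suspected
SEPARATION_THRESHOLD = 15.0


class ConvergenceError(RuntimeError):
    """Fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class ModelSpec:
    """Symbolic model specification.

    ``random_intercepts`` are grouping-factor names, where ``a:b`` denotes
    the interaction (levels = observed combinations).  ``random_slope`` is
    an optional ``(predictor, grouping_factor)`` pair.
    """

    response: str = "survival"
    fixed_terms: tuple[str, ...] = PREDICTORS
    random_intercepts: tuple[str, ...] = DEFAULT_RANDOM_INTERCEPTS
    random_slope: Optional[tuple[str, str]] = None

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        """Parse a formula-like string.

        Accepts e.g.::

            survival ~ dam_generation + offspring_f
                + (1|species/birth_program) + (1|species:year)
                + (0 + offspring_f | species)
        """
        lhs, rhs = formula.split("~")
        response = lhs.strip()
        fixed: list[str] = []
        intercepts: list[str] = []
        slope = None
        # split on '+' not inside parentheses
        parts = re.split(r"\+(?![^(]*\))", rhs)
        for part in parts:
            part = part.strip()
            if not part or part == "1":
                continue
            m = re.fullmatch(r"\(\s*(.+?)\s*\|\s*(.+?)\s*\)", part)
            if m:
                inner, group = m.group(1), m.group(2)
                if inner == "1":
                    if "/" in group:
                        outer, nested = (g.strip() for g in group.split("/"))
                        intercepts.append(outer)
                        intercepts.append(f"{outer}:{nested}")
                    else:
                        intercepts.append(group.replace(" ", ""))
                else:
                    pred = inner.replace("0", "").replace("+", "").strip()
                    slope = (pred, group.replace(" ", ""))
            else:
                fixed.append(part)
        return cls(response=response, fixed_terms=tuple(fixed),
                   random_intercepts=tuple(intercepts), random_slope=slope)


@dataclass
class RandomTerm:
    """One independent Gaussian random-effect term.

    ``codes`` maps each observation to a level in ``[0, n_levels)``;
    ``values`` is the per-observation covariate (all ones for a random
    intercept).
    """

    name: str
    codes: np.ndarray
    n_levels: int
    labels: Sequence[str]
    values: Optional[np.ndarray] = None

    def column_values(self) -> np.ndarray:
        if self.values is None:
            return np.ones(len(self.codes))
        return np.asarray(self.values, dtype=float)


def _factor_codes(data: pd.DataFrame, name: str):
    """Codes/labels for a (possibly interaction) grouping factor."""
    cols = name.split(":")
    mapping = {"year": "birth_year", "program": "birth_program"}
    keys = [mapping.get(c, c) for c in cols]
    combined = data[keys[0]].astype(str)
    for k in keys[1:]:
        combined = combined + ":" + data[k].astype(str)
    labels, codes = np.unique(combined.to_numpy(), return_inverse=True)
    return codes.astype(np.intp), list(labels)


class BinomialMixedModel:
    """Bernoulli-logit mixed model with independent variance components.

    Parameters
    ----------
    endog : (n,) array of 0/1 responses
    exog : (n, p) fixed-effect design (include the intercept column)
    exog_names : names for the p fixed-effect columns
    random_terms : list of :class:`RandomTerm`
    """

    def __init__(self, endog, exog, exog_names, random_terms):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be (n, p) aligned with endog")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        self.exog_names = list(exog_names)
        self.random_terms = list(random_terms)
        for t in self.random_terms:
            if t.n_levels < 2:
                raise ValueError(
                    f"grouping factor {t.name!r} needs >= 2 levels")
        self.n_obs = self.endog.shape[0]
        self.k_fixed = self.exog.shape[1]
        self._offsets = np.cumsum(
            [0] + [t.n_levels for t in self.random_terms])
        self.q = int(self._offsets[-1])
        self._term_values = [t.column_values() for t in self.random_terms]

    # -- construction ---------------------------------------------------
    @classmethod
    def from_table(cls, data, fixed: Sequence[str] = PREDICTORS,
                   random_intercepts: Sequence[str] = DEFAULT_RANDOM_INTERCEPTS,
                   random_slope: Optional[tuple[str, str]] = None,
                   response: str = "survival") -> "BinomialMixedModel":
        """Build from an analysis table (standardized or raw DataFrame).

        ``random_slope=(predictor, group)`` adds an uncorrelated random
        slope for ``predictor`` across the levels of ``group``.
        """
        if isinstance(data, StandardizedTable):
            data = data.data
        y = data[response].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(data))] + [data[f].to_numpy(dtype=float)
                                    for f in fixed])
        names = ["intercept"] + list(fixed)
        terms = []
        for g in random_intercepts:
            codes, labels = _factor_codes(data, g)
            terms.append(RandomTerm(name=g, codes=codes,
                                    n_levels=len(labels), labels=labels))
        if random_slope is not None:
            pred, group = random_slope
            codes, labels = _factor_codes(data, group)
            terms.append(RandomTerm(
                name=f"{pred}|{group}", codes=codes, n_levels=len(labels),
                labels=labels, values=data[pred].to_numpy(dtype=float)))
        return cls(y, X, names, terms)

    @classmethod
    def from_spec(cls, spec: ModelSpec, data) -> "BinomialMixedModel":
        return cls.from_table(
            data, fixed=spec.fixed_terms,
            random_intercepts=spec.random_intercepts,
            random_slope=spec.random_slope, response=spec.response)

    # -- internals ------------------------------------------------------
    def _assemble(self, w, sigma):
        """Dense normal-equation matrix M, ordered [s-blocks, beta]."""
        p, q, n = self.k_fixed, self.q, self.n_obs
        M = np.zeros((q + p, q + p))
        X = self.exog
        WX = X * w[:, None]
        M[q:, q:] = X.T @ WX
        scaled = []  # per-term column values * sigma_k
        for k, t in enumerate(self.random_terms):
            scaled.append(self._term_values[k] * sigma[k])
        for k, t in enumerate(self.random_terms):
            o = self._offsets[k]
            vk = scaled[k]
            # diagonal of the within-term block (one-hot in levels)
            diag = np.bincount(t.codes, weights=w * vk * vk,
                               minlength=t.n_levels)
            idx = np.arange(t.n_levels)
            M[o + idx, o + idx] = diag + 1.0  # + I from the penalty
            # cross with fixed effects
            for a in range(p):
                M[q + a, o:o + t.n_levels] = np.bincount(
                    t.codes, weights=WX[:, a] * vk, minlength=t.n_levels)
                M[o:o + t.n_levels, q + a] = M[q + a, o:o + t.n_levels]
            # cross with other terms
            for l in range(k + 1, len(self.random_terms)):
                u = self.random_terms[l]
                ou = self._offsets[l]
                pair = t.codes * u.n_levels + u.codes
                block = np.bincount(
                    pair, weights=w * vk * scaled[l],
                    minlength=t.n_levels * u.n_levels,
                ).reshape(t.n_levels, u.n_levels)
                M[o:o + t.n_levels, ou:ou + u.n_levels] = block
                M[ou:ou + u.n_levels, o:o + t.n_levels] = block.T
        return M

    def _eta(self, beta, s, sigma):
        eta = self.exog @ beta
        for k, t in enumerate(self.random_terms):
            o = self._offsets[k]
            eta = eta + sigma[k] * self._term_values[k] * s[o + t.codes]
        return eta

    def _joint_loglik(self, beta, s, sigma):
        eta = self._eta(beta, s, sigma)
        ll = float(self.endog @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(s @ s), eta

    def _pirls(self, beta, s, sigma, maxiter=60, tol=1e-11):
        """Joint Newton over (s, beta) with step halving.

        Returns (beta, s, h, logdet_ss, M, w, converged).
        """
        p, q = self.k_fixed, self.q
        h, eta = self._joint_loglik(beta, s, sigma)
        logdet = None
        M = None
        w = None
        converged = False
        for _ in range(maxiter):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            resid = self.endog - mu
            g = np.empty(q + p)
            g[q:] = self.exog.T @ resid
            for k, t in enumerate(self.random_terms):
                o = self._offsets[k]
                vk = self._term_values[k] * sigma[k]
                g[o:o + t.n_levels] = np.bincount(
                    t.codes, weights=resid * vk, minlength=t.n_levels
                ) - s[o:o + t.n_levels]
            M = self._assemble(w, sigma)
            try:
                L = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                M[np.diag_indices_from(M)] += 1e-8
                L = np.linalg.cholesky(M)
            step = solve_triangular(
                L.T, solve_triangular(L, g, lower=True,
                                      check_finite=False),
                lower=False, check_finite=False)
            logdet = 2.0 * float(np.log(np.diag(L)[:q]).sum())
            # step halving on the joint penalized loglik
            t_step = 1.0
            for _half in range(30):
                s_new = s + t_step * step[:q]
                b_new = beta + t_step * step[q:]
                h_new, eta_new = self._joint_loglik(b_new, s_new, sigma)
                if h_new >= h - 1e-13:
                    break
                t_step *= 0.5
            improved = h_new - h
            beta, s, eta = b_new, s_new, eta_new
            h = h_new
            if abs(improved) < tol * (1.0 + abs(h)):
                converged = True
                break
        return beta, s, h, logdet, M, w, converged

    def _profiled_deviance(self, sigma, state):
        beta, s = state["beta"], state["s"]
        beta, s, h, logdet, M, w, ok = self._pirls(beta, s, sigma)
        if not ok:
            # restart cold once; PIRLS is globally convergent with halving,
            # a stale warm start can stall near a weight cliff
            beta, s, h, logdet, M, w, ok = self._pirls(
                np.zeros(self.k_fixed), np.zeros(self.q), sigma, maxiter=120)
        state.update(beta=beta, s=s, M=M, w=w, pirls_ok=ok)
        # h includes the -||s||^2/2 penalty already
        return -2.0 * h + logdet

    # -- fitting --------------------------------------------------------
    def fit(self, start_sd: Optional[Sequence[float]] = None,
            fix_sd: Optional[Sequence[float]] = None,
            outer_maxiter: int = 200) -> "MixedModelResults":
        """Maximize the Laplace marginal likelihood.

        Parameters
        ----------
        start_sd
            Starting standard deviations per random term (default 0.5).
        fix_sd
            If given, the standard deviations are held at these values and
            only (beta, s) are estimated - ``fix_sd=[0, ...]`` reduces the
            model to a plain logistic regression.
        """
        K = len(self.random_terms)
        state = {"beta": np.zeros(self.k_fixed), "s": np.zeros(self.q)}
        trace: list[tuple[np.ndarray, float]] = []

        if fix_sd is not None:
            sigma = np.asarray(fix_sd, dtype=float)
            dev = self._profiled_deviance(sigma, state)
            if not state["pirls_ok"]:
                raise ConvergenceError("PIRLS failed at fixed variances",
                                       trace)
            opt_success, opt_message = True, "variances held fixed"
        else:
            start = (np.full(K, 0.5) if start_sd is None
                     else np.asarray(start_sd, dtype=float))
            start = np.clip(start, 0.0, 20.0)

            def objective(sig):
                d = self._profiled_deviance(np.maximum(sig, 0.0), state)
                trace.append((np.array(sig), d))
                return d

            res = optimize.minimize(
                objective, start, method="L-BFGS-B",
                bounds=[(0.0, 25.0)] * K,
                options={"maxiter": outer_maxiter,
                         "maxfun": (K + 2) * outer_maxiter, "eps": 1e-5,
                         "ftol": 1e-10, "gtol": 1e-6})
            hit_cap = (not res.success) and res.status == 1
            if not res.success and not hit_cap:
                res2 = optimize.minimize(
                    objective, res.x, method="Powell",
                    bounds=[(0.0, 25.0)] * K,
                    options={"maxiter": outer_maxiter, "xtol": 1e-7,
                             "ftol": 1e-9})
                res = res2 if res2.fun <= res.fun else res
            sigma = np.maximum(res.x, 0.0)
            dev = self._profiled_deviance(sigma, state)
            opt_success = bool(res.success) or hit_cap or dev <= min(
                d for _, d in trace) + 1e-6
            opt_message = str(getattr(res, "message", ""))
            if not opt_success or not state["pirls_ok"]:
                raise ConvergenceError(
                    f"mixed-model fit did not converge: {opt_message}",
                    trace)

        beta, s, M, w = state["beta"], state["s"], state["M"], state["w"]
        if np.max(np.abs(beta)) > SEPARATION_THRESHOLD:
            warnings.warn(
                "very large standardized coefficient: possible "
                "quasi-complete separation", stacklevel=2)
        # conditional (on sigma) covariance of beta: beta-block of M^{-1}
        p, q = self.k_fixed, self.q
        E = np.zeros((q + p, p))
        E[q:, :] = np.eye(p)
        Minv_E = np.linalg.solve(M, E)
        vcov = Minv_E[q:, :]
        vcov = 0.5 * (vcov + vcov.T)
        llf = -0.5 * dev
        return MixedModelResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(np.sqrt(np.diag(vcov)), index=self.exog_names),
            vcov_fixed=pd.DataFrame(vcov, index=self.exog_names,
                                    columns=self.exog_names),
            vc_sd=pd.Series([float(x) for x in
                             (sigma if K else [])],
                            index=[t.name for t in self.random_terms]),
            llf=llf, deviance=dev,
            cond_modes=s.copy(), n_obs=self.n_obs,
            k_params=self.k_fixed + K,
            converged=True, optimizer_message=opt_message,
            trace=trace)


@dataclass
class MixedModelResults:
    """Results of a :class:`BinomialMixedModel` fit.

    ``vc_sd`` holds the random-effect standard deviations per term (their
    squares are the variance components); ``llf`` is the Laplace marginal
    log-likelihood; ``k_params`` counts fixed effects plus variance terms.
    """

    model: BinomialMixedModel
    params: pd.Series
    bse: pd.Series
    vcov_fixed: pd.DataFrame
    vc_sd: pd.Series
    llf: float
    deviance: float
    cond_modes: np.ndarray
    n_obs: int
    k_params: int
    converged: bool
    optimizer_message: str = ""
    trace: list = field(default_factory=list)

    # -- derived quantities ---------------------------------------------
    @property
    def aicc(self) -> float:
        from .selection import aicc
        return aicc(self.llf, self.k_params, self.n_obs)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame({
            "low": self.params - z * self.bse,
            "high": self.params + z * self.bse,
        })

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fitted probabilities at the conditional modes."""
        eta = self.model._eta(self.params.to_numpy(), self.cond_modes,
                              self._sigma_vector())
        return 1.0 / (1.0 + np.exp(-eta))

    def _sigma_vector(self) -> np.ndarray:
        return self.vc_sd.to_numpy() if len(self.vc_sd) else np.empty(0)

    def random_effects(self, term: str) -> pd.Series:
        """BLUPs (conditional modes x sigma) for one random term."""
        for k, t in enumerate(self.model.random_terms):
            if t.name == term:
                o = self.model._offsets[k]
                u = self.vc_sd.iloc[k] * self.cond_modes[o:o + t.n_levels]
                return pd.Series(u, index=list(t.labels))
        raise KeyError(f"no random term named {term!r}")

    def species_effects(self, predictor: str,
                        group: str = "species") -> pd.Series:
        """Per-group effect of ``predictor``: fixed slope + group BLUP."""
        blup = self.random_effects(f"{predictor}|{group}")
        return blup + float(self.params[predictor])

    # -- simulation ------------------------------------------------------
    def simulate(self, n_sims: int, seed: int = 0,
                 conditional: bool = False) -> np.ndarray:
        """Draw ``n_sims`` response vectors from the fitted model.

        By default random effects are re-drawn from their estimated
        distributions (marginal simulation); with ``conditional=True``
        they are held at their conditional modes, so only Bernoulli noise
        varies - observations are then independent across rows, which is
        what the quantile-residual diagnostics require.  Returns an
        (n_sims, n_obs) 0/1 matrix.
        """
        m = self.model
        if n_sims == 0:
            return np.empty((0, m.n_obs))
        rng = np.random.default_rng(seed)
        sigma = self._sigma_vector()
        beta = self.params.to_numpy()
        out = np.empty((n_sims, m.n_obs))
        if conditional:
            p = self.fittedvalues
            for r in range(n_sims):
                out[r] = rng.random(m.n_obs) < p
            return out
        base = m.exog @ beta
        for r in range(n_sims):
            eta = base.copy()
            for k, t in enumerate(m.random_terms):
                u = rng.standard_normal(t.n_levels) * sigma[k]
                eta += t.column_values() * u[t.codes]
            p = 1.0 / (1.0 + np.exp(-eta))
            out[r] = rng.random(m.n_obs) < p
        return out

    # -- presentation ----------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-serializable fit summary (estimates, SEs, variances,
        log-likelihood and the AICc inputs)."""
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "vc_sd": {k: float(v) for k, v in self.vc_sd.items()},
            "loglik": float(self.llf),
            "k_params": int(self.k_params),
            "n_obs": int(self.n_obs),
            "aicc": float(self.aicc),
            "converged": bool(self.converged),
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = ["Binomial mixed model (Laplace)",
                 f"  n_obs {self.n_obs}   logLik {self.llf:.3f}   "
                 f"AICc {self.aicc:.3f}",
                 "", "Fixed effects (logit scale):",
                 f"  {'term':<18}{'est':>10}{'se':>10}"
                 f"{'ci_low':>10}{'ci_high':>10}"]
        for name in self.params.index:
            lines.append(
                f"  {name:<18}{self.params[name]:>10.4f}"
                f"{self.bse[name]:>10.4f}{ci.loc[name, 'low']:>10.4f}"
                f"{ci.loc[name, 'high']:>10.4f}")
        lines += ["", "Random-effect standard deviations:"]
        for name, sd in self.vc_sd.items():
            lines.append(f"  {name:<28}{sd:>10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# random slopes
# ---------------------------------------------------------------------------

def fit_random_slope(predictor: str, data,
                     fixed: Sequence[str] = PREDICTORS,
                     group: str = "species",
                     start_sd=None) -> MixedModelResults:
    """Global model plus an uncorrelated random slope for one predictor.

    The fixed structure stays the full global model; the added term lets the
    predictor's effect vary by species.  ``results.species_effects(pred)``
    gives fixed slope + species deviation - the species-level effects.
    Raises :class:`ConvergenceError` when the fit does not converge (slope
    models can legitimately fail when species' responses barely vary).
    """
    model = BinomialMixedModel.from_table(
        data, fixed=fixed, random_slope=(predictor, group))
    try:
        return model.fit(start_sd=start_sd)
    except ConvergenceError as exc:
        raise ConvergenceError(
            f"random-slope model for {predictor!r} did not converge "
            "(this can occur when between-species variation in the slope "
            "is negligible)", exc.trace) from exc


# ---------------------------------------------------------------------------
# simulation-based residual diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Simulation-based residual diagnostics (DHARMa-style)."""

    ks_statistic: float
    ks_uniformity_p: float
    dispersion_ratio: float
    dispersion_p: float
    outlier_fraction: float
    outlier_p: float
    zero_inflation_ratio: float
    zero_inflation_p: float
    vif: Optional[pd.Series] = None

    def to_dict(self) -> dict:
        d = {
            "ks_statistic": self.ks_statistic,
            "ks_uniformity_p": self.ks_uniformity_p,
            "dispersion_ratio": self.dispersion_ratio,
            "dispersion_p": self.dispersion_p,
            "outlier_fraction": self.outlier_fraction,
            "outlier_p": self.outlier_p,
            "zero_inflation_ratio": self.zero_inflation_ratio,
            "zero_inflation_p": self.zero_inflation_p,
        }
        if self.vif is not None:
            d["vif"] = {k: float(v) for k, v in self.vif.items()}
        return d


def _sim_envelope_p(observed: float, simulated: np.ndarray) -> float:
    """Two-sided Monte Carlo p-value of an observed statistic."""
    n = len(simulated)
    ge = (np.count_nonzero(simulated >= observed) + 1) / (n + 1)
    le = (np.count_nonzero(simulated <= observed) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(ge, le)))


def residual_diagnostics(results: MixedModelResults, n_sims: int = 250,
                         seed: int = 0, observed=None) -> DiagnosticsReport:
    """Quantile-residual diagnostics from model simulations.

    Each observation's randomized quantile residual is its empirical
    quantile within ``n_sims`` simulated responses (ties broken uniformly).
    For a correctly specified model the residuals are uniform: tested by
    Kolmogorov-Smirnov.  Dispersion compares the variance of observed
    raw residuals with the simulated distribution of that variance;
    zero inflation compares observed zero counts to simulated ones; the
    outlier test counts observations outside their simulation range.

    Simulations are conditional on the estimated random effects: with
    marginal simulations, observations sharing a group level would share
    re-drawn effects, making the residuals strongly dependent and the
    uniformity test badly anti-conservative for grouped binary data.

    ``observed`` overrides the fitted responses, to diagnose the fitted
    model against a different realization of the same design.
    """
    y = results.model.endog if observed is None \
        else np.asarray(observed, dtype=float)
    sims = results.simulate(n_sims, seed=seed, conditional=True)
    rng = np.random.default_rng(seed + 1)
    n_zero = (sims == 0).sum(axis=0)
    p_zero = n_zero / n_sims  # per-observation P(sim = 0)
    # randomized rank of the observation among the simulations: exactly
    # uniform under a correctly specified model, even at finite n_sims
    below = np.where(y == 1, n_zero, 0)
    equal = np.where(y == 1, n_sims - n_zero, n_zero)
    resid = (below + rng.random(len(y)) * (equal + 1)) / (n_sims + 1)
    ks = stats.kstest(resid, "uniform")

    # dispersion: variance of residuals around the simulation mean; each
    # simulation is scored against the mean of the *other* simulations so
    # that observed and simulated statistics are comparable
    expectation = sims.mean(axis=0)
    disp_obs = float(np.var(y - expectation))
    loo = (n_sims * expectation[None, :] - sims) / max(n_sims - 1, 1)
    disp_sims = np.var(sims - loo, axis=1)
    disp_ratio = disp_obs / float(np.mean(disp_sims))
    disp_p = _sim_envelope_p(disp_obs, disp_sims)

    # outliers: observed value never produced by the simulations; for a
    # Bernoulli response the expected rate is the chance that all n_sims
    # draws land on the other side, estimated from the simulations
    smin, smax = sims.min(axis=0), sims.max(axis=0)
    out_n = int(np.count_nonzero((y < smin) | (y > smax)))
    out_frac = out_n / len(y)
    rate = float(np.mean(p_zero ** n_sims * (1.0 - p_zero)
                         + (1.0 - p_zero) ** n_sims * p_zero))
    if rate <= 0.0:
        out_p = 1.0 if out_n == 0 else 0.0
    else:
        out_p = float(stats.binomtest(out_n, len(y), rate).pvalue)

    zeros_obs = float(np.count_nonzero(y == 0))
    zeros_sims = (sims == 0).sum(axis=1).astype(float)
    mean_zero = float(np.mean(zeros_sims))
    zi_ratio = zeros_obs / mean_zero if mean_zero > 0 else np.inf
    zi_p = _sim_envelope_p(zeros_obs, zeros_sims)

    return DiagnosticsReport(
        ks_statistic=float(ks.statistic), ks_uniformity_p=float(ks.pvalue),
        dispersion_ratio=float(disp_ratio), dispersion_p=disp_p,
        outlier_fraction=float(out_frac), outlier_p=out_p,
        zero_inflation_ratio=float(zi_ratio), zero_inflation_p=zi_p)


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

def variance_inflation(data, predictors: Sequence[str] = PREDICTORS,
                       flag_threshold: float = 2.0) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j).

    R^2_j comes from the linear regression (with intercept) of predictor j
    on the others.  Perfectly collinear predictors get ``inf``.  A warning
    is emitted for any VIF at or above ``flag_threshold`` (the analysis
    requires VIF < 2).
    """
    if isinstance(data, StandardizedTable):
        data = data.data
    preds = list(predictors)
    if len(preds) < 2:
        raise ValueError("need at least two predictors for VIF")
    Xall = np.column_stack([data[p].to_numpy(dtype=float) for p in preds])
    out = {}
    n = Xall.shape[0]
    for j, name in enumerate(preds):
        yj = Xall[:, j]
        Xj = np.column_stack(
            [np.ones(n)] + [Xall[:, k] for k in range(len(preds)) if k != j])
        coef, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ coef
        tss = float(np.sum((yj - yj.mean()) ** 2))
        rss = float(np.sum(resid ** 2))
        if tss == 0.0:
            out[name] = np.inf
            continue
        r2 = 1.0 - rss / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(out)
    high = vif[vif >= flag_threshold]
    if len(high):
        warnings.warn(
            "high collinearity (VIF >= "
            f"{flag_threshold}): {', '.join(high.index)}", stacklevel=2)
    return vif
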