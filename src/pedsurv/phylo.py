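"""Pagel's lambda: phylogenetic signal of a species-level trait.

Under Brownian motion on a rooted tree, the trait covariance between two
species equals the shared branch length from the root to their most recent
common ancestor.  Pagel's lambda multiplies the off-diagonal entries of
that covariance by a factor in [0, 1]: lambda = 0 is a star phylogeny (no
signal), lambda = 1 full Brownian structure.  The likelihood is Gaussian
with analytic profile over the mean and rate, leaving a bounded 1-D
optimization in lambda; significance comes from a likelihood-ratio test of
lambda = 0 with the boundary-corrected null (an equal mixture of a point
mass at zero and chi-square with 1 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "read_newick",
    "tree_covariance",
    "lambda_covariance",
    "PagelLambda",
    "PagelLambdaResults",
    "fit_lambda",
    "signal_for_random_slopes",
]


def read_newick(path_or_string, is_path: Optional[bool] = None
                ) -> dendropy.Tree:
    """Parse a rooted Newick tree; tips must be uniquely labelled.

    Missing branch lengths are replaced by unit lengths with a warning
    (topology-only trees are common for published phylogenies).
    """
    src = str(path_or_string)
    if is_path is None:
        is_path = not src.strip().startswith("(")
    try:
        if is_path:
            tree = dendropy.Tree.get(path=src, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=src, schema="newick",
                                     preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"malformed Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip label(s): {sorted(dupes)}")
    missing = [e for e in tree.preorder_edge_iter()
               if e.head_node is not tree.seed_node and e.length is None]
    if missing:
        warnings.warn(
            f"{len(missing)} branch length(s) missing; using unit lengths")
        for e in missing:
            e.length = 1.0
    for e in tree.preorder_edge_iter():
        if e.length is None:
            e.length = 0.0
    return tree


def tree_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance: shared root-to-MRCA path lengths."""
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(node.parent_node, 0.0)
        depth[node] = parent_depth + (node.edge.length or 0.0)
    n = len(leaves)
    C = np.empty((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for i in range(n):
        C[i, i] = depth[leaves[i]]
        for j in range(i + 1, n):
            mrca = pdm.mrca(leaves[i].taxon, leaves[j].taxon)
            C[i, j] = C[j, i] = depth[mrca]
    return labels, C


def lambda_covariance(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of a BM covariance by lambda in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


@dataclass
class PagelLambdaResults:
    """Maximum-likelihood lambda with its likelihood-ratio test.

    ``identifiable`` is False on a star phylogeny (likelihood flat in
    lambda), in which case ``lambda_hat`` is NaN and the test degenerate.
    """

    lambda_hat: float
    loglik_ml: float
    loglik_lambda0: float
    lrt_stat: float
    p_value: float
    mean: float
    rate: float
    n_tips: int
    identifiable: bool = True

    def summary(self) -> str:
        if not self.identifiable:
            return ("Pagel's lambda: unidentifiable (star phylogeny - "
                    "likelihood flat in lambda)")
        return (f"Pagel's lambda = {self.lambda_hat:.6g} "
                f"(logLik {self.loglik_ml:.4f}; "
                f"logLik[lambda=0] {self.loglik_lambda0:.4f}; "
                f"LRT {self.lrt_stat:.4f}, p = {self.p_value:.4g}, "
                f"n = {self.n_tips})")


class PagelLambda:
    """Model object for phylogenetic signal of one species-level trait.

    Parameters
    ----------
    tree
        A rooted dendropy tree (or Newick path/string).
    trait
        Mapping or Series of trait values keyed by tip label; every trait
        species must be a tip of the tree.
    """

    def __init__(self, tree, trait):
        if not isinstance(tree, dendropy.Tree):
            tree = read_newick(tree)
        self.tree = tree
        labels, C = tree_covariance(tree)
        trait = pd.Series(trait, dtype=float)
        missing = [s for s in trait.index if s not in labels]
        if missing:
            raise ValueError(
                f"species not among tree tips: {sorted(missing)}")
        # restrict the tree covariance to the trait's species
        idx = [labels.index(s) for s in trait.index]
        self.species = list(trait.index)
        self.C = C[np.ix_(idx, idx)]
        self.y = trait.to_numpy()
        if len(self.y) < 4:
            raise ValueError("need >= 4 species to estimate lambda")

    def _profile_loglik(self, lam: float) -> tuple[float, float, float]:
        """Profile log-likelihood at lambda (mean and rate analytic)."""
        V = lambda_covariance(self.C, lam)
        n = len(self.y)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular phylogenetic covariance (zero-length terminal "
                "branches?)")
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        ones = np.ones(n)
        Vi_y = np.linalg.solve(L.T, np.linalg.solve(L, self.y))
        Vi_1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
        mu = float(ones @ Vi_y) / float(ones @ Vi_1)
        r = self.y - mu * ones
        Vi_r = Vi_y - mu * Vi_1
        quad = float(r @ Vi_r)
        if quad <= 0.0:
            raise np.linalg.LinAlgError(
                "degenerate trait (no residual variance)")
        sig2 = quad / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sig2) + logdet + n)
        return ll, mu, sig2

    def fit(self, tol: float = 1e-8) -> PagelLambdaResults:
        """Bounded 1-D ML over lambda in [0, 1] + boundary-corrected LRT."""
        grid = np.linspace(0.0, 1.0, 11)
        grid_ll = np.array([self._profile_loglik(g)[0] for g in grid])
        if grid_ll.max() - grid_ll.min() < 1e-9:
            # star phylogeny or equivalent: likelihood flat in lambda
            ll0, mu, sig2 = self._profile_loglik(0.0)
            return PagelLambdaResults(
                lambda_hat=np.nan, loglik_ml=ll0, loglik_lambda0=ll0,
                lrt_stat=0.0, p_value=1.0, mean=mu, rate=sig2,
                n_tips=len(self.y), identifiable=False)
        res = optimize.minimize_scalar(
            lambda g: -self._profile_loglik(g)[0],
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": tol})
        lam = float(res.x)
        ll_ml, mu, sig2 = self._profile_loglik(lam)
        # the bounded optimizer avoids the exact endpoints; snap if better
        for endpoint, ll_end in ((0.0, grid_ll[0]), (1.0, grid_ll[-1])):
            if ll_end > ll_ml:
                lam, ll_ml = endpoint, ll_end
                _, mu, sig2 = self._profile_loglik(endpoint)
        ll0 = float(grid_ll[0])
        lrt = max(0.0, 2.0 * (ll_ml - ll0))
        # null: 50:50 mixture of point mass at 0 and chi2(1) (lambda = 0
        # lies on the parameter boundary)
        p = 1.0 if lrt == 0.0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
        return PagelLambdaResults(
            lambda_hat=lam, loglik_ml=ll_ml, loglik_lambda0=ll0,
            lrt_stat=lrt, p_value=p, mean=mu, rate=sig2,
            n_tips=len(self.y))


def fit_lambda(tree, trait) -> PagelLambdaResults:
    """Convenience wrapper: ``PagelLambda(tree, trait).fit()``."""
    return PagelLambda(tree, trait).fit()


def signal_for_random_slopes(slopes: pd.DataFrame, tree) -> pd.DataFrame:
    """Lambda fit per predictor on a species x predictor slope table.

    ``slopes`` rows are species (matching tree tips), columns predictors
    (species-level effects from the random-slope models).  Columns that are
    entirely missing - e.g. a predictor whose random-slope model failed to
    converge - are skipped with a note in the output.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    rows = []
    for pred in slopes.columns:
        col = slopes[pred]
        if col.isna().all():
            rows.append({"predictor": pred, "lambda": np.nan,
                         "loglik": np.nan, "lrt": np.nan, "p_value": np.nan,
                         "note": "skipped: no slope estimates"})
            continue
        try:
            res = PagelLambda(tree, col.dropna()).fit()
        except np.linalg.LinAlgError as exc:
            # e.g. species effects (numerically) constant: no signal to fit
            rows.append({"predictor": pred, "lambda": np.nan,
                         "loglik": np.nan, "lrt": np.nan,
                         "p_value": np.nan,
                         "note": f"not estimable: {exc}"})
            continue
        rows.append({"predictor": pred, "lambda": res.lambda_hat,
                     "loglik": res.loglik_ml, "lrt": res.lrt_stat,
                     "p_value": res.p_value,
                     "note": "" if res.identifiable else "unidentifiable"})
    return pd.DataFrame(rows).set_index("predictor")
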