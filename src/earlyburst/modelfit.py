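"""Maximum-likelihood fitting of BM and single-optimum OU trait models.

Both models induce a multivariate normal distribution over tip values.
Under Brownian motion the covariance of tips i and j is ``sigma2 *
s_ij`` with ``s_ij`` the shared root-to-MRCA path length.  Under the
root-at-optimum Ornstein-Uhlenbeck model (theta fixed at the root state
z0, the convention of the classical comparative-methods fitting
functions) the covariance is

    V_ij = sigma2/(2 alpha) (1 - e^{-2 alpha s_ij})
           e^{-alpha (d_i + d_j - 2 s_ij)}

which on an ultrametric tree depends only on ``s_ij`` and is exactly
the BM covariance of a tree whose node heights are warped by
``h(s) = (e^{-2 alpha (T - s)} - e^{-2 alpha T})/(2 alpha)``.  Two
likelihood evaluators are provided: a dense-covariance one (reference)
and an O(n) Felsenstein-pruning one (default); for OU the pruning path
runs BM pruning on the warped tree.

Model scoring uses AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1) with k = 2 for
BM (sigma2, z0) and k = 3 for OU (sigma2, alpha, z0 = theta).

The module follows the statsmodels idiom: build a
:class:`TraitEvolutionModel` from a tree and tip data, call ``fit()``,
and read estimates off the returned :class:`TraitEvolutionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .tree import TimeTree, TreeError

__all__ = [
    "TraitEvolutionModel",
    "TraitEvolutionResults",
    "ModelComparisonTable",
    "bm_loglik",
    "ou_loglik",
    "fit_model",
    "compare_over_trees",
    "aicc",
]

_ALPHA_BM_LIMIT = 1e-9
LOG2PI = np.log(2.0 * np.pi)


def aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------
# likelihood evaluation


def _warped_ages(tree: TimeTree, alpha: float) -> np.ndarray:
    """OU-to-BM node-height warp h(s) on an ultrametric tree."""
    T = tree.crown_age
    if alpha < _ALPHA_BM_LIMIT:
        return tree.age
    return (np.exp(-2.0 * alpha * (T - tree.age)) - np.exp(-2.0 * alpha * T)) / (
        2.0 * alpha
    )


def _pruning_pieces(tree: TimeTree, x: np.ndarray, ages: np.ndarray):
    """Felsenstein pruning on (possibly warped) node heights.

    Returns (logdet_C, Q_contrasts, z0_hat, v_root): the log determinant
    of the sigma2=1 covariance, the sum of squared standardized
    contrasts, the GLS root estimate and its variance factor.
    """
    n = tree.n_nodes
    V = np.zeros(n)
    X = np.zeros(n)
    pos = {int(t): j for j, t in enumerate(tree.tip_ids)}
    bl = np.zeros(n)
    bl[1:] = ages[1:] - ages[tree.parent[1:]]
    logdet = 0.0
    Q = 0.0
    for v in tree.postorder():
        ch = tree.children(v)
        if not ch:
            X[v] = x[pos[v]]
            V[v] = 0.0
            continue
        c1, c2 = ch
        V1 = V[c1] + bl[c1]
        V2 = V[c2] + bl[c2]
        s = V1 + V2
        if s <= 0:
            raise np.linalg.LinAlgError(
                "zero contrast variance: duplicate zero-length tips"
            )
        logdet += np.log(s)
        Q += (X[c1] - X[c2]) ** 2 / s
        X[v] = (V2 * X[c1] + V1 * X[c2]) / s
        V[v] = V1 * V2 / s
    logdet += np.log(V[0])
    return logdet, Q, X[0], V[0]


def _loglik_pruning(tree, x, sigma2, z0, ages) -> float:
    n = tree.n_tips
    logdet, Q, z0_hat, v_root = _pruning_pieces(tree, x, ages)
    Qtot = Q + (z0_hat - z0) ** 2 / v_root
    return -0.5 * (n * (LOG2PI + np.log(sigma2)) + logdet + Qtot / sigma2)


def _bm_cov(tree: TimeTree) -> np.ndarray:
    return tree.mrca_age_matrix()


def _ou_cov(tree: TimeTree, alpha: float) -> np.ndarray:
    """Unit-sigma2 OU covariance from the general (non-warped) formula."""
    s = tree.mrca_age_matrix()
    d = tree.age[tree.tip_ids]
    if alpha < _ALPHA_BM_LIMIT:
        return s
    dd = d[:, None] + d[None, :] - 2.0 * s
    return (1.0 - np.exp(-2.0 * alpha * s)) / (2.0 * alpha) * np.exp(-alpha * dd)


def _loglik_dense(C: np.ndarray, x: np.ndarray, sigma2: float, z0: float) -> float:
    n = len(x)
    L = np.linalg.cholesky(sigma2 * C)
    resid = x - z0
    u = np.linalg.solve(L, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (n * LOG2PI + logdet + float(u @ u))


def bm_loglik(tree: TimeTree, traits, sigma2: float, z0: float, method="pruning"):
    """Brownian-motion log-likelihood of tip values."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    x = _as_vector(tree, traits)
    if method == "pruning":
        return _loglik_pruning(tree, x, sigma2, z0, tree.age)
    return _loglik_dense(_bm_cov(tree), x, sigma2, z0)


def ou_loglik(
    tree: TimeTree, traits, sigma2: float, alpha: float, z0: float, method="pruning"
):
    """Root-at-optimum OU log-likelihood (theta = z0) of tip values."""
    if sigma2 <= 0 or alpha < 0:
        raise ValueError("require sigma2 > 0 and alpha >= 0")
    x = _as_vector(tree, traits)
    if method == "pruning":
        if not tree.is_ultrametric():
            raise TreeError("pruning OU evaluation requires an ultrametric tree")
        return _loglik_pruning(tree, x, sigma2, z0, _warped_ages(tree, alpha))
    return _loglik_dense(_ou_cov(tree, alpha), x, sigma2, z0)


def _as_vector(tree: TimeTree, traits) -> np.ndarray:
    x = np.asarray(traits, dtype=float) if not hasattr(traits, "keys") else None
    if x is not None and x.ndim == 1 and len(x) == tree.n_tips:
        return x
    return tree.tip_values(traits)


# ---------------------------------------------------------------------
# model objects


class TraitEvolutionModel:
    """ML model for continuous trait evolution on an ultrametric tree.

    Parameters
    ----------
    tree : TimeTree
    traits : vector / mapping / pandas Series of tip values
    kind : {"bm", "ou"}
    """

    def __init__(self, tree: TimeTree, traits, kind: str = "bm"):
        if kind not in ("bm", "ou"):
            raise ValueError("kind must be 'bm' or 'ou'")
        if tree.n_tips < 4:
            raise ValueError("need at least 4 tips to fit a trait model")
        self.tree = tree
        self.x = _as_vector(tree, traits)
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite trait values")
        self.kind = kind

    @classmethod
    def from_dataframe(cls, tree: TimeTree, frame, trait: str, kind: str = "bm"):
        """Build from a species-by-trait DataFrame; tips with missing
        values for ``trait`` are dropped from the tree (never imputed)."""
        col = frame[trait]
        have = [l for l in tree.tip_labels if l in col.index and np.isfinite(col[l])]
        dropped = sorted(set(tree.tip_labels) - set(have))
        if dropped:
            import logging

            logging.getLogger(__name__).warning(
                "dropping %d tips without %s values: %s", len(dropped), trait, dropped
            )
            tree = tree.induced(have)
        return cls(tree, col.loc[tree.tip_labels].to_numpy(), kind=kind)

    # profile likelihood: for fixed alpha, z0_hat is the GLS mean and
    # sigma2_hat = Q(z0_hat) / n, both free by-products of pruning
    def _profile(self, alpha: float):
        ages = self.tree.age if alpha == 0.0 else _warped_ages(self.tree, alpha)
        logdet, Q, z0_hat, v_root = _pruning_pieces(self.tree, self.x, ages)
        n = self.tree.n_tips
        sigma2_hat = Q / n
        if sigma2_hat <= 0:
            raise np.linalg.LinAlgError("degenerate data: zero profile sigma2")
        ll = -0.5 * (n * (LOG2PI + np.log(sigma2_hat)) + logdet + n)
        return ll, sigma2_hat, z0_hat

    def loglike(self, sigma2: float, z0: float, alpha: float = 0.0) -> float:
        if self.kind == "bm":
            return bm_loglik(self.tree, self.x, sigma2, z0)
        return ou_loglik(self.tree, self.x, sigma2, alpha, z0)

    def fit(
        self,
        alpha_bounds=(1e-8, 10.0),
        n_starts: int = 12,
    ) -> "TraitEvolutionResults":
        n = self.tree.n_tips
        if self.kind == "bm":
            ll, s2, z0 = self._profile(0.0)
            return TraitEvolutionResults(
                model=self, kind="bm", sigma2=s2, alpha=None, z0=z0,
                loglik=ll, k=2, n=n, converged=True,
            )
        lo, hi = alpha_bounds
        grid = np.geomspace(lo, hi, n_starts)
        prof = []
        for a in grid:
            try:
                prof.append(self._profile(a)[0])
            except np.linalg.LinAlgError:
                prof.append(-np.inf)
        best = int(np.argmax(prof))
        # bounded refinement around the best grid point (log scale)
        left = grid[max(best - 1, 0)]
        right = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda u: -self._profile(float(np.exp(u)))[0],
            bounds=(np.log(left), np.log(right)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        alpha_hat = float(np.exp(res.x))
        ll, s2, z0 = self._profile(alpha_hat)
        # the BM boundary (alpha -> 0) may dominate: OU nests BM exactly
        ll0, s20, z00 = self._profile(0.0)
        if ll0 >= ll:
            alpha_hat, ll, s2, z0 = 0.0, ll0, s20, z00
        return TraitEvolutionResults(
            model=self, kind="ou", sigma2=s2, alpha=alpha_hat, z0=z0,
            loglik=ll, k=3, n=n, converged=bool(res.success),
        )


@dataclass
class TraitEvolutionResults:
    """ML estimates, likelihood and AICc for one trait/tree/model."""

    model: TraitEvolutionModel
    kind: str
    sigma2: float
    alpha: Optional[float]
    z0: float
    loglik: float
    k: int
    n: int
    converged: bool

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    @property
    def params(self) -> dict:
        out = {"sigma2": self.sigma2, "z0": self.z0}
        if self.kind == "ou":
            out["alpha"] = self.alpha
        return out

    def summary(self) -> str:
        lines = [
            f"Trait evolution model: {self.kind.upper()}"
            f"  (n tips = {self.n}, k = {self.k})",
            f"  sigma2 = {self.sigma2:.6g}",
        ]
        if self.kind == "ou":
            lines.append(f"  alpha  = {self.alpha:.6g}  (theta = z0)")
        lines += [
            f"  z0     = {self.z0:.6g}",
            f"  lnL    = {self.loglik:.4f}",
            f"  AICc   = {self.aicc:.4f}",
            f"  converged: {self.converged}",
        ]
        return "\n".join(lines)


def fit_model(tree: TimeTree, traits, kind: str = "bm") -> TraitEvolutionResults:
    """Functional wrapper: fit one model to one tree and trait vector."""
    return TraitEvolutionModel(tree, traits, kind=kind).fit()


# ---------------------------------------------------------------------
# batch comparison across a tree sample


@dataclass
class ModelComparisonTable:
    """Median estimates and AICc preference counts across trees.

    Mirrors the classic per-trait model-comparison table: medians of
    sigma2, alpha, lnL and AICc per model (medians are robust to
    occasional outlier fits), and the number of trees for which each
    model had the lower AICc.
    """

    kinds: tuple
    medians: dict
    n_preferring: dict
    n_trees: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for kind in self.kinds:
            m = self.medians[kind]
            rows.append(
                {
                    "model": kind.upper(),
                    "sigma2": m["sigma2"],
                    "alpha": m.get("alpha", np.nan),
                    "lnL": m["loglik"],
                    "AICc": m["aicc"],
                    "n_preferred": self.n_preferring[kind],
                }
            )
        return pd.DataFrame(rows).set_index("model")

    def summary(self) -> str:
        return self.to_frame().to_string(float_format=lambda v: f"{v:.3f}")


def compare_over_trees(
    trees: Sequence[TimeTree], traits, kinds=("bm", "ou")
) -> ModelComparisonTable:
    """Fit each model on every tree and tabulate medians and AICc wins.

    ``traits`` is a mapping/Series by species; tips missing from it are
    dropped per tree with a logged warning.
    """
    import pandas as pd

    series = traits if isinstance(traits, pd.Series) else pd.Series(traits)
    per_kind = {k: [] for k in kinds}
    wins = {k: 0 for k in kinds}
    for tree in trees:
        have = [l for l in tree.tip_labels if l in series.index and np.isfinite(series[l])]
        t = tree if len(have) == tree.n_tips else tree.induced(have)
        fits = {k: TraitEvolutionModel(t, series, kind=k).fit() for k in kinds}
        for k, f in fits.items():
            per_kind[k].append(f)
        best = min(kinds, key=lambda k: fits[k].aicc)
        wins[best] += 1
    medians = {}
    for k, fs in per_kind.items():
        medians[k] = {
            "sigma2": float(np.median([f.sigma2 for f in fs])),
            "loglik": float(np.median([f.loglik for f in fs])),
            "aicc": float(np.median([f.aicc for f in fs])),
        }
        if k == "ou":
            medians[k]["alpha"] = float(np.median([f.alpha for f in fs]))
    return ModelComparisonTable(
        kinds=tuple(kinds), medians=medians, n_preferring=wins, n_trees=len(trees)
    )
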