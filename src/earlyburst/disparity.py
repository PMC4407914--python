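"""Disparity-through-time curves, null envelopes and the MDI statistic.

Disparity of a set of species is the mean squared pairwise Euclidean
distance between their trait values.  The DTT curve tracks, at each
divergence time of the chronogram, the average disparity of the
lineages alive just before that divergence, each taken relative to the
disparity of the whole clade; the curve opens at (0, 1).  The
morphological disparity index (MDI) is the signed area between an
observed DTT curve and the median curve of a set of null simulations
(conventionally Brownian motion), integrated over the first
``t_max`` fraction of the tree's history (default 0.9, discounting tip
overdispersion near the present).

Curves are right-continuous step functions; areas are exact step areas,
never trapezoids.  Node-age ties are merged into a single time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .tree import TimeTree, TreeError
from .traitsim import TraitModel, simulate_trait_matrix

__all__ = [
    "DTTCurve",
    "MDIResult",
    "disparity",
    "dtt_curve",
    "null_envelope",
    "mdi",
    "dtt_mdi",
]


@dataclass(frozen=True)
class DTTCurve:
    """Step curve of average relative subclade disparity.

    ``times`` are relative (node ages divided by the crown age, root at
    0), ``values`` the curve levels on [t_i, t_{i+1}).
    """

    times: np.ndarray
    values: np.ndarray
    crown_age: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(t) == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, t) -> np.ndarray:
        """Right-continuous evaluation at relative time(s) ``t``."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.values[np.clip(idx, 0, len(self.values) - 1)]


@dataclass(frozen=True)
class MDIResult:
    """MDI of an observed curve against a simulated null envelope."""

    mdi: float
    t_max: float
    n_null: int
    observed: DTTCurve
    null_median: DTTCurve
    null_q05: DTTCurve
    null_q95: DTTCurve


def disparity(values) -> float:
    """Mean squared pairwise Euclidean distance.

    ``values`` is a 1-d vector or an (n, d) matrix of species-by-trait
    values.  Returns 0 for fewer than two rows.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.ndim(values) == 1:
        x = x.T
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    n = x.shape[0]
    if n < 2:
        return 0.0
    # sum_{i<j} |xi-xj|^2 = n sum x^2 - |sum x|^2, per dimension
    num = float(np.sum(n * np.sum(x * x, axis=0) - np.sum(x, axis=0) ** 2))
    return num / (n * (n - 1) / 2.0)


def _tip_matrix(tree: TimeTree, traits) -> np.ndarray:
    """Coerce traits to an (n_tips, d) array in tip-id order."""
    import pandas as pd

    if isinstance(traits, pd.DataFrame):
        missing = [l for l in tree.tip_labels if l not in traits.index]
        if missing:
            raise TreeError(f"missing trait values for tips: {missing}")
        return traits.loc[tree.tip_labels].to_numpy(dtype=float)
    if isinstance(traits, (dict, pd.Series)):
        return tree.tip_values(traits)[:, None]
    x = np.asarray(traits, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != tree.n_tips:
        raise TreeError("trait array length does not match tip count")
    return x


def _node_stats(tree: TimeTree, X: np.ndarray):
    """Per-node tip count and disparity numerators for columns of X.

    X has shape (n_tips, m); returns (counts (n_nodes,), disp (n_nodes, m))
    where disp[v] is the disparity of the tips under node v, per column.
    """
    n_nodes, m = tree.n_nodes, X.shape[1]
    cnt = np.zeros(n_nodes, dtype=np.int64)
    S = np.zeros((n_nodes, m))
    Q = np.zeros((n_nodes, m))
    pos = {int(t): j for j, t in enumerate(tree.tip_ids)}
    for v in tree.postorder():
        ch = tree.children(v)
        if not ch:
            j = pos[v]
            cnt[v] = 1
            S[v] = X[j]
            Q[v] = X[j] * X[j]
        else:
            cnt[v] = cnt[ch[0]] + cnt[ch[1]]
            S[v] = S[ch[0]] + S[ch[1]]
            Q[v] = Q[ch[0]] + Q[ch[1]]
    disp = np.zeros((n_nodes, m))
    mask = cnt >= 2
    nn = cnt[mask].astype(float)[:, None]
    disp[mask] = (nn * Q[mask] - S[mask] ** 2) / (nn * (nn - 1) / 2.0)
    return cnt, disp


def _dtt_values_matrix(tree: TimeTree, X: np.ndarray):
    """DTT curves for each column of X on the merged node-age grid.

    Returns (rel_times (k,), values (k, m)).  Column-wise the trait is
    treated as univariate; for a multivariate DTT pass a single column
    through :func:`dtt_curve` instead.
    """
    if not tree.is_ultrametric():
        raise TreeError("DTT requires an ultrametric tree")
    _, disp = _node_stats(tree, X)
    return _dtt_many_from_disp(tree, disp)


def dtt_curve(tree: TimeTree, traits) -> DTTCurve:
    """Observed DTT curve of one (possibly multivariate) trait set.

    Columns of a matrix are treated as dimensions of one trait space
    (squared distances add across dimensions), producing a single curve.
    """
    if not tree.is_ultrametric():
        raise TreeError("DTT requires an ultrametric tree")
    X = _tip_matrix(tree, traits)
    _, disp = _node_stats(tree, X)
    dsum = disp.sum(axis=1)
    if dsum[0] <= 0:
        raise ValueError("whole-clade disparity is zero; DTT undefined")
    return _dtt_from_node_disp(tree, dsum, dsum[0])


def _dtt_from_node_disp(tree: TimeTree, disp: np.ndarray, d_tot: float) -> DTTCurve:
    times, vals = _dtt_many_from_disp(tree, disp[:, None])
    return DTTCurve(times, vals[:, 0], tree.crown_age)


def null_envelope(
    tree: TimeTree,
    traits,
    model="fitted",
    n_sims: int = 100,
    seed=None,
    quantiles=(0.05, 0.95),
):
    """Median and quantile DTT curves under a simulated null model.

    ``model`` is a :class:`TraitModel`, or the string ``"fitted"`` (BM
    with ML parameters estimated from the observed traits) or
    ``"fitted-ou"`` (single-optimum OU, ML).  Curves are evaluated on
    the tree's node-age grid; quantiles are pointwise with linear
    interpolation between order statistics (numpy default, type 7).
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    X = _tip_matrix(tree, traits)
    if isinstance(model, str):
        from .modelfit import fit_model

        kind = "ou" if model == "fitted-ou" else "bm"
        if model not in ("fitted", "fitted-bm", "fitted-ou"):
            raise ValueError(f"unknown null model {model!r}")
        fits = [fit_model(tree, X[:, j], kind=kind) for j in range(X.shape[1])]
        models = [
            TraitModel(
                kind,
                sigma2=f.sigma2,
                alpha=getattr(f, "alpha", 0.0) or 0.0,
                theta=f.z0,
                x0=f.z0,
            )
            for f in fits
        ]
    else:
        models = [model] * X.shape[1]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = [
        simulate_trait_matrix(tree, m, (), rng, n_sims) for m in models
    ]
    if len(sims) == 1:
        times, vals = _dtt_values_matrix(tree, sims[0])
    else:
        # multivariate null: disparity numerators add across dimensions
        disp_total = None
        for s in sims:
            _, d = _node_stats(tree, s)
            disp_total = d if disp_total is None else disp_total + d
        times, vals = _dtt_many_from_disp(tree, disp_total)
    med = np.median(vals, axis=1)
    qlo = np.quantile(vals, quantiles[0], axis=1)
    qhi = np.quantile(vals, quantiles[1], axis=1)
    T = tree.crown_age
    return (
        DTTCurve(times, med, T),
        DTTCurve(times, qlo, T),
        DTTCurve(times, qhi, T),
    )


def _dtt_many_from_disp(tree: TimeTree, disp: np.ndarray):
    d_tot = disp[0]
    if np.any(d_tot <= 0):
        raise ValueError("whole-clade disparity is zero; DTT undefined")
    T = tree.crown_age
    internal = tree.internal_ids
    ages = tree.age[internal]
    order = np.lexsort((internal, ages))
    events = [(float(ages[i]), int(internal[i])) for i in order if internal[i] != 0]
    times = [0.0]
    values = [np.ones(disp.shape[1])]
    c1, c2 = tree.children(0)
    active_sum = disp[c1] + disp[c2]
    active_n = 2
    i = 0
    while i < len(events):
        t = events[i][0]
        values.append(active_sum / (active_n * d_tot))
        times.append(t / T)
        while i < len(events) and events[i][0] == t:
            v = events[i][1]
            a, b = tree.children(v)
            active_sum = active_sum - disp[v] + disp[a] + disp[b]
            active_n += 1
            i += 1
    return np.asarray(times), np.vstack(values)


def mdi(observed: DTTCurve, null_median: DTTCurve, t_max: float = 0.9) -> float:
    """Signed step-function area (observed - null) over [0, t_max]."""
    if not 0 < t_max <= 1:
        raise ValueError("t_max must be in (0, 1]")
    if abs(observed.crown_age - null_median.crown_age) > 1e-9 * max(
        observed.crown_age, 1.0
    ):
        raise ValueError("curves have mismatched crown ages")
    grid = np.union1d(observed.times, null_median.times)
    grid = np.append(grid[grid < t_max], t_max)
    diff = observed.at(grid[:-1]) - null_median.at(grid[:-1])
    return float(np.sum(diff * np.diff(grid)))


def _mdi_from_values(times, obs_vals, null_vals, t_max: float) -> float:
    """Fast path when both curves share one time grid."""
    grid = np.append(times[times < t_max], t_max)
    k = len(grid) - 1
    diff = obs_vals[:k] - null_vals[:k]
    return float(np.sum(diff * np.diff(grid)))


def dtt_mdi(
    tree: TimeTree,
    traits,
    model="fitted",
    n_sims: int = 100,
    t_max: float = 0.9,
    seed=None,
) -> MDIResult:
    """Observed DTT, null envelope and MDI in one call."""
    obs = dtt_curve(tree, traits)
    med, qlo, qhi = null_envelope(tree, traits, model=model, n_sims=n_sims, seed=seed)
    return MDIResult(
        mdi=mdi(obs, med, t_max=t_max),
        t_max=t_max,
        n_null=n_sims,
        observed=obs,
        null_median=med,
        null_q05=qlo,
        null_q95=qhi,
    )
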