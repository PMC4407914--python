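"""Stepwise AICc detection of diversification-rate shifts on diversity
trees.

A *diversity tree* is an ultrametric phylogeny whose tips each stand
for a terminally unresolved clade carrying an extant species-richness
count.  Each diversification regime is parameterized by its net rate
``r = lambda - mu`` and turnover ``eps = mu / lambda``, and contributes
two kinds of log-likelihood terms:

* a *backbone* (phylogenetic) part for the resolved branching times:
  observed births along a surviving lineage at age ``t`` before present
  arrive at the thinned rate ``lambda * P(t)`` with
  ``P(t) = r / (lambda - mu e^{-r t})`` the survival probability, so an
  internal branch from age ``t1`` down to ``t2`` contributes
  ``-[ln(lambda e^{r t1} - mu) - ln(lambda e^{r t2} - mu)]`` (the exact
  integral of the thinned rate) and each internal node contributes
  ``ln(lambda P(t))``;
* an *unresolved-clade* (taxonomic) part for each tip: the classic
  geometric richness probability conditioned on survival,
  ``P(N = n | t) = (1 - beta) beta^{n-1}`` with
  ``beta = (e^{r t} - 1)/(e^{r t} - eps)`` and ``t`` the tip's stem age.

In the pure-birth case the two parts collapse to
``B ln(lambda) - lambda L`` (B births, L total branch length), whose
maximum is the closed-form Yule estimate ``B / L``.

The stepwise search starts from a single-regime model and greedily adds
the shift (placed on a branch; it applies from the branch's parent node
downwards, i.e. stemwards) that most improves AICc, stopping when no
candidate improves it.  A shift is retained on *any* AICc improvement;
each shift adds three parameters (r, eps, location), and the AICc
sample size is the number of internal nodes plus the number of tips
with richness above one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .tree import TimeTree, TreeError

__all__ = [
    "DiversityTree",
    "Regime",
    "ShiftModel",
    "RateShiftModel",
    "RateShiftResults",
    "unresolved_clade_loglik",
    "backbone_loglik",
    "fit_rate_shifts",
]

_R_BOUNDS = (1e-6, 10.0)
_EPS_BOUNDS = (0.0, 0.999)


class DiversityTree:
    """TimeTree plus an extant-richness count per tip."""

    def __init__(self, tree: TimeTree, richness):
        if not tree.is_ultrametric():
            raise TreeError("diversity tree must be ultrametric")
        self.tree = tree
        if hasattr(richness, "keys"):
            vals = [richness[l] for l in tree.tip_labels]
        else:
            vals = list(richness)
        arr = np.asarray(vals)
        if len(arr) != tree.n_tips:
            raise TreeError("richness length does not match tip count")
        if np.any(arr < 1) or np.any(arr != np.floor(arr)):
            raise TreeError("richness counts must be integers >= 1")
        self.richness = arr.astype(np.int64)

    @property
    def total_richness(self) -> int:
        return int(self.richness.sum())

    def __repr__(self):
        return (
            f"<DiversityTree {self.tree.n_tips} tips, "
            f"{self.total_richness} species>"
        )


def unresolved_clade_loglik(n: int, stem_age: float, r: float, epsilon: float) -> float:
    """log P(N = n | survival) for an unresolved clade of stem age t.

    Geometric in n with ``beta = (e^{rt} - 1)/(e^{rt} - eps)``; the
    critical limit r -> 0 uses ``beta = lambda t / (1 + lambda t)``.
    """
    if n < 1 or stem_age <= 0:
        raise ValueError("require n >= 1 and stem_age > 0")
    t = stem_age
    if abs(r) < 1e-10:
        lam = r / (1.0 - epsilon) if epsilon < 1 else np.nan
        if not np.isfinite(lam):
            raise ValueError("r = 0 with epsilon = 1 is degenerate")
        beta = lam * t / (1.0 + lam * t)
    else:
        ert = np.exp(r * t)
        if epsilon >= ert:
            raise ValueError("invalid turnover: epsilon >= e^{r t}")
        beta = (ert - 1.0) / (ert - epsilon)
    if beta <= 0:
        return 0.0 if n == 1 else -np.inf
    return float(np.log1p(-beta) + (n - 1) * np.log(beta))


@dataclass
class _Piece:
    """Branching data of one regime, extracted once per assignment."""

    node_ages: np.ndarray  # ages before present of regime birth events
    int_t1: np.ndarray  # internal-branch start ages (older)
    int_t2: np.ndarray  # internal-branch end ages
    tip_stem: np.ndarray  # stem ages of regime tips
    tip_n: np.ndarray  # richness of regime tips


def backbone_loglik(piece: _Piece, r: float, epsilon: float) -> float:
    """Log-likelihood of one regime's resolved and unresolved parts."""
    if r <= 0 or not 0 <= epsilon < 1:
        return -np.inf
    lam = r / (1.0 - epsilon)
    mu = lam - r
    ll = 0.0
    if len(piece.node_ages):
        # birth terms: ln(lambda P(t)) with P(t) = r/(lam - mu e^{-rt})
        ll += float(
            np.sum(np.log(lam * r) - np.log(lam - mu * np.exp(-r * piece.node_ages)))
        )
    if len(piece.int_t1):
        # ln(lam e^{rt} - mu) = rt + ln(lam - mu e^{-rt}), overflow-safe
        g1 = r * piece.int_t1 + np.log(lam - mu * np.exp(-r * piece.int_t1))
        g2 = r * piece.int_t2 + np.log(lam - mu * np.exp(-r * piece.int_t2))
        ll -= float(np.sum(g1 - g2))
    if len(piece.tip_stem):
        rt = r * piece.tip_stem
        log_den = rt + np.log1p(-epsilon * np.exp(-rt))  # ln(e^{rt} - eps)
        log_beta = rt + np.log1p(-np.exp(-rt)) - log_den  # ln(e^{rt} - 1) - ...
        log_1m_beta = np.log1p(-epsilon) - log_den
        ll += float(np.sum(log_1m_beta + (piece.tip_n - 1.0) * log_beta))
    return ll


def _at_bound(r: float, eps: float) -> bool:
    if not np.isfinite(r):
        return False
    return abs(eps - _EPS_BOUNDS[1]) < 1e-6 or abs(r - _R_BOUNDS[1]) < 1e-6


def _fit_piece(piece: _Piece, start=None, thorough: bool = True):
    """Maximize backbone_loglik over (r, eps) within box bounds.

    ``thorough`` adds generic multi-starts; the candidate scan uses a
    single warm start for speed and the accepted model is refit
    thoroughly.
    """
    if len(piece.node_ages) == 0 and len(piece.int_t1) == 0 and len(piece.tip_stem) == 0:
        return 0.0, np.nan, np.nan, False
    starts = [(0.05, 0.0), (0.3, 0.5)] if thorough else [(0.1, 0.0)]
    if start is not None and np.all(np.isfinite(np.asarray(start, dtype=float))):
        starts = [tuple(start)] + ([] if not thorough else starts)

    def nll(p):
        v = backbone_loglik(piece, p[0], p[1])
        return -v if np.isfinite(v) else 1e12

    best = None
    for s in starts:
        res = optimize.minimize(
            nll, np.asarray(s, dtype=float), method="L-BFGS-B",
            bounds=[_R_BOUNDS, _EPS_BOUNDS],
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, float(best.x[0]), float(best.x[1]), True


@dataclass
class Regime:
    """One diversification regime of a shift model."""

    shift_node: Optional[int]  # None for the root regime
    r: float
    epsilon: float
    loglik: float
    at_bound: bool = False


@dataclass
class ShiftModel:
    """Regime assignment with likelihood and AICc bookkeeping."""

    regimes: list
    loglik: float
    k: int
    aicc: float

    @property
    def n_shifts(self) -> int:
        return len(self.regimes) - 1

    @property
    def shift_nodes(self) -> list:
        return [g.shift_node for g in self.regimes if g.shift_node is not None]


class RateShiftModel:
    """Stepwise AICc rate-shift scan on a diversity tree.

    Usage follows the Model/Results idiom::

        res = RateShiftModel(dtree).fit(max_shifts=15)
        print(res.summary())
    """

    def __init__(self, dtree: DiversityTree):
        self.dtree = dtree
        t = dtree.tree
        self._ages_bp = t.ages_before_present
        # AICc sample size: internal nodes + tips with richness > 1
        self.n_obs = len(t.internal_ids) + int(np.sum(dtree.richness > 1))

    # -- regime extraction --------------------------------------------

    def _assignment(self, shift_nodes: Sequence[int]) -> np.ndarray:
        """Regime index per node (regime of the branch above the node;
        the root carries the root regime).  Regime 0 is the root regime,
        regime i >= 1 the subtree of shift_nodes[i-1] (stem placement:
        the shift branch itself belongs to the new regime)."""
        t = self.dtree.tree
        reg = np.zeros(t.n_nodes, dtype=np.int64)
        # most tipward shift wins: apply shifts in root-to-tip order so a
        # nested shift's subtree overwrites its ancestor's assignment
        # (parent indices precede children, so index order is such an order)
        order = sorted(range(len(shift_nodes)), key=lambda i: shift_nodes[i])
        for rank, i in enumerate(order):
            s = shift_nodes[i]
            stack = [s]
            while stack:
                v = stack.pop()
                reg[v] = i + 1
                stack.extend(t.children(v))
        return reg

    def _piece(self, reg: np.ndarray, idx: int) -> _Piece:
        t = self.dtree.tree
        bp = self._ages_bp
        node_ages, t1, t2, stems, rich = [], [], [], [], []
        pos = {int(x): j for j, x in enumerate(t.tip_ids)}
        for v in range(t.n_nodes):
            if reg[v] != idx:
                continue
            ch = t.children(v)
            if ch and v != 0:
                node_ages.append(bp[v])
            if v == 0:
                continue  # the root's split is the conditioning event
            p = int(t.parent[v])
            if ch:
                t1.append(bp[p])
                t2.append(bp[v])
            else:
                stems.append(bp[p])
                rich.append(self.dtree.richness[pos[v]])
        # a shift node that is internal: its own split belongs to the new
        # regime (handled above since reg[v] == idx for it)
        return _Piece(
            np.asarray(node_ages), np.asarray(t1), np.asarray(t2),
            np.asarray(stems), np.asarray(rich, dtype=float),
        )

    # -- fitting ------------------------------------------------------

    def _fit_assignment(self, shift_nodes, warm=None):
        reg = self._assignment(shift_nodes)
        regimes = []
        total = 0.0
        for idx in range(len(shift_nodes) + 1):
            piece = self._piece(reg, idx)
            start = warm.get(idx) if warm else None
            ll, r, eps, ok = _fit_piece(piece, start=start)
            shift = None if idx == 0 else shift_nodes[idx - 1]
            regimes.append(Regime(shift, r, eps, ll, _at_bound(r, eps)))
            total += ll
        k = 2 + 3 * len(shift_nodes)
        from .modelfit import aicc as _aicc

        return ShiftModel(regimes, total, k, _aicc(total, k, self.n_obs))

    def _subtree(self, v: int) -> list:
        t = self.dtree.tree
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(t.children(u))
        return out

    def fit(self, max_shifts: int = 15) -> "RateShiftResults":
        """Greedy stepwise scan.

        Candidates are scanned in node-index order each step; only the
        two regimes affected by a candidate (the one it splits and the
        new one) are refitted, warm-started from the current estimates.
        """
        from .modelfit import aicc as _aicc

        t = self.dtree.tree
        path = [self._fit_assignment([])]
        shifts: list[int] = []
        while len(shifts) < max_shifts:
            current = path[-1]
            reg_now = self._assignment(shifts)
            best_aicc = current.aicc
            best = None
            k_next = 2 + 3 * (len(shifts) + 1)
            new_idx = len(shifts) + 1
            for v in range(1, t.n_nodes):
                if v in shifts:
                    continue
                old_idx = int(reg_now[v])
                reg_trial = reg_now.copy()
                sub = self._subtree(v)
                moved = [w for w in sub if reg_trial[w] == old_idx]
                reg_trial[moved] = new_idx
                warm = (current.regimes[old_idx].r, current.regimes[old_idx].epsilon)
                ll_new, r_new, e_new, _ = _fit_piece(
                    self._piece(reg_trial, new_idx), start=warm, thorough=False
                )
                ll_old, r_old, e_old, _ = _fit_piece(
                    self._piece(reg_trial, old_idx), start=warm, thorough=False
                )
                total = (
                    current.loglik
                    - current.regimes[old_idx].loglik
                    + ll_old
                    + ll_new
                )
                a = _aicc(total, k_next, self.n_obs)
                # strict improvement, index-order scan: earliest node wins ties
                if a < best_aicc - 1e-9:
                    best_aicc = a
                    best = (v, total, (ll_old, r_old, e_old), (ll_new, r_new, e_new))
            if best is None:
                break
            v, total, old_fit, new_fit = best
            shifts.append(v)
            # thorough refit of the accepted assignment, warm-started
            warm = {i: (g.r, g.epsilon) for i, g in enumerate(current.regimes)}
            warm[len(shifts)] = (new_fit[1], new_fit[2])
            refit = self._fit_assignment(shifts, warm=warm)
            if refit.aicc >= path[-1].aicc - 1e-9:
                shifts.pop()  # refit lost the improvement: stop cleanly
                break
            path.append(refit)
        return RateShiftResults(self, path)


@dataclass
class RateShiftResults:
    """AICc path and retained model of a stepwise rate-shift scan."""

    model: RateShiftModel
    path: list

    @property
    def retained(self) -> ShiftModel:
        return self.path[-1]

    @property
    def base(self) -> ShiftModel:
        return self.path[0]

    @property
    def n_shifts(self) -> int:
        return self.retained.n_shifts

    @property
    def delta_aicc(self) -> float:
        """Total AICc improvement of the retained model over the base."""
        return self.base.aicc - self.retained.aicc

    def summary(self) -> str:
        lines = [
            f"Rate-shift scan: {self.n_shifts} shift(s) retained "
            f"(AICc {self.base.aicc:.2f} -> {self.retained.aicc:.2f}, "
            f"improvement {self.delta_aicc:.2f})",
        ]
        tree = self.model.dtree.tree
        for g in self.retained.regimes:
            where = "root" if g.shift_node is None else f"node {g.shift_node}"
            flag = "  [at bound]" if g.at_bound else ""
            lines.append(
                f"  regime @ {where}: r = {g.r:.4f}, eps = {g.epsilon:.4f}{flag}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_shifts": self.n_shifts,
            "aicc_path": [m.aicc for m in self.path],
            "regimes": [
                {
                    "shift_node": g.shift_node,
                    "r": g.r,
                    "epsilon": g.epsilon,
                    "at_bound": g.at_bound,
                }
                for g in self.retained.regimes
            ],
        }


def fit_rate_shifts(dtree: DiversityTree, max_shifts: int = 15) -> RateShiftResults:
    """Functional wrapper around :class:`RateShiftModel`."""
    return RateShiftModel(dtree).fit(max_shifts=max_shifts)
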