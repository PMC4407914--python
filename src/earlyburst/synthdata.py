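"""Synthetic study-shaped fixtures: tree, trait table and richness table.

The generator emulates the *shape* of a study system of cold-water
marine fishes radiating over the last ~13.4 myr: a 49-tip ultrametric
tree containing one large "polar" clade (46 tips standing for 122 of
132 species) that includes a very young, species-rich subclade (crown
age ~1.2 myr), plus a small non-polar grade (3 tips, 10 species); five
continuous traits (two body-shape canonical variates, log body size,
buoyancy and the mean sea-surface temperature of occupied habitat)
simulated under BM or single-optimum OU with the rate and constraint
parameters of the package's canonical model-fit table; and a richness
table for diversity-tree analyses.  Habitat temperatures are truncated
below at the freezing point of sea water (-1.86 degC) and one tip is
forced to a warm outlier value, mimicking a single species with a
far more temperate distribution than the rest of the clade.

No attempt is made to reproduce a real topology or real trait values;
the fixtures exist so that every downstream stage is testable from a
seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .tree import TimeTree, TreeError
from .treesim import (
    BDParams,
    ConditioningSpec,
    simulate_bd_forward,
    simulate_conditioned_tree,
)
from .traitsim import TraitModel, simulate_trait_matrix

__all__ = ["FixtureSpec", "TRAIT_MODELS", "make_fixture", "make_planted_shift_tree"]

SEA_WATER_FREEZING = -1.86  # degC, hard lower bound for habitat temperature

# per-trait generating models: (kind, sigma2, alpha, x0 = theta)
TRAIT_MODELS = {
    "cv1": ("bm", 3.47, 0.0, 0.0),
    "cv2": ("ou", 39.05, 0.30, 0.0),
    "body_size_log": ("ou", 0.12, 0.11, 3.4),
    "buoyancy": ("bm", 0.23, 0.0, 3.0),
    "temperature": ("ou", 2.37, 0.25, -1.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of the synthetic study system.

    The clade plan is fixed-shape: a focal clade of ``n_focal`` tips
    (crown slightly younger than the root), containing a fast young
    subclade of ``n_fast`` tips with crown age ``fast_crown_age``, and
    an outgroup grade with the remaining tips.  Richness sums are the
    study-shaped constants (132 species total, 122 in the focal clade).
    """

    n_tips: int = 49
    crown_age: float = 13.4
    n_focal: int = 46
    n_fast: int = 7
    fast_crown_age: float = 1.2
    fast_stem_floor: float = 2.5
    outgroup_crown_age: float = 8.0
    total_richness: int = 132
    focal_richness: int = 122
    fast_richness: int = 30
    outlier_temperature: float = 7.64
    outlier_pair_age: float = 2.7
    seed: int = 0

    def __post_init__(self):
        if self.n_focal + (self.n_tips - self.n_focal) != self.n_tips:
            raise ValueError("inconsistent clade plan")
        n_out = self.n_tips - self.n_focal
        if n_out < 2 or self.n_fast < 2 or self.n_fast >= self.n_focal:
            raise ValueError("infeasible clade plan")
        if not 0 < self.fast_crown_age < self.fast_stem_floor < self.crown_age:
            raise ValueError("fast-clade ages must nest inside the crown age")
        if not self.focal_richness < self.total_richness:
            raise ValueError("focal richness must be below the total")
        if self.focal_richness < self.n_focal or self.fast_richness < self.n_fast:
            raise ValueError("richness below tip counts")


def _conditioned(n: int, crown: float, rng, prefix: str = "t") -> TimeTree:
    spec = ConditioningSpec(
        crown_age=crown, n_extant=n, rate_sampler=(0.1, 0.6), max_attempts=200_000
    )
    return _relabel(simulate_conditioned_tree(spec, rng), prefix)


def _relabel(tree: TimeTree, prefix: str) -> TimeTree:
    """Rename tips ``{prefix}_01 ...`` in tip-id order."""
    mapping = {l: f"{prefix}_{i + 1:02d}" for i, l in enumerate(tree.tip_labels)}
    return TimeTree(
        tree.parent, tree.age,
        [mapping[l] if l is not None else None for l in tree.labels],
    )


def _graft(host: TimeTree, host_tip_label: str, guest: TimeTree, guest_crown_bp: float):
    """Replace a host tip by ``guest``, placing the guest's crown at
    ``guest_crown_bp`` Ma before present on the host's time scale."""
    T = host.crown_age
    tip = [i for i in host.tip_ids if host.labels[i] == host_tip_label][0]
    parent_bp = T - host.age[host.parent[tip]]
    if parent_bp <= guest_crown_bp:
        raise TreeError("graft point younger than the guest crown")
    n0 = host.n_nodes
    parent = list(host.parent)
    age = list(host.age)
    labels = list(host.labels)
    # host tip becomes the guest's crown node
    age[tip] = T - guest_crown_bp
    labels[tip] = None
    stretch = guest_crown_bp / guest.crown_age
    for v in range(1, guest.n_nodes):
        gp = int(guest.parent[v])
        parent.append(tip if gp == 0 else n0 + gp - 1)
        age.append((T - guest_crown_bp) + guest.age[v] * stretch)
        labels.append(guest.labels[v])
    return TimeTree(parent, age, labels)


def _join_at_root(crown_age: float, left: TimeTree, left_crown_bp: float,
                  right: TimeTree, right_crown_bp: float) -> TimeTree:
    """New root at ``crown_age`` with the two trees as crown clades."""
    parent = [-1]
    age = [0.0]
    labels: list = [None]

    def add(sub: TimeTree, crown_bp: float):
        off = len(parent)
        stretch = crown_bp / sub.crown_age if sub.crown_age > 0 else 1.0
        for v in range(sub.n_nodes):
            parent.append(0 if v == 0 else off + sub.parent[v])
            age.append((crown_age - crown_bp) + sub.age[v] * stretch)
            labels.append(sub.labels[v])

    add(left, left_crown_bp)
    add(right, right_crown_bp)
    return TimeTree(parent, age, labels)


def _richness_allocation(n: int, total: int, rng) -> np.ndarray:
    """Deterministic-ish allocation: every tip >= 1, surplus spread with
    a geometric-flavoured profile over a shuffled tip order."""
    out = np.ones(n, dtype=np.int64)
    surplus = total - n
    order = rng.permutation(n)
    i = 0
    while surplus > 0:
        take = max(1, int(np.ceil(surplus * 0.25)))
        take = min(take, surplus)
        out[order[i % n]] += take
        surplus -= take
        i += 1
    return out


def make_fixture(spec: FixtureSpec = FixtureSpec(), seed: Optional[int] = None):
    """Build (TimeTree, trait DataFrame, richness Series) from a spec.

    Deterministic given ``seed`` (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_out = spec.n_tips - spec.n_focal

    # focal clade: conditioned simulation with one placeholder tip for
    # the fast subclade
    focal = _conditioned(
        spec.n_focal - spec.n_fast + 1, spec.crown_age * 0.95, rng, prefix="focal"
    )
    # graft the fast clade onto the placeholder with the oldest stem
    T = focal.crown_age
    parent_bp = T - focal.age[focal.parent[focal.tip_ids]]
    ok = np.flatnonzero(parent_bp > spec.fast_stem_floor)
    if len(ok) == 0:
        raise TreeError("no graft point older than the fast-clade stem floor")
    host_tip = focal.tip_ids[ok[np.argmax(parent_bp[ok])]]
    fast = _conditioned(spec.n_fast, spec.fast_crown_age, rng, prefix="fast")
    focal = _graft(focal, focal.labels[host_tip], fast, spec.fast_crown_age)

    outgroup = _conditioned(n_out, spec.outgroup_crown_age, rng, prefix="out")
    tree = _join_at_root(
        spec.crown_age, focal, focal.crown_age, outgroup, spec.outgroup_crown_age
    )

    # traits
    traits = {}
    for name, (kind, s2, alpha, x0) in TRAIT_MODELS.items():
        model = TraitModel(kind, sigma2=s2, alpha=alpha, theta=x0, x0=x0)
        vals = simulate_trait_matrix(tree, model, (), rng, 1)[:, 0]
        if name == "temperature":
            vals = np.maximum(vals, SEA_WATER_FREEZING)
            # one warm outlier among the focal (non-fast) tips, mimicking
            # a single species with a temperate distribution
            # The outlier loads the late DTT curve through the lineage
            # that subtends it together with its sister: that lineage
            # carries near-total disparity from its stem down to the
            # sister split.  Pick the focal tip whose sister split is
            # late (near the target pair age) but whose enclosing
            # lineage stem is as old as possible, mimicking an old,
            # species-poor lineage with one temperate member.
            T = tree.crown_age
            best = None
            for j, t in enumerate(tree.tip_ids):
                if not tree.labels[int(t)].startswith("focal_"):
                    continue
                p = int(tree.parent[t])
                gp = int(tree.parent[p]) if p != 0 else p
                p_bp, gp_bp = T - tree.age[p], T - tree.age[gp]
                score = (gp_bp - p_bp) - abs(p_bp - spec.outlier_pair_age)
                if best is None or score > best[0]:
                    best = (score, j)
            vals[best[1]] = spec.outlier_temperature
        traits[name] = vals
    trait_frame = pd.DataFrame(traits, index=pd.Index(tree.tip_labels, name="species"))

    # richness
    rich = pd.Series(0, index=trait_frame.index, name="n_species", dtype=np.int64)
    fast_labels = [l for l in tree.tip_labels if l.startswith("fast_")]
    slow_labels = [l for l in tree.tip_labels if l.startswith("focal_")]
    out_labels = [l for l in tree.tip_labels if l.startswith("out_")]
    rich[fast_labels] = _richness_allocation(len(fast_labels), spec.fast_richness, rng)
    rich[slow_labels] = _richness_allocation(
        len(slow_labels), spec.focal_richness - spec.fast_richness, rng
    )
    rich[out_labels] = _richness_allocation(
        len(out_labels), spec.total_richness - spec.focal_richness, rng
    )
    assert rich.sum() == spec.total_richness
    return tree, trait_frame, rich


def make_planted_shift_tree(
    seed=None,
    lam_background: float = 0.2,
    crown_age: float = 15.0,
    n_fast: int = 15,
    rate_factor: float = 10.0,
    min_background: int = 20,
    max_background: int = 80,
    stem_window: tuple = (0.7, 1.2),
):
    """Yule tree in which one whole lineage diversified at
    ``rate_factor`` times the background speciation rate.

    A background pure-birth tree is simulated (rejected outside the
    background tip-count window); a tip whose stem starts inside
    ``stem_window`` (Ma before present) is then replaced by a fast
    subtree simulated forward from that very node at the elevated rate
    and conditioned on ``n_fast`` extant tips.  The rate shift
    therefore applies from the parent node downwards, matching the
    stem-placement convention of the shift scan, and the reported shift
    node is the first divergence of the fast lineage.

    Returns ``(TimeTree, shift_node_id, fast_tip_labels)``; all tips
    carry richness 1.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lam_fast = lam_background * rate_factor
    while True:
        bg = None
        while bg is None or not (min_background <= bg.n_tips <= max_background):
            bg = simulate_bd_forward(BDParams(lam_background), crown_age, rng)
        T = bg.crown_age
        parent_bp = T - bg.age[bg.parent[bg.tip_ids]]
        ok = np.flatnonzero((parent_bp > stem_window[0]) & (parent_bp < stem_window[1]))
        if len(ok) == 0:
            continue
        host_tip = int(bg.tip_ids[ok[rng.integers(len(ok))]])
        stem_age = float(T - bg.age[bg.parent[host_tip]])
        fast, stem_len = _stem_conditioned(n_fast, stem_age, lam_fast, rng)
        fast = _relabel(fast, "fast")
        tree = _graft(bg, bg.labels[host_tip], fast, stem_age - stem_len)
        fast_set = set(fast.tip_labels)
        shift_node = _clade_node(tree, fast_set)
        return tree, shift_node, fast_set


def _stem_conditioned(n: int, stem_age: float, lam: float, rng, max_attempts=500_000):
    """Pure-birth subtree from a single stem lineage of age ``stem_age``
    conditioned on exactly ``n`` extant tips.

    Returns (crown TimeTree, stem length above its crown)."""
    for _ in range(max_attempts):
        t1 = float(rng.exponential(1.0 / lam))
        if t1 >= stem_age:
            continue  # lineage never split: cannot yield n >= 2 tips
        tree = simulate_bd_forward(BDParams(lam), stem_age - t1, rng, max_extant=n)
        if tree is not None and tree.n_tips == n:
            return tree, t1
    raise RuntimeError(
        f"no stem-conditioned subtree with n={n} in {max_attempts} attempts"
    )


def _clade_node(tree: TimeTree, tip_labels: set) -> int:
    """Node whose descendant tip set equals ``tip_labels``."""
    for v in tree.internal_ids:
        tips = {tree.labels[int(i)] for i in tree.clade_tips(v)}
        if tips == tip_labels:
            return int(v)
    raise TreeError("no node subtends exactly the given tip set")
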