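"""Ultrametric time-tree container.

Every stage of the package operates on :class:`TimeTree`, a compact
array-backed representation of a rooted binary phylogeny with branch
lengths in millions of years (myr).  Two age conventions are in use in
the field; internally a single one is adopted:

* ``age`` — distance *below the root*, so the root has age 0 and, on an
  ultrametric tree, every tip has age equal to the crown age;
* ``ages_before_present`` — the mirrored convention (tips at 0) used by
  all I/O and by geological interval arithmetic.

Nodes are stored in a canonical order in which every parent index is
smaller than its children's indices and the root is node 0; iterating
indices forward is therefore a valid preorder, and backward a valid
postorder.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence

import numpy as np

__all__ = ["TimeTree", "TreeError", "ltt"]


class TreeError(ValueError):
    """Structurally invalid tree, or tree/data mismatch."""


def _canonical_order(parent: np.ndarray) -> np.ndarray:
    """Return a BFS ordering of nodes such that parents precede children."""
    n = len(parent)
    roots = np.flatnonzero(parent < 0)
    if len(roots) != 1:
        raise TreeError(f"tree must have exactly one root, found {len(roots)}")
    children: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    order = []
    stack = [int(roots[0])]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children[v]))
    if len(order) != n:
        raise TreeError("tree contains a cycle or disconnected nodes")
    return np.asarray(order, dtype=np.int64)


class TimeTree:
    """Rooted binary ultrametric phylogeny with node ages in myr.

    Parameters
    ----------
    parent : array of int
        Parent index per node; exactly one entry must be -1 (the root).
    age : array of float
        Distance of each node below the root, in myr.
    labels : sequence of str or None
        Label per node; tips must be labelled, labels must be unique.
    """

    __slots__ = ("parent", "age", "labels", "_children", "_tip_ids")

    def __init__(self, parent, age, labels, validate: bool = True):
        parent = np.asarray(parent, dtype=np.int64)
        age = np.asarray(age, dtype=float)
        labels = list(labels)
        n = len(parent)
        if not (len(age) == n == len(labels)):
            raise TreeError("parent, age and labels must have equal length")
        # renumber into canonical (parent-before-child) order if needed
        if not (parent[0] == -1 and np.all(parent[1:] < np.arange(1, n))):
            order = _canonical_order(parent)
            rank = np.empty(n, dtype=np.int64)
            rank[order] = np.arange(n)
            new_parent = np.where(parent[order] >= 0, rank[parent[order]], -1)
            parent, age = new_parent, age[order]
            labels = [labels[i] for i in order]
        self.parent = parent
        self.age = age
        self.labels = labels
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            children[parent[i]].append(i)
        self._children = children
        self._tip_ids = np.asarray(
            [i for i in range(n) if not children[i]], dtype=np.int64
        )
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        """Parse a Newick string (branch lengths in myr)."""
        import dendropy

        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree) -> "TimeTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        age = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                length = nd.edge.length if nd.edge.length is not None else 0.0
                age[i] = age[p] + float(length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("tip without a label")
                labels[i] = str(nd.taxon.label)
        return cls(parent, age, labels)

    # -- basic properties ---------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self._tip_ids)

    @property
    def tip_ids(self) -> np.ndarray:
        return self._tip_ids

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self._tip_ids]

    @property
    def crown_age(self) -> float:
        return float(self.age[self._tip_ids].max())

    @property
    def internal_ids(self) -> np.ndarray:
        return np.asarray(
            [i for i in range(self.n_nodes) if self._children[i]], dtype=np.int64
        )

    def children(self, v: int) -> list[int]:
        return self._children[v]

    @property
    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        bl[1:] = self.age[1:] - self.age[self.parent[1:]]
        return bl

    @property
    def ages_before_present(self) -> np.ndarray:
        return self.crown_age - self.age

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        tips = self.age[self._tip_ids]
        depth = tips.max()
        if depth == 0:
            return True
        return bool(np.all(np.abs(tips - depth) <= rtol * depth))

    def _validate(self):
        for i in range(self.n_nodes):
            nc = len(self._children[i])
            if nc not in (0, 2):
                raise TreeError(f"node {i} has {nc} children; tree must be binary")
        bl = self.branch_lengths
        if np.any(bl[1:] <= 0):
            bad = int(np.flatnonzero(bl[1:] <= 0)[0]) + 1
            raise TreeError(f"non-positive branch length above node {bad}")
        tips = self.tip_labels
        if any(l is None for l in tips):
            raise TreeError("unlabelled tip")
        if len(set(tips)) != len(tips):
            raise TreeError("duplicate tip labels")

    # -- derived structure --------------------------------------------

    def postorder(self) -> Iterable[int]:
        return range(self.n_nodes - 1, -1, -1)

    def clade_tips(self, v: int) -> np.ndarray:
        """Tip ids descending from node ``v`` (``v`` itself if a tip)."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            ch = self._children[u]
            if ch:
                stack.extend(ch)
            else:
                out.append(u)
        return np.asarray(sorted(out), dtype=np.int64)

    def tip_incidence(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: tip j descends from node i."""
        n, tips = self.n_nodes, self._tip_ids
        col = {int(t): j for j, t in enumerate(tips)}
        inc = np.zeros((n, len(tips)), dtype=bool)
        for v in self.postorder():
            ch = self._children[v]
            if not ch:
                inc[v, col[v]] = True
            else:
                for c in ch:
                    inc[v] |= inc[c]
        return inc

    def mrca_age_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) matrix of MRCA ages below the root.

        Entry (i, j) is the shared path length from the root of tips i
        and j; the diagonal holds each tip's own age (= crown age on an
        ultrametric tree).
        """
        inc = self.tip_incidence()
        k = self.n_tips
        s = np.zeros((k, k))
        for v in self.internal_ids:
            c1, c2 = self._children[v]
            a = np.flatnonzero(inc[c1])
            b = np.flatnonzero(inc[c2])
            s[np.ix_(a, b)] = self.age[v]
            s[np.ix_(b, a)] = self.age[v]
        np.fill_diagonal(s, self.age[self._tip_ids])
        return s

    def tip_values(self, mapping) -> np.ndarray:
        """Order a {label: value} mapping (or pandas Series) by tip id."""
        try:
            out = np.asarray([mapping[l] for l in self.tip_labels], dtype=float)
        except KeyError as exc:
            missing = [l for l in self.tip_labels if l not in mapping]
            raise TreeError(f"missing trait values for tips: {missing}") from exc
        return out

    # -- editing ------------------------------------------------------

    def induced(self, keep_labels: Sequence[str]) -> "TimeTree":
        """Induced subtree on a subset of tips.

        Branch lengths along retained paths are preserved; unifurcations
        are suppressed with lengths summed.  The new root is the MRCA of
        the retained tips and is re-based to age 0.
        """
        keep = set(keep_labels)
        if not keep <= set(self.tip_labels):
            raise TreeError("unknown tip labels in subset")
        if len(keep) < 2:
            raise TreeError("need at least two tips")
        n = self.n_nodes
        kept_below = np.zeros(n, dtype=np.int64)
        for v in self.postorder():
            ch = self._children[v]
            if not ch:
                kept_below[v] = int(self.labels[v] in keep)
            else:
                kept_below[v] = sum(kept_below[c] for c in ch)
        # nodes of the induced tree: kept tips, and internal nodes whose
        # >=2 children subtend kept tips
        is_node = np.zeros(n, dtype=bool)
        for v in range(n):
            ch = self._children[v]
            if not ch:
                is_node[v] = kept_below[v] > 0
            else:
                is_node[v] = sum(kept_below[c] > 0 for c in ch) >= 2
        # new root = rootmost induced node
        root = int(np.flatnonzero(is_node)[0])
        new_parent, new_age, new_labels = [], [], []
        remap: dict[int, int] = {}
        order = [v for v in range(n) if is_node[v]]
        for v in order:
            if v == root:
                p_new = -1
            else:
                u = int(self.parent[v])
                while not is_node[u]:
                    u = int(self.parent[u])
                p_new = remap[u]
            remap[v] = len(new_parent)
            new_parent.append(p_new)
            new_age.append(self.age[v] - self.age[root])
            new_labels.append(self.labels[v] if not self._children[v] else None)
        return TimeTree(new_parent, new_age, new_labels)

    # -- output -------------------------------------------------------

    def newick(self, precision: int = 12) -> str:
        """Newick string with branch lengths in myr."""
        buf = _io.StringIO()
        bl = self.branch_lengths
        # iterative postorder string assembly
        parts: dict[int, str] = {}
        for v in self.postorder():
            ch = self._children[v]
            if not ch:
                lab = self.labels[v]
                if any(c in lab for c in " ,():;'"):
                    lab = "'" + lab.replace("'", "''") + "'"
                s = lab
            else:
                s = "(" + ",".join(parts.pop(c) for c in ch) + ")"
            if v != 0:
                s += f":{bl[v]:.{precision}g}"
            parts[v] = s
        buf.write(parts[0] + ";")
        return buf.getvalue()

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick(), schema="newick")

    def __repr__(self) -> str:
        return (
            f"<TimeTree {self.n_tips} tips, crown age "
            f"{self.crown_age:.4g} myr>"
        )


def ltt(tree: TimeTree) -> np.ndarray:
    """Lineage-through-time step function.

    Returns an array of (age-from-root, lineage count) rows: starts at
    (0, 2) at the root and increments at each later internal node age.
    Tied internal ages are merged into one step.
    """
    if not tree.is_ultrametric():
        raise TreeError("LTT requires an ultrametric tree")
    ages = np.sort(tree.age[tree.internal_ids])
    out = [(0.0, 2)]
    count = 2
    for a in ages[1:]:
        count += 1
        if out and out[-1][0] == a:
            out[-1] = (float(a), count)
        else:
            out.append((float(a), count))
    return np.asarray(out)
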