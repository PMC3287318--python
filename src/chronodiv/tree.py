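"""Ultrametric time trees (chronograms) and queries on them.

A chronogram is a rooted tree whose branch lengths are in absolute time
(here Myr), so every tip is equidistant from the root.  Two time
conventions are used consistently throughout the package:

* ``age``  — Myr before present; tips have age 0, the root has age
  ``root_age``.
* ``t``    — Myr since the root, ``t = root_age - age``.  Likelihood
  integrals run forward in ``t``; user-facing thresholds and breakpoints
  are ages, matching the Ma axis of dated phylogenies.

Branching events follow a right-continuous convention: an event at time
``t`` counts toward the lineage total from ``t`` onward, which makes
``integral N(t) dt`` equal the sum of edge lengths exactly.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    InsufficientTipsError,
    NewickParseError,
    UltrametricityError,
)

__all__ = [
    "Chronogram",
    "read_newick",
    "branching_times",
    "lineage_count",
    "divergence_matrix",
    "clades_below_threshold",
]

DEFAULT_ULTRAMETRIC_TOL = 1e-6


class Chronogram:
    """A validated ultrametric time tree.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with branch lengths on all non-root edges.
    tolerance : float
        Maximum allowed relative spread of root-to-tip path lengths.

    Attributes
    ----------
    n : int
        Number of tips.
    root_age : float
        Tree depth in Myr.
    tips : list of str
        Tip labels, in a stable (postorder-discovery) order.
    """

    def __init__(self, tree: dendropy.Tree, tolerance: float = DEFAULT_ULTRAMETRIC_TOL):
        self._tree = tree
        self._validate_and_index(tolerance)

    # ------------------------------------------------------------------
    # construction / validation
    # ------------------------------------------------------------------
    def _validate_and_index(self, tolerance: float) -> None:
        tree = self._tree
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = []
        for lf in leaves:
            label = lf.taxon.label if lf.taxon is not None else lf.label
            if label is None or str(label).strip() == "":
                raise NewickParseError("tip with empty or missing label")
            labels.append(str(label))
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate tip labels: {dupes}")

        # depth of every node (distance from root along edges)
        depth: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                el = node.edge.length
                if el is None:
                    raise NewickParseError("edge without a branch length")
                if el < 0:
                    raise NewickParseError(f"negative edge length {el}")
                depth[node] = depth[node.parent_node] + el

        tip_depths = np.array([depth[lf] for lf in leaves], dtype=float)
        root_age = float(tip_depths.max())
        if root_age <= 0 and len(leaves) > 1:
            raise UltrametricityError("tree has zero depth but multiple tips")
        spread = float(tip_depths.max() - tip_depths.min())
        scale = root_age if root_age > 0 else 1.0
        if spread > tolerance * scale:
            worst = labels[int(np.argmin(tip_depths))]
            raise UltrametricityError(
                f"tree is not ultrametric: root-to-tip lengths span "
                f"[{tip_depths.min():.6g}, {tip_depths.max():.6g}] "
                f"(worst tip {worst!r}, relative spread {spread / scale:.3g} "
                f"> tolerance {tolerance:g})"
            )

        self.n = len(leaves)
        self.root_age = root_age
        self.tips = labels
        self._leaves = leaves
        self._depth = depth
        # age = root_age - depth, tips clamped to exactly 0
        self._age = {
            node: (0.0 if node.is_leaf() else root_age - d) for node, d in depth.items()
        }

        # branching-event ages: an internal node of out-degree m contributes
        # m-1 events at its age (multifurcations keep their ties)
        events: list[float] = []
        for node in tree.preorder_internal_node_iter():
            m = len(node.child_nodes())
            if m >= 2:
                events.extend([self._age[node]] * (m - 1))
        self._event_ages = np.sort(np.asarray(events, dtype=float))[::-1]  # descending

    @classmethod
    def from_newick(
        cls, text: str, tolerance: float = DEFAULT_ULTRAMETRIC_TOL
    ) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"could not parse Newick input: {exc}") from exc
        if tree.seed_node is None or not list(tree.leaf_node_iter()):
            raise NewickParseError("empty tree")
        return cls(tree, tolerance=tolerance)

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    def node_age(self, node) -> float:
        return self._age[node]

    @property
    def event_ages(self) -> np.ndarray:
        """Ages of all branching events, descending; length n-1 on a binary tree."""
        return self._event_ages.copy()

    def branching_times(self) -> np.ndarray:
        """Branching-event ages (Myr), sorted descending; first = root_age."""
        if self.n < 2:
            raise InsufficientTipsError("branching times need at least 2 tips")
        return self._event_ages.copy()

    def nonroot_event_ages(self) -> np.ndarray:
        """Event ages excluding the single conditioned root split, descending."""
        if self.n < 2:
            raise InsufficientTipsError("no branching events on a 1-tip tree")
        return self._event_ages[1:].copy()

    def lineage_count(self, t: float) -> int:
        """Number of reconstructed lineages N(t) at time ``t`` since the root.

        Right-continuous: the value jumps at a branching time.
        """
        if t < 0 or t > self.root_age:
            raise DomainError(f"t={t} outside [0, {self.root_age}]")
        if self.n < 2:
            return 1
        # event times since root, ascending
        ev_t = self.root_age - self._event_ages[::-1]
        return 1 + int(np.searchsorted(np.sort(ev_t), t, side="right"))

    def total_branch_length(self) -> float:
        """Sum of all edge lengths; equals the integral of N(t) dt."""
        return float(
            sum(
                e.length
                for e in self._tree.preorder_edge_iter()
                if e.length is not None
            )
        )

    # ------------------------------------------------------------------
    # cumulative lineage-time / event-count functions (used by the
    # piecewise likelihood machinery)
    # ------------------------------------------------------------------
    def lineage_time_below_age(self, age) -> np.ndarray | float:
        """Lineage-time accumulated at ages younger than or equal to ``age``.

        G(a) = integral of N over the age window [0, a]; G(root_age) = total
        branch length.  Vectorised over ``age``.
        """
        asc = self._event_ages[::-1]  # event ages ascending
        n_ev = len(asc)
        if n_ev == 0:
            out = np.clip(np.asarray(age, dtype=float), 0.0, self.root_age)
            return float(out) if np.isscalar(age) else out
        knots = np.concatenate(([0.0], asc))  # ascending, last = root_age
        # On the age segment (knots[i], knots[i+1]) the lineage count is
        # 1 + #{event ages >= knots[i+1]}  (events at the old end of the
        # segment have not yet reduced the count looking backward in age).
        older = n_ev - np.searchsorted(asc, knots[1:], side="left")
        seg_N = 1.0 + older
        seg = np.diff(knots) * seg_N
        G_knots = np.concatenate(([0.0], np.cumsum(seg)))

        a = np.asarray(age, dtype=float)
        a_cl = np.clip(a, 0.0, self.root_age)
        idx = np.searchsorted(knots, a_cl, side="left")
        idx = np.clip(idx, 1, len(knots) - 1)
        frac = G_knots[idx - 1] + (a_cl - knots[idx - 1]) * seg_N[idx - 1]
        out = np.where(a_cl <= 0, 0.0, frac)
        if np.isscalar(age):
            return float(out)
        return out

    def nonroot_events_below_age(self, age) -> np.ndarray:
        """Count of non-root branching events at ages <= ``age`` (vectorised)."""
        ev = np.sort(self.nonroot_event_ages())  # ascending
        a = np.asarray(age, dtype=float)
        return np.searchsorted(ev, a, side="right")

    # ------------------------------------------------------------------
    # divergence matrix and threshold clades
    # ------------------------------------------------------------------
    def divergence_matrix(self) -> pd.DataFrame:
        """Pairwise divergence ages: d(i, j) = age of MRCA(i, j) in Myr.

        Divergence between two species is the MRCA age, not twice it.
        Returns a symmetric DataFrame with zero diagonal indexed by tip label.
        """
        n = self.n
        idx = {lf: i for i, lf in enumerate(self._leaves)}
        d = np.zeros((n, n), dtype=float)
        # postorder: tips under each child of a node diverge at the node's age
        below: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = [idx[node]]
                continue
            kids = [below[c] for c in node.child_nodes()]
            age = self._age[node]
            for a_i in range(len(kids)):
                for b_i in range(a_i + 1, len(kids)):
                    ii = np.asarray(kids[a_i])
                    jj = np.asarray(kids[b_i])
                    d[np.ix_(ii, jj)] = age
                    d[np.ix_(jj, ii)] = age
            below[node] = [x for k in kids for x in k]
        return pd.DataFrame(d, index=self.tips, columns=self.tips)

    def clades_below_threshold(self, threshold: float) -> list[set[str]]:
        """Partition tips into maximal groups whose MRCA age < ``threshold``.

        Tips with no relative within the threshold form singleton blocks.
        """
        if threshold <= 0:
            raise DomainError("threshold must be positive")
        blocks: list[set[str]] = []

        def label_of(node) -> str:
            return str(node.taxon.label if node.taxon is not None else node.label)

        def tips_under(node) -> set[str]:
            return {label_of(lf) for lf in node.leaf_iter()}

        root = self._tree.seed_node
        stack = [root]
        while stack:
            node = stack.pop()
            if self._age[node] < threshold:
                blocks.append(tips_under(node))
            else:
                stack.extend(node.child_nodes())
        return blocks

    # ------------------------------------------------------------------
    # output
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        """Newick string with branch lengths; round-trips topology and ages."""
        out = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
        return out

    def write_divergence_matrix(self, path) -> None:
        """Tab-separated dump of the divergence matrix."""
        self.divergence_matrix().to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Chronogram(n={self.n}, root_age={self.root_age:.4g} Myr)"


# ----------------------------------------------------------------------
# functional façade
# ----------------------------------------------------------------------
def read_newick(text: str, tolerance: float = DEFAULT_ULTRAMETRIC_TOL) -> Chronogram:
    """Parse a Newick string into a validated :class:`Chronogram`."""
    return Chronogram.from_newick(text, tolerance=tolerance)


def branching_times(tree: Chronogram) -> np.ndarray:
    return tree.branching_times()


def lineage_count(tree: Chronogram, t: float) -> int:
    return tree.lineage_count(t)


def divergence_matrix(tree: Chronogram) -> pd.DataFrame:
    return tree.divergence_matrix()


def clades_below_threshold(tree: Chronogram, threshold: float) -> list[set[str]]:
    return tree.clades_below_threshold(threshold)
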