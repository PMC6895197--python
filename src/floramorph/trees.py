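"""Rooted, dated phylogenies: Newick I/O, pruning, and Brownian covariance.

A :class:`Tree` wraps a :mod:`dendropy` tree and exposes the quantities the
comparative methods need: tip depths, the phylogenetic covariance matrix
``C`` (entries = root-path length shared by two tips), and an edge list in
preorder for simulating trait evolution along branches.
"""

from __future__ import annotations

import io
import warnings

import dendropy
import numpy as np

__all__ = ["Tree", "simulate_tree"]

#: relative spread of root-to-tip depths tolerated before warning
ULTRAMETRIC_RTOL = 1e-6


class Tree:
    """Rooted phylogeny with branch lengths in time units.

    Tip labels must be unique; branch lengths nonnegative.  Dated trees are
    expected to be ultrametric: a depth spread larger than ``ULTRAMETRIC_RTOL``
    times the depth triggers a warning (numerical Newick exports drift).
    """

    def __init__(self, dtree: dendropy.Tree):
        self._t = dtree
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls(dt)

    @classmethod
    def from_file(cls, path) -> "Tree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        s = io.StringIO()
        self._t.write(file=s, schema="newick", suppress_rooting=True)
        return s.getvalue().strip()

    def copy(self) -> "Tree":
        return Tree(self._t.clone(depth=1))

    # -- validation --------------------------------------------------------

    def _validate(self):
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        for edge in self._t.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                edge.length = 0.0
            if edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    # -- basic queries ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._t.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._t.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        self._t.calc_node_root_distances(return_leaf_distances_only=False)
        return {lf.taxon.label: lf.root_distance for lf in self._t.leaf_node_iter()}

    @property
    def depth(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return float(d.max() - d.min()) <= rtol * max(d.max(), np.finfo(float).tiny)

    def check_ultrametric(self):
        if not self.is_ultrametric():
            d = self.tip_depths()
            warnings.warn(
                "tree is not ultrametric within tolerance "
                f"(depth spread {max(d.values()) - min(d.values()):.3g})"
            )

    # -- manipulation ------------------------------------------------------

    def prune(self, keep: list[str]) -> "Tree":
        """Return the subtree induced by ``keep``; tip-to-tip path lengths preserved."""
        have = set(self.tip_labels)
        missing = sorted(set(keep) - have)
        if missing:
            raise ValueError(f"species absent from tree: {missing}")
        # re-read through Newick so the pruned tree owns a fresh taxon
        # namespace: clone(depth=1) shares the namespace, and purging a
        # shared namespace corrupts later prunes of the same tree
        nwk = self.to_newick()
        dt = dendropy.Tree.get(data=nwk if nwk.endswith(";") else nwk + ";",
                               schema="newick")
        dt.retain_taxa_with_labels(list(keep))
        dt.purge_taxon_namespace()
        return Tree(dt)

    def scaled(self, factor: float) -> "Tree":
        dt = self._t.clone(depth=1)
        for edge in dt.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Tree(dt)

    def rescaled_to_depth(self, depth: float = 1.0) -> "Tree":
        return self.scaled(depth / self.depth)

    # -- comparative-method machinery -------------------------------------

    def cov_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Brownian-motion covariance C: C_ij = root-path length shared by tips i, j."""
        order = list(order) if order is not None else self.tip_labels
        idx = {lab: k for k, lab in enumerate(order)}
        if set(idx) != set(self.tip_labels) or len(order) != self.n_tips:
            raise ValueError("order must be a permutation of the tip labels")
        n = len(order)
        C = np.zeros((n, n))
        self._t.calc_node_root_distances(return_leaf_distances_only=False)
        for node in self._t.postorder_node_iter():
            if node.is_leaf():
                node._fm_tips = [idx[node.taxon.label]]
                C[node._fm_tips[0], node._fm_tips[0]] = node.root_distance
            else:
                kids = node.child_nodes()
                depth = node.root_distance
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]._fm_tips:
                            for j in kids[b]._fm_tips:
                                C[i, j] = C[j, i] = depth
                node._fm_tips = [i for k in kids for i in k._fm_tips]
        for node in self._t.postorder_node_iter():
            del node._fm_tips
        return C

    def edges_preorder(self):
        """Edge list for simulation: (parent_id, child_id, length), plus tip id map.

        Node ids are assigned in preorder with the root = 0.  Returns
        ``(edges, n_nodes, tip_index)`` where ``tip_index`` maps tip label to
        node id.
        """
        ids = {}
        edges = []
        tip_index = {}
        for k, node in enumerate(self._t.preorder_node_iter()):
            ids[id(node)] = k
            if node.parent_node is not None:
                edges.append((ids[id(node.parent_node)], k, float(node.edge.length or 0.0)))
            if node.is_leaf():
                tip_index[node.taxon.label] = k
        return edges, len(ids), tip_index

    def branches(self):
        """All non-root branches as dicts with id, start/end times and descendant tips.

        Used by the regime-shift search, where a candidate shift is placed on a
        branch and applies to every tip below it.
        """
        self._t.calc_node_root_distances(return_leaf_distances_only=False)
        out = []
        for k, node in enumerate(self._t.preorder_node_iter()):
            if node.parent_node is None:
                continue
            tips = sorted(
                lf.taxon.label for lf in (node.leaf_iter() if not node.is_leaf() else [node])
            )
            out.append(
                {
                    "id": k,
                    "start": node.parent_node.root_distance,
                    "end": node.root_distance,
                    "tips": tips,
                }
            )
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tree(n_tips={self.n_tips}, depth={self.depth:.4g})"


def simulate_tree(n_tips: int, seed: int | None = None, rng: np.random.Generator | None = None) -> Tree:
    """Simulate a pure-birth (Yule) tree and rescale its depth to 1.

    The crown split happens at time 0; lineages split at rate 1 per lineage
    until ``n_tips`` are extant, after which all pendant branches are extended
    by one further exponential waiting time so the newest tip has a positive
    pendant edge.  The resulting ultrametric tree is rescaled to unit depth,
    keeping evolutionary rates interpretable per total tree depth.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed) if rng is None else rng

    taxon_namespace = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = dt.seed_node
    root._fm_birth = 0.0
    a = root.new_child()
    b = root.new_child()
    active = [a, b]
    for node in active:
        node._fm_birth = 0.0
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        parent.edge.length = t - parent._fm_birth
        for _ in range(2):
            child = parent.new_child()
            child._fm_birth = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_tips)
    for i, node in enumerate(active):
        node.edge.length = t_end - node._fm_birth
    root.edge.length = 0.0
    # deterministic tip naming in birth order
    for i, lf in enumerate(dt.leaf_node_iter()):
        lf.taxon = taxon_namespace.new_taxon(f"sp{i + 1:03d}")
    for node in dt.preorder_node_iter():
        if hasattr(node, "_fm_birth"):
            del node._fm_birth
    tree = Tree(dt)
    return tree.rescaled_to_depth(1.0)
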