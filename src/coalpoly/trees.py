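"""Lightweight rooted-tree machinery shared by the deep-coalescence code.

Gene trees are stored as arrays of leaf-set bitmasks ("clades"), one entry
per tree node, together with the parent clade of each node.  Counting the
gene lineages that exit a species-tree cluster then reduces to bit tests,
which lets a whole posterior sample of trees be scored against many candidate
species trees with vectorised numpy operations.

Species-tree *topologies* are nested tuples of leaf indices, e.g.
``((0, 1), (2, (3, 4)))``; helpers convert them to newick and enumerate the
full space of rooted binary shapes for small leaf counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "EncodedTrees",
    "encode_dendropy_trees",
    "encode_newick",
    "enumerate_topologies",
    "topology_clusters",
    "topology_to_newick",
    "newick_to_topology",
]

# sentinel high bit so the root's "parent" is never contained in any cluster
_ROOT_SENTINEL = np.uint64(1) << np.uint64(63)

_MAX_LEAVES = 62


@dataclass
class EncodedTrees:
    """A set of rooted trees over one shared leaf-label universe.

    Attributes
    ----------
    taxa : list of str
        Leaf labels; leaf ``i`` corresponds to bit ``i``.
    clades : (N,) uint64 array
        Leaf-set bitmask of every node, all trees concatenated.
    parents : (N,) uint64 array
        Bitmask of each node's parent (root gets a sentinel bit so it is
        never "contained" in a proper cluster).
    offsets : (T+1,) int array
        ``clades[offsets[t]:offsets[t+1]]`` are the nodes of tree ``t``.
    """

    taxa: list[str]
    clades: np.ndarray
    parents: np.ndarray
    offsets: np.ndarray
    _taxon_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._taxon_index:
            self._taxon_index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def n_trees(self) -> int:
        return len(self.offsets) - 1

    def taxon_bit(self, label: str) -> np.uint64:
        return np.uint64(1) << np.uint64(self._taxon_index[label])

    def mask_of(self, labels: Iterable[str]) -> np.uint64:
        m = np.uint64(0)
        for lab in labels:
            m |= self.taxon_bit(lab)
        return m

    # ------------------------------------------------------------------
    def lineage_counts(self, cluster_masks: np.ndarray) -> np.ndarray:
        """Number of gene lineages exiting each cluster, per tree.

        Parameters
        ----------
        cluster_masks : (C,) uint64 array
            Each mask is the set of gene-tree leaves mapped into one
            species-tree cluster.

        Returns
        -------
        (T, C) int array: for tree ``t`` and cluster ``c`` the number of
        maximal gene-tree clades fully contained in the cluster's leaf set
        (0 when the cluster holds no leaf of the tree).
        """
        masks = np.asarray(cluster_masks, dtype=np.uint64)
        inv = ~masks
        contained = (self.clades[:, None] & inv[None, :]) == 0
        parent_out = (self.parents[:, None] & inv[None, :]) != 0
        maximal = contained & parent_out
        return np.add.reduceat(maximal, self.offsets[:-1], axis=0)

    def extra_lineages(self, cluster_masks: np.ndarray) -> np.ndarray:
        """Total extra lineages per cluster, summed over all trees."""
        counts = self.lineage_counts(cluster_masks)
        return np.maximum(counts - 1, 0).sum(axis=0)


def encode_dendropy_trees(
    trees: Sequence[dendropy.Tree], taxa: Sequence[str] | None = None
) -> EncodedTrees:
    """Encode rooted dendropy trees over a shared taxon universe."""
    if taxa is None:
        labels: set[str] = set()
        for t in trees:
            labels.update(lf.taxon.label for lf in t.leaf_node_iter())
        taxa = sorted(labels)
    taxa = list(taxa)
    if len(taxa) > _MAX_LEAVES:
        raise ValueError(f"at most {_MAX_LEAVES} distinct leaf labels supported")
    index = {t: i for i, t in enumerate(taxa)}

    all_clades: list[np.ndarray] = []
    all_parents: list[np.ndarray] = []
    offsets = [0]
    for tree in trees:
        node_mask: dict[object, int] = {}
        rows: list[tuple[int, object]] = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                if label not in index:
                    raise KeyError(f"gene-tree leaf {label!r} not in taxon universe")
                mask = 1 << index[label]
            else:
                mask = 0
                for ch in node.child_nodes():
                    mask |= node_mask[ch]
            node_mask[node] = mask
            rows.append((mask, node))
        clades = np.array([m for m, _ in rows], dtype=np.uint64)
        parents = np.empty(len(rows), dtype=np.uint64)
        for i, (_, node) in enumerate(rows):
            par = node.parent_node
            if par is None:
                parents[i] = np.uint64(node_mask[node]) | _ROOT_SENTINEL
            else:
                parents[i] = np.uint64(node_mask[par])
        all_clades.append(clades)
        all_parents.append(parents)
        offsets.append(offsets[-1] + len(rows))

    return EncodedTrees(
        taxa=taxa,
        clades=np.concatenate(all_clades) if all_clades else np.empty(0, np.uint64),
        parents=np.concatenate(all_parents) if all_parents else np.empty(0, np.uint64),
        offsets=np.asarray(offsets, dtype=np.intp),
    )


def encode_newick(
    newicks: Sequence[str], taxa: Sequence[str] | None = None
) -> EncodedTrees:
    trees = [
        dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted", preserve_underscores=True)
        for nwk in newicks
    ]
    return encode_dendropy_trees(trees, taxa=taxa)


# ----------------------------------------------------------------------
# rooted binary topology enumeration (nested-tuple representation)
# ----------------------------------------------------------------------

Topology = object  # int leaf index or 2-tuple of topologies


def _insert_everywhere(top: Topology, leaf: int) -> list[Topology]:
    out: list[Topology] = [(top, leaf)]
    if isinstance(top, tuple):
        left, right = top
        out.extend((sub, right) for sub in _insert_everywhere(left, leaf))
        out.extend((left, sub) for sub in _insert_everywhere(right, leaf))
    return out


@lru_cache(maxsize=None)
def enumerate_topologies(n_leaves: int) -> tuple[Topology, ...]:
    """All rooted binary topologies on leaves ``0..n-1`` ((2n-3)!! shapes)."""
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    if n_leaves == 1:
        return (0,)
    tops: list[Topology] = [0]
    for leaf in range(1, n_leaves):
        tops = [t for old in tops for t in _insert_everywhere(old, leaf)]
    return tuple(tops)


def _leafset(top: Topology) -> frozenset[int]:
    if isinstance(top, tuple):
        return _leafset(top[0]) | _leafset(top[1])
    return frozenset((top,))


def topology_clusters(top: Topology, proper: bool = True) -> list[frozenset[int]]:
    """Clusters (leaf sets of internal edges) of a topology.

    With ``proper=True`` (default) only internal, non-root, non-leaf
    clusters are returned — pendant and root clusters are handled
    separately by the scoring code.
    """
    clusters: list[frozenset[int]] = []

    def walk(t: Topology, is_root: bool) -> frozenset[int]:
        if not isinstance(t, tuple):
            s = frozenset((t,))
            if not proper:
                clusters.append(s)
            return s
        s = walk(t[0], False) | walk(t[1], False)
        if not is_root or not proper:
            if proper and len(s) > 1:
                clusters.append(s)
            elif not proper:
                clusters.append(s)
        return s

    full = walk(top, True)
    if proper and full in clusters:
        clusters.remove(full)
    return clusters


def topology_to_newick(top: Topology, labels: Sequence[str]) -> str:
    def fmt(t: Topology) -> str:
        if isinstance(t, tuple):
            return f"({fmt(t[0])},{fmt(t[1])})"
        return labels[t]

    return fmt(top) + ";"


def newick_to_topology(newick: str, labels: Sequence[str]) -> Topology:
    """Parse a rooted binary newick string into the nested-tuple form."""
    index = {lab: i for i, lab in enumerate(labels)}
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True)

    def conv(node) -> Topology:
        if node.is_leaf():
            return index[node.taxon.label]
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("topology must be strictly binary")
        return (conv(children[0]), conv(children[1]))

    return conv(tree.seed_node)
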