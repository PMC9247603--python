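"""Multispecies-coalescent probability of a gene-tree topology.

Computes P(gene-tree topology | species tree with branch lengths in
coalescent units) by summing over coalescent histories: each gene-tree
internal node is placed on a species-tree branch consistent with its leaf
mapping and its children's placements; every history contributes

    prod_b  g_{u_b, v_b}(T_b) * w_b / d_{u_b, v_b}

where ``g_uv(T)`` is Tavare's probability that u lineages coalesce down to v
within T coalescent time units, ``d_uv`` is the number of distinct
u-to-v coalescence sequences, and ``w_b`` counts the orderings of the
branch's coalescence events that respect the gene-tree ancestry (hook-length
formula on the induced forest).

Branch lengths are not part of the minimize-deep-coalescence machinery, so
for tie-breaking they are estimated from the gene trees themselves: internal
branches by inverting the expected triplet concordance 1 - (2/3)e^(-T), and
pendant branches (for taxa with several alleles) from the observed allele
monophyly rate.  Both are deliberately coarse point estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees import EncodedTrees, Topology

__all__ = [
    "tavare_guv",
    "gene_tree_log_prob",
    "estimate_coalescent_lengths",
    "log_prob_assignment",
]

_MAX_GENE_LEAVES = 12


def tavare_guv(u: int, v: int, t: float) -> float:
    """Probability that ``u`` lineages coalesce to exactly ``v`` in time ``t``."""
    if u == v == 0:
        return 1.0
    if v > u or v < 1:
        return 0.0
    if math.isinf(t):
        return 1.0 if v == 1 else 0.0
    total = 0.0
    for k in range(v, u + 1):
        coef = math.exp(-k * (k - 1) * t / 2.0)
        num = (2 * k - 1) * (-1) ** (k - v)
        den = math.factorial(v) * math.factorial(k - v) * (v + k - 1)
        prod = 1.0
        for y in range(k):
            prod *= (v + y) * (u - y) / (u + y)
        total += coef * num / den * prod
    return max(total, 0.0)


def _d_uv(u: int, v: int) -> float:
    out = 1.0
    for k in range(v + 1, u + 1):
        out *= k * (k - 1) / 2.0
    return out


# ----------------------------------------------------------------------
# species / gene tree scaffolding
# ----------------------------------------------------------------------


@dataclass
class _SpNode:
    idx: int
    label: int | None  # leaf label index, None for internal
    children: list[int] = field(default_factory=list)
    parent: int | None = None
    length: float = math.inf  # coalescent units; root stays inf
    below: frozenset[int] = frozenset()


def _build_species_nodes(
    top: Topology, lengths: dict[frozenset[int] | int, float]
) -> list[_SpNode]:
    nodes: list[_SpNode] = []

    def rec(t: Topology, parent: int | None) -> int:
        idx = len(nodes)
        if isinstance(t, tuple):
            node = _SpNode(idx=idx, label=None, parent=parent)
            nodes.append(node)
            c0 = rec(t[0], idx)
            c1 = rec(t[1], idx)
            node.children = [c0, c1]
            node.below = nodes[c0].below | nodes[c1].below
            key = node.below
        else:
            node = _SpNode(idx=idx, label=t, parent=parent, below=frozenset((t,)))
            nodes.append(node)
            key = t
        node.length = math.inf if parent is None else lengths.get(key, 2.0)
        return idx

    rec(top, None)
    return nodes


@dataclass
class _GNode:
    idx: int
    children: list[int]
    species_mrca: int = -1  # species node index
    allowed: list[int] = field(default_factory=list)


def _gene_nodes_from_encoded(
    enc: EncodedTrees, tree_index: int
) -> tuple[list[int], list[list[int]], list[int]]:
    """Rebuild (parent, children, leaf-bit) structure of one encoded tree.

    Returns (node order as local indices, children lists, leaf label bit
    position or -1 for internal nodes); nodes are in postorder.
    """
    lo, hi = enc.offsets[tree_index], enc.offsets[tree_index + 1]
    clades = enc.clades[lo:hi]
    parents = enc.parents[lo:hi]
    n = hi - lo
    children: list[list[int]] = [[] for _ in range(n)]
    # parent of node i is the node j with clades[j] == parents[i] and j "above" i;
    # encoded postorder guarantees the parent appears after the child.
    for i in range(n):
        pm = parents[i]
        if pm & (np.uint64(1) << np.uint64(63)):
            continue  # root
        for j in range(i + 1, n):
            if clades[j] == pm and (clades[j] & clades[i]) == clades[i]:
                children[j].append(i)
                break
    leaf_bits = []
    for i in range(n):
        if not children[i]:
            leaf_bits.append(int(clades[i]).bit_length() - 1)
        else:
            leaf_bits.append(-1)
    return list(range(n)), children, leaf_bits


def gene_tree_log_prob(
    enc: EncodedTrees,
    tree_index: int,
    allele_label: dict[str, int],
    sp_nodes: list[_SpNode],
) -> float:
    """log P(one encoded gene tree's topology | species tree)."""
    order, children, leaf_bits = _gene_nodes_from_encoded(enc, tree_index)
    n = len(order)
    if (n + 1) // 2 > _MAX_GENE_LEAVES:
        raise ValueError("gene tree too large for coalescent-history enumeration")
    max_histories = 100_000

    bit_label = {}
    for allele, lab in allele_label.items():
        if allele in enc._taxon_index:
            bit_label[enc._taxon_index[allele]] = lab

    sp_leaf = {node.label: node.idx for node in sp_nodes if node.label is not None}
    # ancestors of each species node (path to root, inclusive)
    ancestors: list[list[int]] = []
    for node in sp_nodes:
        path, cur = [], node.idx
        while cur is not None:
            path.append(cur)
            cur = sp_nodes[cur].parent
        ancestors.append(path)
    depth = {}
    for node in sp_nodes:
        d, cur = 0, node.parent
        while cur is not None:
            d += 1
            cur = sp_nodes[cur].parent
        depth[node.idx] = d

    def sp_mrca(a: int, b: int) -> int:
        pa, pb = set(ancestors[a]), ancestors[b]
        for x in pb:
            if x in pa:
                return x
        return 0

    # map gene leaves to species leaves; compute mrca species node per gene node
    gmap: list[int] = [-1] * n
    internal: list[int] = []
    for i in range(n):
        if leaf_bits[i] >= 0:
            gmap[i] = sp_leaf[bit_label[leaf_bits[i]]]
        else:
            internal.append(i)
    for i in internal:
        m = gmap[children[i][0]]
        for c in children[i][1:]:
            m = sp_mrca(m, gmap[c])
        gmap[i] = m

    # leaves entering each species leaf branch
    entering_leaf = {node.idx: 0 for node in sp_nodes}
    for i in range(n):
        if leaf_bits[i] >= 0:
            entering_leaf[gmap[i]] += 1

    # gene-tree descendant relation among internal nodes (for w_b)
    desc: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for c in children[i]:
            desc[i].add(c)
            desc[i] |= desc[c]

    internal_post = internal  # postorder already
    root_sp = next(node.idx for node in sp_nodes if node.parent is None)

    # cheap upper bound on the history count before enumerating anything
    bound = 1
    for g in internal:
        bound *= len(ancestors[gmap[g]])
        if bound > max_histories:
            raise ValueError(
                "coalescent-history enumeration too large "
                f"(> {max_histories} candidate histories)"
            )

    total = 0.0
    assign: dict[int, int] = {}
    n_histories = 0

    sp_post = sorted(range(len(sp_nodes)), key=lambda i: -depth[i])

    def history_prob() -> float:
        per_branch: dict[int, list[int]] = {}
        for g, b in assign.items():
            per_branch.setdefault(b, []).append(g)
        leaving: dict[int, int] = {}
        p = 1.0
        for b in sp_post:
            node = sp_nodes[b]
            if node.label is not None:
                u = entering_leaf[b]
            else:
                u = sum(leaving[c] for c in node.children)
            k = len(per_branch.get(b, ()))
            v = u - k
            if u and v < 1:
                return 0.0
            leaving[b] = v
            if u <= 1 and k == 0:
                continue
            if b == root_sp and v != 1 and u > 0:
                return 0.0
            members = per_branch.get(b, ())
            w = math.factorial(k)
            for g in members:
                s = 1 + sum(1 for h in members if h in desc[g])
                w /= s
            p *= tavare_guv(u, v, node.length) * w / _d_uv(u, v)
            if p == 0.0:
                return 0.0
        return p

    def rec(pos: int) -> None:
        nonlocal total, n_histories
        if pos == len(internal_post):
            n_histories += 1
            if n_histories > max_histories:
                raise ValueError("coalescent-history enumeration too large")
            total += history_prob()
            return
        g = internal_post[pos]
        # allowed branches: ancestors of the mrca that are also >= children's branches
        lo = gmap[g]
        for c in children[g]:
            if c in assign:
                b = assign[c]
                if depth[b] < depth[lo]:
                    lo = b
                elif b not in ancestors[lo]:
                    lo = sp_mrca(lo, b)
        for b in ancestors[lo]:
            assign[g] = b
            rec(pos + 1)
        del assign[g]

    rec(0)
    if total <= 0.0:
        return -math.inf
    return math.log(total)


# ----------------------------------------------------------------------
# branch-length estimation from gene-tree concordance
# ----------------------------------------------------------------------


def _representative_bits(enc: EncodedTrees, allele_label: dict[str, int]):
    rep: dict[int, int] = {}
    for allele, lab in allele_label.items():
        if allele in enc._taxon_index:
            bit = enc._taxon_index[allele]
            if lab not in rep or bit < rep[lab]:
                rep[lab] = bit
    return rep


def estimate_coalescent_lengths(
    samples, allele_label: dict[str, int], top: Topology, n_labels: int
) -> dict:
    """Coalescent-unit branch lengths from observed concordance frequencies.

    Internal edges: T = -ln(1.5 (1 - p)) with p the frequency of the
    concordant triplet around the edge; pendant edges of multi-allele taxa:
    T = -ln(1 - p_mono) with p_mono the allele-monophyly rate.  Clamped to
    [0.05, 8] coalescent units.
    """
    lengths: dict = {}

    # collect clusters with an available outside label
    def clusters(t: Topology, parent_labels: frozenset[int]):
        if not isinstance(t, tuple):
            return frozenset((t,))
        left = clusters(t[0], parent_labels)
        right = clusters(t[1], parent_labels)
        s = left | right
        outside = parent_labels - s
        if outside and len(s) > 1:
            internal_edges.append((s, left, right, outside))
        return s

    all_labels = frozenset(range(n_labels))
    internal_edges: list = []
    clusters(top, all_labels)

    for s, left, right, outside in internal_edges:
        x, y = min(left), min(right)
        z = min(outside)
        conc = tot = 0
        for gts in samples:
            enc = gts.encoded
            rep = _representative_bits(enc, allele_label)
            if x not in rep or y not in rep or z not in rep:
                continue
            bx = np.uint64(1) << np.uint64(rep[x])
            by = np.uint64(1) << np.uint64(rep[y])
            bz = np.uint64(1) << np.uint64(rep[z])
            for ti in range(enc.n_trees):
                lo, hi = enc.offsets[ti], enc.offsets[ti + 1]
                cl = enc.clades[lo:hi]
                hit = ((cl & bx) != 0) & ((cl & by) != 0) & ((cl & bz) == 0)
                conc += bool(hit.any())
                tot += 1
        p = conc / tot if tot else 2 / 3
        p = min(max(p, 1 / 3 + 1e-6), 1 - 1e-9)
        lengths[s] = float(np.clip(-math.log(1.5 * (1 - p)), 0.05, 8.0))

    # pendant branches for multi-allele labels
    for lab in range(n_labels):
        mono = tot = 0
        multi = False
        for gts in samples:
            enc = gts.encoded
            mask = np.uint64(0)
            cnt = 0
            for allele, l2 in allele_label.items():
                if l2 == lab and allele in enc._taxon_index:
                    mask |= enc.taxon_bit(allele)
                    cnt += 1
            if cnt < 2:
                continue
            multi = True
            for ti in range(enc.n_trees):
                lo, hi = enc.offsets[ti], enc.offsets[ti + 1]
                mono += bool((enc.clades[lo:hi] == mask).any())
                tot += 1
        if multi and tot:
            p = min(max(mono / tot, 1e-6), 1 - 1e-6)
            lengths[lab] = float(np.clip(-math.log(1 - p), 0.05, 8.0))
    return lengths


def log_prob_assignment(
    samples, lineage_map: dict[str, str], top: Topology, labels: list[str]
) -> float:
    """Summed log P(gene-tree topology) over all loci and trees."""
    label_index = {lab: i for i, lab in enumerate(labels)}
    allele_label = {a: label_index[l] for a, l in lineage_map.items()}
    lengths = estimate_coalescent_lengths(samples, allele_label, top, len(labels))
    sp_nodes = _build_species_nodes(top, lengths)

    total = 0.0
    for gts in samples:
        enc = gts.encoded
        # deduplicate identical topologies within the locus
        groups: dict[tuple, list[int]] = {}
        for ti in range(enc.n_trees):
            lo, hi = enc.offsets[ti], enc.offsets[ti + 1]
            sig = tuple(sorted(int(c) for c in enc.clades[lo:hi]))
            groups.setdefault(sig, []).append(ti)
        for sig, members in groups.items():
            lp = gene_tree_log_prob(enc, members[0], allele_label, sp_nodes)
            total += lp * len(members)
    return total
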