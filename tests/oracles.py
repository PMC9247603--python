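"""Independent brute-force oracles used only by the tests.

Deliberately separate machinery from the package: pure-Python sets and a
split-based topology generator, so agreement with the bitmask/enumeration
code is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math


def parse_newick(s: str):
    """Minimal rooted-newick parser -> nested tuples of leaf labels."""
    s = s.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse()]
            while s[pos] == ",":
                pos += 1
                children.append(parse())
            assert s[pos] == ")"
            pos += 1
            # skip any label/branch length after the clade
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            return tuple(children)
        start = pos
        while pos < len(s) and s[pos] not in ",():":
            pos += 1
        label = s[start:pos]
        while pos < len(s) and s[pos] not in ",()":
            pos += 1
        return label

    return parse()


def leafset(node) -> frozenset:
    if isinstance(node, tuple):
        out = frozenset()
        for c in node:
            out |= leafset(c)
        return out
    return frozenset((node,))


def clusters_of(node, include_root: bool = False):
    """Leaf sets of all non-root edges (pendant edges included)."""
    out = []

    def walk(n, is_root):
        ls = leafset(n)
        if not is_root:
            out.append(ls)
        if isinstance(n, tuple):
            for c in n:
                walk(c, False)
        return ls

    walk(node, not include_root)
    return out


def maximal_clades_within(gene, allele_set: frozenset) -> int:
    """Number of maximal gene-tree clades whose leaves all lie in the set."""
    if leafset(gene) <= allele_set:
        return 1
    if not isinstance(gene, tuple):
        return 0
    return sum(maximal_clades_within(c, allele_set) for c in gene)


def naive_extra_lineages(gene, species, mapping: dict[str, str]) -> int:
    """Deep-coalescence count by direct per-cluster lineage counting."""
    if isinstance(gene, str):
        gene = parse_newick(gene)
    if isinstance(species, str):
        species = parse_newick(species)
    by_label: dict[str, set] = {}
    for allele, lab in mapping.items():
        by_label.setdefault(lab, set()).add(allele)
    total = 0
    for cl in clusters_of(species):
        alleles = frozenset(a for lab in cl for a in by_label.get(lab, ()))
        k = maximal_clades_within(gene, alleles)
        total += max(k - 1, 0)
    return total


def all_rooted_trees(labels: tuple):
    """Every rooted binary tree shape, by recursive bipartition (each shape
    generated exactly once)."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            left = (first,) + combo
            right = tuple(x for x in rest if x not in combo)
            if not right:
                continue
            for lt in all_rooted_trees(left):
                for rt in all_rooted_trees(right):
                    yield (lt, rt)


def naive_best_species_tree(gene_trees, mapping: dict[str, str]):
    """Exhaustive minimum-score species tree; returns (score, tree)."""
    labels = tuple(sorted(set(mapping.values())))
    best_score, best_tree = math.inf, None
    for sp in all_rooted_trees(labels):
        score = sum(naive_extra_lineages(g, sp, mapping) for g in gene_trees)
        if score < best_score:
            best_score, best_tree = score, sp
    return best_score, best_tree


def to_newick(node) -> str:
    def fmt(n):
        if isinstance(n, tuple):
            return "(" + ",".join(fmt(c) for c in n) + ")"
        return n

    return fmt(node) + ";"


def random_coalescent_topology(labels, rng):
    """Random rooted shape by sequential pair joins."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]
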