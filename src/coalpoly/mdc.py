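"""Minimize-deep-coalescence inference: species trees and sub-genome assignment.

The central quantity is Maddison's *extra lineages* count: for every cluster
(edge) of a candidate species tree, the number of gene lineages exiting that
cluster minus one, summed over clusters and over a sample of gene trees.
Polyploid alleles are assigned to diploid sub-genome bins by searching over
allele partitions (hill climbing with random reinitialisation), scoring each
candidate labelling by the best species tree it admits.

The model/results pair :class:`SubgenomeModel` / :class:`SubgenomeResults`
is the main user-facing interface; the module-level functions expose the
individual operations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .trees import (
    EncodedTrees,
    Topology,
    encode_dendropy_trees,
    enumerate_topologies,
    topology_clusters,
    topology_to_newick,
)

__all__ = [
    "GeneTreeSample",
    "PolyploidLineage",
    "SubgenomeModel",
    "SubgenomeResults",
    "subsample_gene_trees",
    "count_extra_lineages",
    "mdc_species_tree",
    "score_assignment",
    "hill_climb_assignment",
    "gene_tree_prob_tiebreak",
    "assignment_accuracy",
]

EXHAUSTIVE_MAX_LABELS = 7


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------


@dataclass
class GeneTreeSample:
    """Rooted gene trees for one locus, leaves labelled by allele id."""

    locus_id: str
    encoded: EncodedTrees

    @property
    def n_trees(self) -> int:
        return self.encoded.n_trees

    @property
    def weight(self) -> float:
        return 1.0 / max(self.n_trees, 1)

    @property
    def alleles(self) -> list[str]:
        return list(self.encoded.taxa)

    @classmethod
    def from_trees(
        cls, locus_id: str, trees, taxa=None
    ) -> "GeneTreeSample":
        return cls(locus_id, encode_dendropy_trees(list(trees), taxa=taxa))

    @classmethod
    def from_newick_file(cls, locus_id: str, path: str) -> "GeneTreeSample":
        trees = dendropy.TreeList.get(path=path, schema="newick", rooting="force-rooted", preserve_underscores=True)
        return cls.from_trees(locus_id, trees)


def subsample_gene_trees(
    posterior,
    n: int,
    burnin: int = 0,
    seed: int | None = None,
    outgroup: str | None = None,
    locus_id: str = "locus",
) -> GeneTreeSample:
    """Uniform without-replacement subsample of a posterior tree sample.

    The first ``burnin`` trees are discarded; if ``outgroup`` is given each
    tree is rooted on it and the outgroup leaf is pruned afterwards.
    """
    trees = list(posterior)
    if len(trees) - burnin < n:
        raise ValueError(
            f"posterior has {len(trees)} trees; cannot draw {n} after burn-in {burnin}"
        )
    rng = np.random.default_rng(seed)
    kept = trees[burnin:]
    idx = rng.choice(len(kept), size=n, replace=False)
    chosen = [kept[i] for i in sorted(idx)]

    processed = []
    for t in chosen:
        if isinstance(t, str):
            t = dendropy.Tree.get(data=t, schema="newick", rooting="force-rooted", preserve_underscores=True)
        else:
            t = t.clone(depth=1)
        if outgroup is not None:
            og = t.find_node_with_taxon_label(outgroup)
            if og is None:
                raise ValueError(f"outgroup {outgroup!r} missing from a tree")
            t.to_outgroup_position(og, update_bipartitions=False)
            t.prune_taxa([og.taxon])
        processed.append(t)
    return GeneTreeSample.from_trees(locus_id, processed)


@dataclass
class PolyploidLineage:
    """A putative polyploid lineage: its samples share sub-genome bins."""

    name: str
    samples: list[str]
    ploidy: int

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4, 6):
            raise ValueError("ploidy must be 2, 4 or 6")

    @property
    def n_bins(self) -> int:
        return self.ploidy // 2

    @property
    def bin_labels(self) -> list[str]:
        return [f"{self.name}_sg{k + 1}" for k in range(self.n_bins)]


# ----------------------------------------------------------------------
# topology space with shared-cluster bookkeeping
# ----------------------------------------------------------------------


class _TopologySpace:
    """All rooted topologies over n labels, with deduplicated clusters."""

    _cache: dict[int, "_TopologySpace"] = {}

    def __init__(self, n_labels: int):
        self.n = n_labels
        self.topologies = enumerate_topologies(n_labels)
        cluster_index: dict[frozenset[int], int] = {}
        rows, cols = [], []
        for ti, top in enumerate(self.topologies):
            for cl in topology_clusters(top, proper=True):
                ci = cluster_index.setdefault(cl, len(cluster_index))
                rows.append(ti)
                cols.append(ci)
        self.clusters = [None] * len(cluster_index)
        for cl, ci in cluster_index.items():
            self.clusters[ci] = cl
        inc = np.zeros((len(self.topologies), len(cluster_index)), dtype=np.int32)
        inc[rows, cols] = 1
        self.incidence = inc
        # (U, n) bool membership
        self.member = np.zeros((len(self.clusters), n_labels), dtype=bool)
        for ci, cl in enumerate(self.clusters):
            for lab in cl:
                self.member[ci, lab] = True

    @classmethod
    def get(cls, n_labels: int) -> "_TopologySpace":
        if n_labels not in cls._cache:
            cls._cache[n_labels] = cls(n_labels)
        return cls._cache[n_labels]

    def cluster_masks(self, label_masks: np.ndarray) -> np.ndarray:
        sel = np.where(self.member, label_masks[None, :], np.uint64(0))
        return np.bitwise_or.reduce(sel, axis=1)


def _locus_contrib(
    enc: EncodedTrees, label_masks: np.ndarray, space: _TopologySpace
) -> np.ndarray:
    """Extra-lineage contribution of one locus to every topology's score."""
    leaf_xl = int(enc.extra_lineages(label_masks).sum())
    xlu = enc.extra_lineages(space.cluster_masks(label_masks))
    return leaf_xl + space.incidence @ xlu


def _score_single_topology(
    enc: EncodedTrees, label_masks: np.ndarray, top: Topology
) -> int:
    leaf_xl = int(enc.extra_lineages(label_masks).sum())
    clusters = topology_clusters(top, proper=True)
    if clusters:
        masks = np.array(
            [np.bitwise_or.reduce(label_masks[list(cl)]) for cl in clusters],
            dtype=np.uint64,
        )
        leaf_xl += int(enc.extra_lineages(masks).sum())
    return leaf_xl


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------


def _as_dendropy(tree, label: str = "tree") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick", rooting="force-rooted", preserve_underscores=True)


def count_extra_lineages(gene_tree, species_tree, lineage_map: dict[str, str]) -> int:
    """Maddison deep-coalescence count of one gene tree against a species tree.

    ``lineage_map`` sends every gene-tree leaf (allele id) to a species-tree
    leaf label.  All non-root species-tree edges (pendant edges included)
    contribute ``lineages_exiting - 1``.
    """
    gt = _as_dendropy(gene_tree)
    st = _as_dendropy(species_tree)
    for leaf in gt.leaf_node_iter():
        if leaf.taxon.label not in lineage_map:
            raise KeyError(f"gene-tree leaf {leaf.taxon.label!r} has no lineage mapping")

    enc = encode_dendropy_trees([gt])
    # species clusters as allele masks
    label_alleles: dict[str, list[str]] = {}
    for allele, lab in lineage_map.items():
        label_alleles.setdefault(lab, []).append(allele)

    masks = []
    for node in st.preorder_node_iter():
        if node.parent_node is None:
            continue
        labels = [lf.taxon.label for lf in node.leaf_iter()]
        alleles = [a for lab in labels for a in label_alleles.get(lab, [])]
        alleles = [a for a in alleles if a in enc._taxon_index]
        masks.append(enc.mask_of(alleles))
    if not masks:
        return 0
    return int(enc.extra_lineages(np.array(masks, dtype=np.uint64)).sum())


def _build_label_masks(
    samples: list[GeneTreeSample], lineage_map: dict[str, str], labels: list[str]
) -> list[np.ndarray]:
    """Per-locus (n_labels,) allele bitmasks under a fixed labelling."""
    index = {lab: i for i, lab in enumerate(labels)}
    per_locus = []
    for s in samples:
        lm = np.zeros(len(labels), dtype=np.uint64)
        for allele in s.encoded.taxa:
            if allele not in lineage_map:
                raise KeyError(f"allele {allele!r} unmapped")
            lm[index[lineage_map[allele]]] |= s.encoded.taxon_bit(allele)
        per_locus.append(lm)
    return per_locus


def mdc_species_tree(
    samples: list[GeneTreeSample] | GeneTreeSample,
    lineage_map: dict[str, str],
    exhaustive_max: int = EXHAUSTIVE_MAX_LABELS,
    seed: int | None = None,
    nni_starts: int = 5,
):
    """Species tree minimising the total extra-lineage count.

    Exhaustive over all rooted topologies for up to ``exhaustive_max``
    labels (guaranteed optimum); NNI hill climbing with random restarts
    above that.

    Returns ``(newick, score)``.
    """
    if isinstance(samples, GeneTreeSample):
        samples = [samples]
    labels = sorted(set(lineage_map.values()))
    n = len(labels)
    per_locus = _build_label_masks(samples, lineage_map, labels)

    if n <= 2:
        top = 0 if n == 1 else (0, 1)
        score = sum(
            _score_single_topology(s.encoded, lm, top)
            for s, lm in zip(samples, per_locus)
        )
        return topology_to_newick(top, labels), int(score)

    if n <= exhaustive_max:
        space = _TopologySpace.get(n)
        totals = np.zeros(len(space.topologies), dtype=np.int64)
        for s, lm in zip(samples, per_locus):
            totals += _locus_contrib(s.encoded, lm, space)
        best = int(np.argmin(totals))
        return topology_to_newick(space.topologies[best], labels), int(totals[best])

    return _nni_search(samples, per_locus, labels, seed=seed, starts=nni_starts)


def _nni_neighbors(top: Topology) -> list[Topology]:
    """All topologies one nearest-neighbour interchange away.

    For every internal edge (above an internal child), the child's two
    subclades are exchanged with the child's sibling in the two possible
    ways.
    """
    rearrangements: list[tuple[Topology, Topology]] = []  # (node, replacement)

    def rec(node: Topology) -> None:
        if not isinstance(node, tuple):
            return
        left, right = node
        for child, sib in ((left, right), (right, left)):
            if isinstance(child, tuple):
                a, b = child
                rearrangements.append((node, ((a, sib), b)))
                rearrangements.append((node, ((b, sib), a)))
            rec(child)

    def replace(t: Topology, target: Topology, repl: Topology) -> Topology:
        if t is target:
            return repl
        if not isinstance(t, tuple):
            return t
        return (replace(t[0], target, repl), replace(t[1], target, repl))

    rec(top)
    return [replace(top, node, repl) for node, repl in rearrangements]


def _nni_search(samples, per_locus, labels, seed=None, starts=5):
    rng = np.random.default_rng(seed)
    n = len(labels)

    def random_topology() -> Topology:
        items: list[Topology] = list(range(n))
        while len(items) > 1:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
            b = items.pop(j)
            a = items.pop(i)
            items.append((a, b))
        return items[0]

    def score(top: Topology) -> int:
        return sum(
            _score_single_topology(s.encoded, lm, top)
            for s, lm in zip(samples, per_locus)
        )

    best_top, best_score = None, None
    for _ in range(starts):
        cur = random_topology()
        cur_score = score(cur)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(cur):
                s = score(nb)
                if s < cur_score:
                    cur, cur_score = nb, s
                    improved = True
                    break
        if best_score is None or cur_score < best_score:
            best_top, best_score = cur, cur_score
    return topology_to_newick(best_top, labels), int(best_score)


# ----------------------------------------------------------------------
# sub-genome assignment model
# ----------------------------------------------------------------------


def _valid_bin_states(n_alleles: int, n_bins: int) -> list[tuple[int, ...]]:
    """All assignments of ``n_alleles`` labelled alleles to bins, <=2 per bin."""
    states = []
    for combo in itertools.product(range(n_bins), repeat=n_alleles):
        counts = [0] * n_bins
        ok = True
        for b in combo:
            counts[b] += 1
            if counts[b] > 2:
                ok = False
                break
        if ok:
            states.append(combo)
    return states


def _state_neighbors(state: tuple[int, ...], n_bins: int) -> list[tuple[int, ...]]:
    """States reachable by moving one allele, swapping two alleles' bins, or
    permuting the unit's bin labels wholesale.

    The wholesale permutation escapes label-switching local optima: two loci
    whose bins are anti-aligned differ by two swaps, with both intermediate
    single-swap states scoring worse.
    """
    out = set()
    for perm in itertools.permutations(range(n_bins)):
        out.add(tuple(perm[b] for b in state))
    counts = [0] * n_bins
    for b in state:
        counts[b] += 1
    m = len(state)
    for i in range(m):
        for b in range(n_bins):
            if b != state[i] and counts[b] < 2:
                s = list(state)
                s[i] = b
                out.add(tuple(s))
    for i in range(m):
        for j in range(i + 1, m):
            if state[i] != state[j]:
                s = list(state)
                s[i], s[j] = s[j], s[i]
                out.add(tuple(s))
    out.discard(state)
    return sorted(out)


class SubgenomeModel:
    """Assign polyploid alleles to diploid sub-genomes by minimising deep
    coalescence.

    Parameters
    ----------
    gene_tree_samples : list of GeneTreeSample
        One per locus; leaves are allele ids (globally unique).
    diploid_map : dict
        Allele id -> diploid species label, for every diploid allele.
    polyploid_alleles : dict
        Allele id -> polyploid sample id, for every polyploid allele.
    lineages : list of PolyploidLineage
        Grouping of polyploid samples into putative lineages; samples within
        a lineage share the same p/2 sub-genome bins.
    """

    def __init__(
        self,
        gene_tree_samples: list[GeneTreeSample],
        diploid_map: dict[str, str],
        polyploid_alleles: dict[str, str],
        lineages: list[PolyploidLineage],
    ):
        if not lineages:
            raise ValueError("need at least one polyploid lineage")
        self.samples = list(gene_tree_samples)
        self.diploid_map = dict(diploid_map)
        self.polyploid_alleles = dict(polyploid_alleles)
        self.lineages = list(lineages)

        sample_lineage: dict[str, PolyploidLineage] = {}
        for lin in lineages:
            for s in lin.samples:
                if s in sample_lineage:
                    raise ValueError(f"sample {s!r} in two lineages")
                sample_lineage[s] = lin
        self.sample_lineage = sample_lineage

        self.diploid_labels = sorted(set(self.diploid_map.values()))
        self.bin_labels: list[str] = []
        for lin in self.lineages:
            self.bin_labels.extend(lin.bin_labels)
        self.labels = self.diploid_labels + self.bin_labels
        self._label_index = {lab: i for i, lab in enumerate(self.labels)}
        self.n_labels = len(self.labels)
        self.exhaustive = self.n_labels <= EXHAUSTIVE_MAX_LABELS
        if self.exhaustive:
            self._space = _TopologySpace.get(self.n_labels)
        self._contrib_cache: dict[tuple, np.ndarray] = {}

        # per (sample, locus): ordered allele list, bitmasks, state table
        self._units: list[tuple[str, int]] = []  # (sample, locus index)
        self._unit_alleles: dict[tuple[str, int], list[str]] = {}
        self._unit_masks: dict[tuple[str, int], np.ndarray] = {}
        self._unit_states: dict[tuple[str, int], list[tuple[int, ...]]] = {}
        self._unit_bins: dict[tuple[str, int], list[int]] = {}
        # fixed (diploid) part of per-locus label masks
        self._base_masks: list[np.ndarray] = []

        for li, gts in enumerate(self.samples):
            enc = gts.encoded
            base = np.zeros(self.n_labels, dtype=np.uint64)
            per_sample: dict[str, list[str]] = {}
            for allele in enc.taxa:
                if allele in self.diploid_map:
                    base[self._label_index[self.diploid_map[allele]]] |= enc.taxon_bit(
                        allele
                    )
                elif allele in self.polyploid_alleles:
                    per_sample.setdefault(self.polyploid_alleles[allele], []).append(
                        allele
                    )
                else:
                    raise KeyError(f"allele {allele!r} not mapped")
            self._base_masks.append(base)
            for samp, alleles in sorted(per_sample.items()):
                lin = self.sample_lineage.get(samp)
                if lin is None:
                    raise KeyError(f"polyploid sample {samp!r} not in any lineage")
                if len(alleles) > lin.ploidy:
                    raise ValueError(
                        f"{samp}/{gts.locus_id}: {len(alleles)} alleles exceeds ploidy"
                    )
                alleles = sorted(alleles)
                key = (samp, li)
                self._units.append(key)
                self._unit_alleles[key] = alleles
                self._unit_masks[key] = np.array(
                    [enc.taxon_bit(a) for a in alleles], dtype=np.uint64
                )
                self._unit_states[key] = _valid_bin_states(len(alleles), lin.n_bins)
                self._unit_bins[key] = [
                    self._label_index[b] for b in lin.bin_labels
                ]

    # ------------------------------------------------------------------
    def _locus_masks(self, state: dict[tuple[str, int], tuple[int, ...]], li: int):
        masks = self._base_masks[li].copy()
        for key in self._units:
            if key[1] != li:
                continue
            bins = self._unit_bins[key]
            amasks = self._unit_masks[key]
            for a_i, b_i in enumerate(state[key]):
                masks[bins[b_i]] |= amasks[a_i]
        return masks

    def _contrib(self, state, li: int) -> np.ndarray:
        # per locus the score depends only on the joint bin-state of the
        # locus's own units, of which there are few — cache aggressively
        key = (li,) + tuple(state[u] for u in self._units if u[1] == li)
        cached = self._contrib_cache.get(key)
        if cached is None:
            cached = _locus_contrib(
                self.samples[li].encoded, self._locus_masks(state, li), self._space
            )
            self._contrib_cache[key] = cached
        return cached

    def score_state(self, state) -> tuple[int, Topology]:
        """Exact score (best species tree over all topologies) of a state."""
        totals = np.zeros(len(self._space.topologies), dtype=np.int64)
        for li in range(len(self.samples)):
            totals += self._contrib(state, li)
        best = int(np.argmin(totals))
        return int(totals[best]), self._space.topologies[best]

    # ------------------------------------------------------------------
    def assignment_to_state(self, assignment: dict) -> dict:
        """Convert {(sample, locus_id): {allele: bin_label}} to internal state."""
        locus_index = {s.locus_id: i for i, s in enumerate(self.samples)}
        state = {}
        for key in self._units:
            samp, li = key
            lin = self.sample_lineage[samp]
            lookup = assignment[(samp, self.samples[li].locus_id)]
            bin_pos = {b: k for k, b in enumerate(lin.bin_labels)}
            st = tuple(bin_pos[lookup[a]] for a in self._unit_alleles[key])
            counts = np.bincount(st, minlength=lin.n_bins)
            if counts.max(initial=0) > 2:
                raise ValueError(
                    f"{samp}/{self.samples[li].locus_id}: a sub-genome bin "
                    "holds more than 2 alleles"
                )
            state[key] = st
        return state

    def state_to_assignment(self, state) -> dict:
        out: dict[tuple[str, str], dict[str, str]] = {}
        for key in self._units:
            samp, li = key
            lin = self.sample_lineage[samp]
            d = {
                a: lin.bin_labels[b]
                for a, b in zip(self._unit_alleles[key], state[key])
            }
            out[(samp, self.samples[li].locus_id)] = d
        return out

    def lineage_map_for(self, state) -> dict[str, str]:
        """Full allele -> label map implied by a state."""
        lm = dict(self.diploid_map)
        for key in self._units:
            samp, li = key
            lin = self.sample_lineage[samp]
            for a, b in zip(self._unit_alleles[key], state[key]):
                lm[a] = lin.bin_labels[b]
        return lm

    def _canonical_state(self, state: dict) -> dict:
        """Normalise the per-lineage global bin-label permutation.

        Two states that differ only by relabelling a lineage's bins
        consistently across all its samples and loci describe the same
        allele partition; pick the lexicographically smallest representative
        so such duplicates collapse.
        """
        out = dict(state)
        for lin in self.lineages:
            units = [u for u in self._units if self.sample_lineage[u[0]] is lin]
            if not units:
                continue
            best = None
            for perm in itertools.permutations(range(lin.n_bins)):
                mapped = tuple(
                    tuple(perm[b] for b in state[u]) for u in units
                )
                if best is None or mapped < best:
                    best = mapped
            for u, st in zip(units, best):
                out[u] = st
        return out

    def _random_state(self, rng) -> dict:
        return {
            key: self._unit_states[key][rng.integers(len(self._unit_states[key]))]
            for key in self._units
        }

    # ------------------------------------------------------------------
    def fit(
        self,
        iterations: int = 1000,
        restarts: int = 10,
        seed: int | None = None,
        tiebreak: str = "auto",
    ) -> "SubgenomeResults":
        """Hill-climbing search with random reinitialisation.

        One iteration is one accepted move (or one reinitialisation at a
        local optimum).  ``restarts`` independent repetitions are run; if
        distinct best assignments tie on the extra-lineage score, the tie is
        broken by the coalescent gene-tree probability (``tiebreak='auto'``).
        """
        if not self.exhaustive:
            return self._fit_heuristic(iterations, restarts, seed)
        rng = np.random.default_rng(seed)
        n_topo = len(self._space.topologies)
        best_overall: list[tuple[int, dict, Topology]] = []
        trajectory: list[tuple[int, int, int]] = []

        for r in range(restarts):
            state = self._random_state(rng)
            contribs = [
                self._contrib(state, li) for li in range(len(self.samples))
            ]
            totals = np.sum(contribs, axis=0)
            cur_score = int(totals.min())
            best_score = cur_score
            best_state = dict(state)
            it = 0
            while it < iterations:
                moved = False
                units = list(self._units)
                rng.shuffle(units)
                for key in units:
                    nbrs = _state_neighbors(
                        state[key], len(self._unit_bins[key])
                    )
                    order = rng.permutation(len(nbrs))
                    for ni in order:
                        cand = nbrs[ni]
                        old = state[key]
                        state[key] = cand
                        li = key[1]
                        new_contrib = self._contrib(state, li)
                        new_totals = totals - contribs[li] + new_contrib
                        new_score = int(new_totals.min())
                        if new_score < cur_score:
                            contribs[li] = new_contrib
                            totals = new_totals
                            cur_score = new_score
                            moved = True
                            break
                        state[key] = old
                    if moved:
                        break
                it += 1
                if cur_score < best_score:
                    best_score = cur_score
                    best_state = dict(state)
                trajectory.append((r, it, cur_score))
                if not moved:
                    # local optimum: reinitialise
                    state = self._random_state(rng)
                    contribs = [
                        self._contrib(state, li)
                        for li in range(len(self.samples))
                    ]
                    totals = np.sum(contribs, axis=0)
                    cur_score = int(totals.min())
                    if cur_score < best_score:
                        best_score = cur_score
                        best_state = dict(state)
            score, top = self.score_state(best_state)
            best_overall.append((score, best_state, top))

        best_overall.sort(key=lambda t: t[0])
        best_score = best_overall[0][0]
        tied = [t for t in best_overall if t[0] == best_score]
        # deduplicate assignments identical up to bin relabelling
        seen, distinct = set(), []
        for score, st, _ in tied:
            canon = self._canonical_state(st)
            sig = tuple(sorted((k, v) for k, v in canon.items()))
            if sig not in seen:
                seen.add(sig)
                score, top = self.score_state(canon)
                distinct.append((score, canon, top))

        tie_broken = False
        chosen = distinct[0]
        if len(distinct) > 1 and tiebreak == "auto":
            try:
                winner = self._tiebreak_states([d[1] for d in distinct])
                chosen = distinct[winner]
                tie_broken = True
            except Exception as exc:  # pragma: no cover - fallback path
                warnings.warn(f"gene-tree probability tie-break failed: {exc}")

        score, state, top = chosen
        return SubgenomeResults(
            model=self,
            score=score,
            state=state,
            topology=top,
            species_tree=topology_to_newick(top, self.labels),
            trajectory=pd.DataFrame(
                trajectory, columns=["restart", "iteration", "score"]
            ),
            n_tied=len(distinct),
            tie_broken=tie_broken,
        )

    def _fit_heuristic(self, iterations, restarts, seed):
        # >EXHAUSTIVE_MAX_LABELS labels: score states against an NNI-searched
        # species tree instead of the full topology vector.
        rng = np.random.default_rng(seed)
        best = None
        for r in range(restarts):
            state = self._random_state(rng)
            lm = self.lineage_map_for(state)
            tree, cur_score = mdc_species_tree(
                self.samples, lm, seed=int(rng.integers(2**31))
            )
            it = 0
            while it < iterations:
                moved = False
                for key in rng.permutation(len(self._units)):
                    key = self._units[int(key)]
                    for cand in _state_neighbors(
                        state[key], len(self._unit_bins[key])
                    ):
                        old = state[key]
                        state[key] = cand
                        t2, s2 = mdc_species_tree(
                            self.samples,
                            self.lineage_map_for(state),
                            seed=int(rng.integers(2**31)),
                        )
                        if s2 < cur_score:
                            tree, cur_score = t2, s2
                            moved = True
                            break
                        state[key] = old
                    if moved:
                        break
                it += 1
                if not moved:
                    break
            if best is None or cur_score < best[0]:
                best = (cur_score, dict(state), tree)
        score, state, tree = best
        return SubgenomeResults(
            model=self,
            score=score,
            state=state,
            topology=None,
            species_tree=tree,
            trajectory=pd.DataFrame(columns=["restart", "iteration", "score"]),
            n_tied=1,
            tie_broken=False,
        )

    def _tiebreak_states(self, states: list[dict]) -> int:
        from .coalprob import log_prob_assignment

        def lexicographic() -> int:
            sigs = [tuple(sorted(st.items())) for st in states]
            return min(range(len(sigs)), key=lambda i: sigs[i])

        if self.n_labels > 8:
            warnings.warn(
                "more than 8 lineages: tie broken lexicographically, not by "
                "coalescent gene-tree probability"
            )
            return lexicographic()
        try:
            logps = []
            for st in states:
                _, top = self.score_state(st)
                logps.append(
                    log_prob_assignment(
                        self.samples, self.lineage_map_for(st), top, self.labels
                    )
                )
            return int(np.argmax(logps))
        except ValueError as exc:
            warnings.warn(f"tie broken lexicographically: {exc}")
            return lexicographic()


@dataclass
class SubgenomeResults:
    """Result of a sub-genome assignment search."""

    model: SubgenomeModel
    score: int
    state: dict
    topology: Topology | None
    species_tree: str
    trajectory: pd.DataFrame
    n_tied: int = 1
    tie_broken: bool = False

    @property
    def assignment(self) -> dict:
        return self.model.state_to_assignment(self.state)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (sample, locus), d in sorted(self.assignment.items()):
            for allele, sg in sorted(d.items()):
                rows.append((sample, locus, allele, sg))
        return pd.DataFrame(rows, columns=["sample", "locus", "allele", "subgenome"])

    def summary(self) -> str:
        lines = [
            "Sub-genome assignment by minimum deep coalescence",
            "=" * 49,
            f"Loci:                 {len(self.model.samples)}",
            f"Gene trees:           {sum(s.n_trees for s in self.model.samples)}",
            f"Lineage labels:       {', '.join(self.model.labels)}",
            f"Total extra lineages: {self.score}",
            f"Best MUL species tree: {self.species_tree}",
        ]
        if self.n_tied > 1:
            how = "coalescent gene-tree probability" if self.tie_broken else "order"
            lines.append(
                f"Tied optima:          {self.n_tied} (broken by {how})"
            )
        lines.append("")
        lines.append(self.to_dataframe().to_string(index=False))
        return "\n".join(lines)


# ----------------------------------------------------------------------
# functional wrappers + helpers
# ----------------------------------------------------------------------


def score_assignment(
    gene_tree_samples: list[GeneTreeSample],
    assignment: dict,
    diploid_map: dict[str, str],
    polyploid_alleles: dict[str, str],
    lineages: list[PolyploidLineage],
) -> int:
    """Extra-lineage score of a complete assignment under its best species tree."""
    model = SubgenomeModel(gene_tree_samples, diploid_map, polyploid_alleles, lineages)
    state = model.assignment_to_state(assignment)
    score, _ = model.score_state(state)
    return score


def hill_climb_assignment(
    gene_tree_samples: list[GeneTreeSample],
    diploid_map: dict[str, str],
    polyploid_alleles: dict[str, str],
    lineages: list[PolyploidLineage],
    iterations: int = 1000,
    restarts: int = 10,
    seed: int | None = None,
) -> SubgenomeResults:
    model = SubgenomeModel(gene_tree_samples, diploid_map, polyploid_alleles, lineages)
    return model.fit(iterations=iterations, restarts=restarts, seed=seed)


def gene_tree_prob_tiebreak(
    model: SubgenomeModel, assignment_a: dict, assignment_b: dict
):
    """Break a score tie between two assignments by MSC gene-tree probability.

    Raises ``ValueError`` when the two assignments do not tie.
    """
    sa = model.assignment_to_state(assignment_a)
    sb = model.assignment_to_state(assignment_b)
    score_a, _ = model.score_state(sa)
    score_b, _ = model.score_state(sb)
    if score_a != score_b:
        raise ValueError(f"assignments do not tie ({score_a} vs {score_b})")
    if sa == sb:
        return assignment_a
    winner = model._tiebreak_states([sa, sb])
    return assignment_a if winner == 0 else assignment_b


def assignment_accuracy(
    assignment: dict,
    truth: dict,
    lineages: list[PolyploidLineage],
) -> float:
    """Allele-level agreement with a truth assignment.

    Sub-genome bin labels are exchangeable per lineage, so the agreement is
    maximised over one bin permutation per lineage applied consistently
    across all of that lineage's samples and loci.
    """
    total = 0
    matched = 0
    by_lineage: dict[str, list[tuple[str, str]]] = {lin.name: [] for lin in lineages}
    lin_by_sample = {s: lin for lin in lineages for s in lin.samples}
    per_lineage_pairs: dict[str, list[tuple[str, str]]] = {
        lin.name: [] for lin in lineages
    }
    for key, d in assignment.items():
        sample = key[0]
        lin = lin_by_sample[sample]
        td = truth[key]
        for allele, sg in d.items():
            per_lineage_pairs[lin.name].append((sg, td[allele]))
    for lin in lineages:
        pairs = per_lineage_pairs[lin.name]
        if not pairs:
            continue
        bins = lin.bin_labels
        truth_bins = sorted({t for _, t in pairs})
        best = 0
        for perm in itertools.permutations(bins, len(truth_bins)):
            mapping = dict(zip(truth_bins, perm))
            best = max(
                best, sum(1 for got, want in pairs if got == mapping[want])
            )
        matched += best
        total += len(pairs)
    return matched / total if total else float("nan")
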