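"""Coalescent simulation of planted auto-/allopolyploid histories.

Generates everything the downstream stages consume, with truth labels:

* a dated multi-labeled (MUL) species tree in which every sub-genome of a
  polyploid is a leaf, plus its folded network;
* per-locus rooted gene trees under the multispecies coalescent within that
  MUL-tree (msprime), emulating posterior tree samples as independent
  coalescent draws that share one allele label set;
* true allele sequences (HKY mutations on a simulated genealogy) and
  amplicon reads with per-base errors, Phred strings and PCR chimeras.

Allopolyploid sub-genomes are modelled disomically (each sub-genome is its
own population from the present back to the origin, then merges into its
diploid parent); autopolyploids are tetra-/hexasomic (all allele copies
share a single population until the origin, when it merges into the single
parent), which is why an autopolyploid's sub-genome bins are exchangeable.
The plastid locus carries one lineage per sample routed through the
maternal parent only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import msprime
import numpy as np

from .alleles import AlleleSet, Read
from .mdc import GeneTreeSample, PolyploidLineage
from .trees import EncodedTrees

__all__ = [
    "PolyploidEvent",
    "SimulationConfig",
    "PlantedHistory",
    "simulate_history",
    "simulate_gene_trees",
    "simulate_alleles",
    "simulate_reads",
    "random_allele_set",
    "write_gene_trees",
    "write_truth_tables",
    "write_reads_fastq",
]

PLASTID = "plastid"


@dataclass
class PolyploidEvent:
    """One polyploid formation.

    ``kind='auto'``: genome doubling within ``parents[0]``.
    ``kind='allo'``: merger of two (tetraploid) or three (hexaploid)
    parental genomes; ``parents[maternal]`` contributes the plastid.
    ``origin_ma`` is the formation time in million years before present.
    """

    kind: str
    sample: str
    parents: tuple[str, ...]
    origin_ma: float
    ploidy: int = 4
    maternal: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("auto", "allo"):
            raise ValueError("kind must be 'auto' or 'allo'")
        if self.ploidy not in (4, 6):
            raise ValueError("polyploid ploidy must be 4 or 6")
        if self.kind == "auto":
            if len(self.parents) != 1:
                raise ValueError("an autopolyploid has one parent lineage")
        else:
            if len(self.parents) != self.ploidy // 2:
                raise ValueError(
                    "an allopolyploid needs one parent per sub-genome "
                    f"({self.ploidy // 2} for {self.ploidy}x)"
                )
            if len(set(self.parents)) != len(self.parents):
                raise ValueError("allopolyploid parents must be distinct")
        if self.origin_ma <= 0:
            raise ValueError("origin time must be positive")

    @property
    def n_subgenomes(self) -> int:
        return self.ploidy // 2

    def subgenome_labels(self) -> list[str]:
        return [f"{self.sample}_sg{k + 1}" for k in range(self.n_subgenomes)]


@dataclass
class SimulationConfig:
    """Study-scale defaults: a small clade with crown age 4.39 Ma, five
    nuclear loci plus one plastid locus, 3-year generation time and a plant
    nuclear substitution rate of 5e-9 /site/year."""

    n_diploid_lineages: int = 4
    polyploid_events: list[PolyploidEvent] = field(default_factory=list)
    crown_age_ma: float = 4.39
    crown_age_sd_ma: float = 0.91
    pop_size: float = 5e4  # diploid effective size per branch
    generation_time: float = 3.0
    n_nuclear_loci: int = 5
    include_plastid: bool = True
    n_trees_per_locus: int = 1
    seq_length: int = 300
    subst_rate: float = 5e-9  # substitutions / site / year
    kappa: float = 3.0
    read_depth: int = 300
    error_rate: float = 0.01
    chimera_rate: float = 0.0
    lowq_read_frac: float = 0.05
    rng_seed: int = 0
    species_tree_newick: str | None = None  # dated diploid tree (ages in Ma)

    def __post_init__(self) -> None:
        for name in ("crown_age_ma", "pop_size", "generation_time", "subst_rate",
                     "error_rate", "crown_age_sd_ma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.chimera_rate < 1.0:
            raise ValueError("chimera_rate must lie in [0, 1)")
        for ev in self.polyploid_events:
            if ev.origin_ma >= self.crown_age_ma:
                raise ValueError(
                    f"polyploid {ev.sample}: origin {ev.origin_ma} Ma is not "
                    f"below the crown age {self.crown_age_ma} Ma"
                )
        names = [ev.sample for ev in self.polyploid_events]
        if len(set(names)) != len(names):
            raise ValueError("polyploid sample names must be unique")

    @property
    def coalescent_unit_ma(self) -> float:
        """One coalescent unit (2N generations) in Ma."""
        return 2 * self.pop_size * self.generation_time / 1e6

    def nuclear_locus_ids(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_nuclear_loci)]


# ----------------------------------------------------------------------
# planted history
# ----------------------------------------------------------------------


class _Node:
    __slots__ = ("name", "age", "children")

    def __init__(self, name: str | None, age: float, children=None):
        self.name = name
        self.age = age
        self.children: list[_Node] = children or []

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PlantedHistory:
    """Truth produced by :func:`simulate_history`."""

    config: SimulationConfig
    mul_tree: dendropy.Tree
    diploids: list[str]
    events: list[PolyploidEvent]
    truth_assignment: dict[str, str]  # allele-slot "sample:i" -> sub-genome label
    maternal_parent: dict[str, str]  # polyploid sample -> maternal sub-genome label
    _root: _Node = None

    @property
    def network(self):
        from .netbuild import join_subgenome_leaves

        polymap = {ev.sample: ev.subgenome_labels() for ev in self.events}
        maternal = dict(self.maternal_parent)
        return join_subgenome_leaves(self.mul_tree, polymap, maternal)

    @property
    def sample_ploidies(self) -> dict[str, int]:
        out = {d: 2 for d in self.diploids}
        out.update({ev.sample: ev.ploidy for ev in self.events})
        return out

    def lineages(self) -> list[PolyploidLineage]:
        return [
            PolyploidLineage(ev.sample, [ev.sample], ev.ploidy) for ev in self.events
        ]

    def truth_for_locus(self, locus_id: str) -> dict:
        """{(sample, locus): {allele_id: sub-genome label}} truth assignment."""
        out: dict[tuple[str, str], dict[str, str]] = {}
        for slot, label in self.truth_assignment.items():
            sample, idx = slot.rsplit(":", 1)
            allele = f"{sample}.{locus_id}.a{idx}"
            out.setdefault((sample, locus_id), {})[allele] = label
        return out


def _random_dated_tree(names: list[str], crown_age: float, rng) -> _Node:
    """Random topology by sequential joins; internal node ages are sorted
    uniforms below the crown age (root pinned at the crown age)."""
    n = len(names)
    nodes = [_Node(nm, 0.0) for nm in names]
    if n == 1:
        return nodes[0]
    ages = sorted(rng.uniform(0.2 * crown_age, 0.95 * crown_age, size=n - 2))
    ages.append(crown_age)
    k = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(_Node(None, ages[k], [a, b]))
        k += 1
    # ensure child ages below parents (re-sort by construction order)
    _fix_ages(nodes[0])
    return nodes[0]


def _fix_ages(node: _Node) -> float:
    if not node.children:
        return node.age
    hi = max(_fix_ages(c) for c in node.children)
    if node.age <= hi:
        node.age = hi + 1e-6
    return node.age


def _parse_dated_newick(newick: str) -> _Node:
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True)
    tree.calc_node_ages(ultrametricity_precision=1e-3)

    def conv(nd) -> _Node:
        if nd.is_leaf():
            return _Node(nd.taxon.label, 0.0)
        return _Node(None, float(nd.age), [conv(c) for c in nd.child_nodes()])

    return conv(tree.seed_node)


def _attach_at(root: _Node, leaf_name: str, age: float, subtree: _Node) -> None:
    """Insert an attachment node at ``age`` on the path from the named leaf
    toward the root, and hang ``subtree`` there."""
    path: list[_Node] = []

    def find(node: _Node) -> bool:
        path.append(node)
        if node.name == leaf_name and not node.children:
            return True
        for c in node.children:
            if find(c):
                return True
        path.pop()
        return False

    if not find(root):
        raise ValueError(f"parent lineage {leaf_name!r} not in the species tree")
    # only the pendant branch counts as the named lineage: above its parent
    # node the branch belongs to an ancestor shared with other lineages
    # (events are applied deepest-first, so earlier attachments on the same
    # branch have already shortened the pendant edge consistently)
    leaf, parent = path[-1], path[-2]
    if not age < parent.age:
        raise ValueError(
            f"lineage {leaf_name!r} is not extant at {age} Ma: its branch "
            f"merges at {parent.age:g} Ma; choose a younger origin or "
            "another parent"
        )
    join = _Node(None, age, [leaf, subtree])
    parent.children[parent.children.index(leaf)] = join


def _to_dendropy(root: _Node) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: _Node, parent) -> None:
        nd = parent.new_child()
        nd.age_ma = node.age
        if not node.children:
            nd.taxon = taxa.require_taxon(label=node.name)
        for c in node.children:
            build(c, nd)
        nd.edge.length = None

    tree.seed_node.age_ma = root.age
    for c in root.children:
        build(c, tree.seed_node)
    if not root.children:
        tree.seed_node.taxon = taxa.require_taxon(label=root.name)
    # branch lengths from ages
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age_ma - nd.age_ma
    return tree


def simulate_history(config: SimulationConfig) -> PlantedHistory:
    """Build the planted MUL-tree and truth labels for a configuration."""
    rng = np.random.default_rng(config.rng_seed)
    names = [f"D{i + 1}" for i in range(config.n_diploid_lineages)]
    if config.species_tree_newick is not None:
        root = _parse_dated_newick(config.species_tree_newick)
        names = [lf.name for lf in root.leaves()]
    else:
        root = _random_dated_tree(names, config.crown_age_ma, rng)

    truth: dict[str, str] = {}
    maternal: dict[str, str] = {}
    # process events deepest-first so nested attachments stay consistent;
    # repeat attachments to one parent at the same origin time are nudged
    # apart by a negligible epsilon so each gets its own join node
    used: dict[tuple[str, float], int] = {}

    def attach(parent: str, age: float, subtree: _Node) -> None:
        k = used.get((parent, age), 0)
        used[(parent, age)] = k + 1
        adjusted = age - 1e-6 * k
        subtree.age = min(subtree.age, adjusted)
        _attach_at(root, parent, adjusted, subtree)

    for ev in sorted(config.polyploid_events, key=lambda e: -e.origin_ma):
        labels = ev.subgenome_labels()
        if ev.kind == "auto":
            sub = _Node(None, ev.origin_ma, [_Node(lab, 0.0) for lab in labels])
            attach(ev.parents[0], ev.origin_ma, sub)
            maternal[ev.sample] = labels[ev.maternal]
        else:
            for lab, parent in zip(labels, ev.parents):
                attach(parent, ev.origin_ma, _Node(lab, 0.0))
            maternal[ev.sample] = labels[ev.maternal]
        for i in range(ev.ploidy):
            truth[f"{ev.sample}:{i}"] = labels[i // 2]
    for d in names:
        for i in range(2):
            truth[f"{d}:{i}"] = d

    return PlantedHistory(
        config=config,
        mul_tree=_to_dendropy(root),
        diploids=names,
        events=list(config.polyploid_events),
        truth_assignment=truth,
        maternal_parent=maternal,
        _root=root,
    )


# ----------------------------------------------------------------------
# demography + gene trees
# ----------------------------------------------------------------------


def _demography(history: PlantedHistory, plastid: bool) -> msprime.Demography:
    """msprime demography mirroring the MUL-tree.

    Allopolyploid sub-genomes are separate populations; an autopolyploid is
    one population holding all its allele copies.  Sizes are in lineage
    copies: 2N for nuclear branches, N (maternal haploid transmission) for
    the plastid locus.
    """
    cfg = history.config
    size = cfg.pop_size if plastid else 2 * cfg.pop_size
    to_gen = 1e6 / cfg.generation_time
    demo = msprime.Demography()

    auto_samples = {ev.sample for ev in history.events if ev.kind == "auto"}

    counter = [0]

    def pop_name(node: _Node) -> str:
        if node.name is not None:
            return node.name
        counter[0] += 1
        return f"anc{counter[0]}"

    def add(node: _Node) -> str:
        # collapse an autopolyploid cherry into a single (polysomic) population
        if node.children and all(
            not c.children
            and c.name is not None
            and "_sg" in c.name
            and c.name.rsplit("_sg", 1)[0] in auto_samples
            for c in node.children
        ) and len({c.name.rsplit("_sg", 1)[0] for c in node.children}) == 1:
            sample = node.children[0].name.rsplit("_sg", 1)[0]
            demo.add_population(name=sample, initial_size=size)
            return sample
        name = pop_name(node)
        demo.add_population(name=name, initial_size=size)
        if node.children:
            derived = [add(c) for c in node.children]
            demo.add_population_split(
                time=node.age * to_gen, derived=derived, ancestral=name
            )
        return name

    add(history._root)
    demo.sort_events()
    return demo


def _sample_sets(history: PlantedHistory, plastid: bool):
    """SampleSets plus the allele-name pattern (sample, index) per lineage."""
    sets = []
    slots: list[tuple[str, int]] = []
    for d in history.diploids:
        n = 1 if plastid else 2
        sets.append(msprime.SampleSet(n, population=d, ploidy=1))
        slots.extend((d, i) for i in range(n))
    for ev in history.events:
        if plastid:
            pop = ev.sample if ev.kind == "auto" else history.maternal_parent[ev.sample]
            sets.append(msprime.SampleSet(1, population=pop, ploidy=1))
            slots.append((ev.sample, 0))
        elif ev.kind == "auto":
            sets.append(msprime.SampleSet(ev.ploidy, population=ev.sample, ploidy=1))
            slots.extend((ev.sample, i) for i in range(ev.ploidy))
        else:
            for k, lab in enumerate(ev.subgenome_labels()):
                sets.append(msprime.SampleSet(2, population=lab, ploidy=1))
                slots.extend((ev.sample, 2 * k + i) for i in range(2))
    return sets, slots


def _encode_tskit(ts_iter, taxa: list[str], n_trees: int) -> EncodedTrees:
    sentinel = np.uint64(1) << np.uint64(63)
    clades_all, parents_all, offsets = [], [], [0]
    for ts in ts_iter:
        tree = ts.first()
        mask: dict[int, int] = {}
        rows: list[tuple[int, int]] = []  # (mask, parent node id)
        order = list(tree.nodes(order="postorder"))
        for u in order:
            if tree.is_leaf(u):
                mask[u] = 1 << u
            else:
                m = 0
                for c in tree.children(u):
                    m |= mask[c]
                mask[u] = m
        clades = np.array([mask[u] for u in order], dtype=np.uint64)
        parents = np.empty(len(order), dtype=np.uint64)
        for i, u in enumerate(order):
            p = tree.parent(u)
            if p == -1:
                parents[i] = np.uint64(mask[u]) | sentinel
            else:
                parents[i] = np.uint64(mask[p])
        clades_all.append(clades)
        parents_all.append(parents)
        offsets.append(offsets[-1] + len(order))
    return EncodedTrees(
        taxa=taxa,
        clades=np.concatenate(clades_all),
        parents=np.concatenate(parents_all),
        offsets=np.asarray(offsets, dtype=np.intp),
    )


def simulate_gene_trees(
    history: PlantedHistory,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> list[GeneTreeSample]:
    """Multispecies-coalescent gene trees for every locus.

    Per nuclear locus, ``n_trees_per_locus`` independent rooted genealogies
    (a parametric stand-in for a posterior tree sample); the plastid locus
    carries one lineage per sample routed through the maternal sub-genome.
    """
    cfg = config or history.config
    if seed is None:
        seed = cfg.rng_seed + 1
    rng = np.random.default_rng(seed)
    out: list[GeneTreeSample] = []

    demo_nuc = _demography(history, plastid=False)
    sets_nuc, slots_nuc = _sample_sets(history, plastid=False)
    loci = cfg.nuclear_locus_ids()
    for locus in loci:
        taxa = [f"{s}.{locus}.a{i}" for s, i in slots_nuc]
        reps = msprime.sim_ancestry(
            samples=sets_nuc,
            demography=demo_nuc,
            ploidy=1,
            num_replicates=cfg.n_trees_per_locus,
            random_seed=int(rng.integers(1, 2**31)),
        )
        out.append(GeneTreeSample(locus, _encode_tskit(reps, taxa, cfg.n_trees_per_locus)))

    if cfg.include_plastid:
        demo_pla = _demography(history, plastid=True)
        sets_pla, slots_pla = _sample_sets(history, plastid=True)
        taxa = [f"{s}.{PLASTID}.a{i}" for s, i in slots_pla]
        reps = msprime.sim_ancestry(
            samples=sets_pla,
            demography=demo_pla,
            ploidy=1,
            num_replicates=cfg.n_trees_per_locus,
            random_seed=int(rng.integers(1, 2**31)),
        )
        out.append(
            GeneTreeSample(PLASTID, _encode_tskit(reps, taxa, cfg.n_trees_per_locus))
        )
    return out


# ----------------------------------------------------------------------
# sequences and reads
# ----------------------------------------------------------------------


def simulate_alleles(
    history: PlantedHistory, seed: int | None = None
) -> dict[tuple[str, str], AlleleSet]:
    """True allele sequences per sample x nuclear locus.

    One genealogy per locus; HKY mutations at the configured substitution
    rate; identical sequences within a sample collapse into one allele with
    summed copy support.
    """
    cfg = history.config
    if seed is None:
        seed = cfg.rng_seed + 2
    rng = np.random.default_rng(seed)
    demo = _demography(history, plastid=False)
    sets, slots = _sample_sets(history, plastid=False)
    ploidies = history.sample_ploidies
    out: dict[tuple[str, str], AlleleSet] = {}
    for locus in cfg.nuclear_locus_ids():
        ts = msprime.sim_ancestry(
            samples=sets,
            demography=demo,
            ploidy=1,
            sequence_length=cfg.seq_length,
            random_seed=int(rng.integers(1, 2**31)),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=cfg.subst_rate * cfg.generation_time,
            model=msprime.HKY(kappa=cfg.kappa),
            random_seed=int(rng.integers(1, 2**31)),
        )
        n = len(slots)
        base = rng.choice(list("ACGT"), size=cfg.seq_length)
        seqs = np.tile(base, (n, 1))
        for var in ts.variants():
            pos = int(var.site.position)
            alleles = var.alleles
            for i in range(n):
                seqs[i, pos] = alleles[var.genotypes[i]]
        per_sample: dict[str, list[str]] = {}
        for i, (sample, _) in enumerate(slots):
            per_sample.setdefault(sample, []).append("".join(seqs[i]))
        for sample, seq_list in per_sample.items():
            uniq: dict[str, int] = {}
            for s in seq_list:
                uniq[s] = uniq.get(s, 0) + 1
            ordered = sorted(uniq.items(), key=lambda kv: (-kv[1], kv[0]))
            out[(sample, locus)] = AlleleSet(
                sample,
                locus,
                ploidies[sample],
                [a for a, _ in ordered],
                [c for _, c in ordered],
            )
    return out


def random_allele_set(
    sample_id: str,
    locus_id: str,
    ploidy: int,
    rng,
    length: int = 300,
    divergence: float = 0.08,
) -> AlleleSet:
    """Synthetic allele set with controlled pairwise divergence.

    Each allele carries its own disjoint block of ``divergence * length / 2``
    private substitutions relative to a random root sequence, so every
    allele pair differs at ``divergence * length`` sites.  Used to
    benchmark read-level calling at a realistic homeolog divergence.
    """
    root = rng.choice(list("ACGT"), size=length)
    m = max(1, round(divergence * length / 2))
    positions = rng.permutation(length)[: m * ploidy]
    alleles = []
    for k in range(ploidy):
        seq = root.copy()
        for pos in positions[k * m : (k + 1) * m]:
            cur = seq[pos]
            seq[pos] = rng.choice([b for b in "ACGT" if b != cur])
        alleles.append("".join(seq))
    return AlleleSet(sample_id, locus_id, ploidy, alleles, [1] * ploidy)


def simulate_reads(
    allele_set: AlleleSet,
    config: SimulationConfig,
    rng=None,
) -> list[Read]:
    """Amplicon reads from an allele set, with truth labels in the read ids.

    Reads are drawn from allele copies uniformly; a ``chimera_rate``
    fraction are prefix+suffix recombinants of two distinct alleles with a
    uniform breakpoint.  Per-base Phred scores are drawn first (a high band
    31-41 and a low band 3-15, mixed so the quality-implied error
    probability averages ``error_rate``) and each base is then miscalled
    with its own implied probability — i.e. the quality strings are
    calibrated.  A ``lowq_read_frac`` fraction of reads additionally get a
    quarter of their positions degraded to Phred 2-15 (with the implied
    extra errors), to exercise the read-level QC filter.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 3)
    alleles = allele_set.alleles
    weights = np.asarray(allele_set.support, dtype=float)
    weights /= weights.sum()
    length = len(alleles[0])
    mats = [np.frombuffer(a.encode(), dtype=np.uint8).copy() for a in alleles]

    high_band = np.arange(31, 42)
    low_band = np.arange(3, 16)
    p_high = float(np.mean(10.0 ** (-high_band / 10)))
    p_low = float(np.mean(10.0 ** (-low_band / 10)))
    w_low = float(np.clip((config.error_rate - p_high) / (p_low - p_high), 0.0, 1.0))
    mixture_mean = w_low * p_low + (1 - w_low) * p_high
    # rescale so the marginal per-base error equals error_rate exactly
    # (in particular zero errors when error_rate = 0)
    scale = config.error_rate / mixture_mean if mixture_mean > 0 else 0.0

    def draw_quals(n: int) -> np.ndarray:
        lo = rng.random(n) < w_low
        q = rng.choice(high_band, size=n)
        q[lo] = rng.choice(low_band, size=int(lo.sum()))
        return q

    def apply_errors(seq: np.ndarray, quals: np.ndarray) -> np.ndarray:
        p = scale * 10.0 ** (-quals / 10)
        err = rng.random(len(seq)) < p
        for pos in np.nonzero(err)[0]:
            cur = chr(seq[pos])
            seq[pos] = ord(rng.choice([b for b in "ACGT" if b != cur]))
        return seq

    reads: list[Read] = []
    for i in range(config.read_depth):
        is_chimera = len(alleles) >= 2 and rng.random() < config.chimera_rate
        if is_chimera:
            a, b = rng.choice(len(alleles), size=2, replace=False)
            k = int(rng.integers(1, length))
            seq = np.concatenate([mats[a][:k], mats[b][k:]])
            tag = f"chimera={a},{b},{k}"
        else:
            a = int(rng.choice(len(alleles), p=weights))
            seq = mats[a].copy()
            tag = f"allele={a}"
        quals = draw_quals(length)
        if rng.random() < config.lowq_read_frac:
            degrade = rng.random(length) < 0.25
            quals[degrade] = rng.integers(2, 16, size=int(degrade.sum()))
        seq = apply_errors(seq, quals)
        reads.append(
            Read(
                f"{allele_set.sample_id}|{allele_set.locus_id}|read{i}|{tag}",
                seq.tobytes().decode(),
                [int(q) for q in quals],
            )
        )
    return reads


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------


def write_gene_trees(samples: list[GeneTreeSample], outdir) -> None:
    """One newick file per locus, one tree per line (topology only)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gts in samples:
        enc = gts.encoded
        with open(outdir / f"{gts.locus_id}.nwk", "w") as fh:
            for ti in range(enc.n_trees):
                fh.write(_encoded_to_newick(enc, ti) + "\n")


def _encoded_to_newick(enc: EncodedTrees, tree_index: int) -> str:
    lo, hi = enc.offsets[tree_index], enc.offsets[tree_index + 1]
    clades = [int(c) for c in enc.clades[lo:hi]]
    parents = [int(p) for p in enc.parents[lo:hi]]
    n = hi - lo
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    root = None
    for i in range(n):
        if parents[i] >> 63:
            root = i
            continue
        for j in range(i + 1, n):
            if clades[j] == parents[i] and (clades[j] & clades[i]) == clades[i]:
                children[j].append(i)
                break

    def fmt(i: int) -> str:
        if not children[i]:
            return enc.taxa[clades[i].bit_length() - 1]
        return "(" + ",".join(fmt(c) for c in children[i]) + ")"

    return fmt(root) + ";"


def write_truth_tables(history: PlantedHistory, outdir) -> None:
    """TSV truth tables: sample ploidies and allele-slot sub-genome labels."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "ploidy.tsv", "w") as fh:
        fh.write("sample\tploidy\n")
        for s, p in sorted(history.sample_ploidies.items()):
            fh.write(f"{s}\t{p}\n")
    with open(outdir / "truth_subgenomes.tsv", "w") as fh:
        fh.write("sample\tallele_index\tsubgenome\n")
        for slot, label in sorted(history.truth_assignment.items()):
            sample, idx = slot.rsplit(":", 1)
            fh.write(f"{sample}\t{idx}\t{label}\n")
    history.mul_tree.write(
        path=str(outdir / "mul_tree.nwk"), schema="newick",
        suppress_rooting=True,
    )


def write_reads_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(min(q, 93) + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{q}\n")
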