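"""Statistical-parsimony (TCS-style) haplotype networks for plastid data.

Aligned sequences are collapsed into distinct haplotypes, a maximum
connection distance is derived from the probability that a connection of
j mutational steps is parsimonious (no superimposed substitutions), and
haplotypes are then joined in increasing step order, inserting hypothetical
intermediate nodes for multi-step connections and retaining all
equal-length alternative connections (reticulations allowed).  Pairs beyond
the connection limit stay in separate components.

The parsimony probability follows a per-site Poisson substitution model
with a Jukes-Cantor multiple-hit correction, moment-matched to the
observed divergence j/L:

    lambda(j) = -(3/4) ln(1 - 4j/(3L))
    P_j = [ lambda e^(-lambda) / ((3/4)(1 - e^(-4 lambda/3))) ]^j

i.e. the probability that each of the j observed differences reflects
exactly one substitution.  The construction order (not any particular
published program variant) is what is documented and tested here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .seqprep import Alignment, _gap_runs

__all__ = [
    "HaplotypeTable",
    "HaplotypeNetwork",
    "collapse_haplotypes",
    "step_distance",
    "parsimony_probability",
    "parsimony_limit",
    "build_network",
]


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with their carriers."""

    sequences: list[str]
    members: list[list[str]]
    indel_mode: str = "single-step"
    flagged: list[str] = field(default_factory=list)

    @property
    def counts(self) -> list[int]:
        return [len(m) for m in self.members]

    @property
    def n_samples(self) -> int:
        return sum(self.counts)


def collapse_haplotypes(
    aln: Alignment,
    indel_mode: str = "single-step",
    long_deletion_threshold: int = 20,
) -> HaplotypeTable:
    """Merge identical sequences into haplotypes.

    ``indel_mode='ignore'`` drops every column containing a gap before
    comparing; ``'single-step'`` keeps gaps, so indels are part of haplotype
    identity (and later count one mutational step per contiguous run).
    Samples with a deletion longer than ``long_deletion_threshold`` are
    flagged: such haplotypes are ambiguous and candidates for exclusion.
    """
    if indel_mode not in ("single-step", "ignore"):
        raise ValueError("indel_mode must be 'single-step' or 'ignore'")
    seqs = {k: v.upper() for k, v in aln.sequences.items()}
    flagged = sorted(
        sid
        for sid, s in seqs.items()
        if any(b - a + 1 > long_deletion_threshold for a, b in _gap_runs(s))
    )
    if indel_mode == "ignore":
        gap_cols = set()
        for s in seqs.values():
            gap_cols.update(i for i, c in enumerate(s) if c == "-")
        keep = [i for i in range(aln.length) if i not in gap_cols]
        seqs = {sid: "".join(s[i] for i in keep) for sid, s in seqs.items()}

    order: dict[str, list[str]] = {}
    for sid, s in seqs.items():
        order.setdefault(s, []).append(sid)
    items = sorted(order.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    return HaplotypeTable(
        sequences=[s for s, _ in items],
        members=[sorted(m) for _, m in items],
        indel_mode=indel_mode,
        flagged=flagged,
    )


def step_distance(a: str, b: str, indel_mode: str = "single-step") -> int:
    """Mutational steps between two aligned haplotypes: one per substitution
    plus (in ``single-step`` mode) one per gap run present in only one of
    the two sequences."""
    subs = sum(
        1 for x, y in zip(a, b) if x != y and x != "-" and y != "-"
    )
    if indel_mode == "ignore":
        return subs
    runs_a, runs_b = set(_gap_runs(a)), set(_gap_runs(b))
    return subs + len(runs_a ^ runs_b)


def parsimony_probability(j: int, seq_length: int) -> float:
    """Probability that a j-step connection over ``seq_length`` sites is
    parsimonious (every observed difference is a single substitution)."""
    if j <= 0:
        return 1.0
    x = 4 * j / (3 * seq_length)
    if x >= 1.0:
        return 0.0
    lam = -0.75 * math.log1p(-x)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))
    p_single = lam * math.exp(-lam) / p_diff
    return p_single**j


def parsimony_limit(seq_length: int, alpha: float = 0.95) -> int:
    """Largest number of steps whose parsimonious interpretation holds with
    probability at least ``alpha``; nondecreasing in ``seq_length``."""
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    j = 0
    while parsimony_probability(j + 1, seq_length) >= alpha:
        j += 1
    return j


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    connection_limit: int
    table: HaplotypeTable

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def component_of(self, sample_id: str):
        for i, hap_members in enumerate(self.table.members):
            if sample_id in hap_members:
                node = f"H{i + 1}"
                for comp in self.components:
                    if node in comp:
                        return comp
        raise KeyError(f"sample {sample_id!r} not in the haplotype table")

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            [
                {
                    "node": n,
                    "observed": d.get("observed", False),
                    "count": d.get("count", 0),
                    "samples": ",".join(d.get("samples", [])),
                }
                for n, d in self.graph.nodes(data=True)
            ]
        )
        edges = pd.DataFrame(
            [{"node1": u, "node2": v} for u, v in self.graph.edges()]
        )
        return nodes, edges


def build_network(
    table: HaplotypeTable,
    limit: int | None = None,
    alpha: float = 0.95,
) -> HaplotypeNetwork:
    """Join haplotypes up to the parsimony connection limit.

    Pairs are processed in increasing mutational distance; a pair is
    connected (inserting ``d - 1`` hypothetical intermediates for a d-step
    connection) unless the current network already links it at graph
    distance <= d.  All pairs at the same distance are judged against the
    same network snapshot, so equal-length alternative connections are all
    retained.
    """
    n = len(table.sequences)
    if limit is None:
        length = len(table.sequences[0]) if n else 0
        limit = parsimony_limit(max(length, 1), alpha)
    g = nx.Graph()
    names = [f"H{i + 1}" for i in range(n)]
    for i, name in enumerate(names):
        g.add_node(
            name,
            observed=True,
            count=len(table.members[i]),
            samples=list(table.members[i]),
        )
    dist = {
        (i, j): step_distance(
            table.sequences[i], table.sequences[j], table.indel_mode
        )
        for i, j in itertools.combinations(range(n), 2)
    }
    hyp_counter = [0]

    def connect(u: str, v: str, d: int) -> None:
        prev = u
        for _ in range(d - 1):
            hyp_counter[0] += 1
            h = f"h{hyp_counter[0]}"
            g.add_node(h, observed=False, count=0, samples=[])
            g.add_edge(prev, h)
            prev = h
        g.add_edge(prev, v)

    for d in range(1, limit + 1):
        pairs = [ij for ij, dd in dist.items() if dd == d]
        if not pairs:
            continue
        snapshot = dict(nx.all_pairs_shortest_path_length(g))
        for i, j in pairs:
            u, v = names[i], names[j]
            cur = snapshot.get(u, {}).get(v)
            if cur is not None and cur <= d:
                continue
            connect(u, v, d)
    return HaplotypeNetwork(graph=g, connection_limit=limit, table=table)
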