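"""From multi-labeled species trees to reticulate species networks.

A MUL-tree carries one leaf per sub-genome of every polyploid.  Folding it
joins each polyploid's sub-genome leaves into a single network leaf that
receives one incoming edge per former leaf position: an allopolyploid
becomes a reticulation (in-degree 2, or 3 for a three-parent hexaploid),
while an autopolyploid — whose sub-genome leaves are sisters — folds to an
ordinary tree node annotated as autopolyploid.  Branches below a posterior
support threshold are collapsed into polytomies, and a polyploid's age
interval is the covering interval of its sub-genomes' divergence-time HPDs.

Species-delimitation scenarios (ways of grouping polyploid samples into
lineages) are ranked by the total deep-coalescence score of their best
sub-genome assignment, a surrogate criterion for marginal-likelihood
comparison.
"""

from __future__ import annotations

import warnings

import dendropy
import networkx as nx
import pandas as pd

from .mdc import GeneTreeSample, PolyploidLineage, SubgenomeModel

__all__ = [
    "read_mul_tree",
    "collapse_low_support",
    "join_subgenome_leaves",
    "merge_hpd",
    "polyploid_age_interval",
    "rank_scenarios",
    "network_to_edge_table",
]

SCORE_COLUMN = "mdc_score (surrogate criterion)"


def read_mul_tree(path, schema: str = "nexus") -> dendropy.Tree:
    """Read an annotated (BEAST/FigTree dialect) MUL-tree.

    Node comments like ``posterior`` and ``height_95%_HPD`` become dendropy
    annotations accessible to :func:`collapse_low_support` and
    :func:`polyploid_age_interval`.
    """
    return dendropy.Tree.get(
        path=str(path),
        schema=schema,
        extract_comment_metadata=True,
        rooting="force-rooted",
    )


def _support(node) -> float | None:
    val = node.annotations.get_value("posterior")
    if val is not None:
        return float(val)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def _hpd(node) -> tuple[float, float] | None:
    for key in ("height_95%_HPD", "height_95%HPD", "age_95%_HPD"):
        val = node.annotations.get_value(key)
        if val is not None:
            lo, hi = (float(x) for x in val)
            return (lo, hi)
    return None


def collapse_low_support(tree: dendropy.Tree, threshold: float = 0.7) -> dendropy.Tree:
    """Contract internal branches whose support is strictly below the
    threshold (a branch at exactly the threshold is retained); node heights
    of surviving nodes are untouched."""
    out = tree.clone(depth=1)
    internal = [
        nd
        for nd in out.preorder_internal_node_iter()
        if nd.parent_node is not None
    ]
    if internal and all(_support(nd) is None for nd in internal):
        raise ValueError("tree carries no support values")
    to_collapse = []
    for nd in internal:
        sup = _support(nd)
        if sup is not None and sup < threshold:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return out


def join_subgenome_leaves(
    mul_tree: dendropy.Tree,
    polyploid_map: dict[str, list[str]],
    maternal: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Fold a MUL-tree into a species network.

    ``polyploid_map`` sends each polyploid to its sub-genome leaf labels;
    these leaves are merged into one network leaf with one incoming edge per
    former leaf position (edges from a single shared parent collapse into
    one edge flagged ``auto=True``).  ``maternal`` optionally names the
    maternal sub-genome; its edge is flagged.
    """
    maternal = maternal or {}
    g = nx.DiGraph()
    node_id: dict = {}
    counter = [0]

    def ident(nd) -> str:
        if nd.is_leaf():
            return nd.taxon.label
        if nd not in node_id:
            counter[0] += 1
            node_id[nd] = f"n{counter[0]}"
        return node_id[nd]

    subgenome_owner = {
        lab: poly for poly, labs in polyploid_map.items() for lab in labs
    }
    leaf_labels = {lf.taxon.label for lf in mul_tree.leaf_node_iter()}
    for poly, labs in polyploid_map.items():
        for lab in labs:
            if lab not in leaf_labels:
                raise ValueError(f"sub-genome leaf {lab!r} missing from MUL-tree")

    for nd in mul_tree.preorder_node_iter():
        name = ident(nd)
        attrs = {}
        hpd = _hpd(nd)
        if hpd is not None:
            attrs["hpd"] = hpd
        if hasattr(nd, "age_ma"):
            attrs["age"] = nd.age_ma
        if nd.is_leaf() and nd.taxon.label in subgenome_owner:
            continue  # handled below
        g.add_node(name, reticulation=False, **attrs)
        if nd.parent_node is not None:
            sup = _support(nd)
            g.add_edge(
                ident(nd.parent_node),
                name,
                length=nd.edge.length,
                support=sup,
                maternal=False,
            )

    for poly, labs in polyploid_map.items():
        parents: dict[str, list[str]] = {}
        for lab in labs:
            leaf = mul_tree.find_node_with_taxon_label(lab)
            parents.setdefault(ident(leaf.parent_node), []).append(lab)
        is_auto = len(parents) == 1 and len(labs) > 1
        g.add_node(
            poly,
            reticulation=len(parents) > 1,
            autopolyploid=is_auto,
            subgenomes=list(labs),
        )
        for parent, labs_here in parents.items():
            g.add_edge(
                parent,
                poly,
                subgenomes=labs_here,
                auto=len(labs_here) > 1,
                maternal=maternal.get(poly) in labs_here,
            )
    return g


def merge_hpd(intervals: list[tuple[float, float]]) -> tuple[float, float]:
    """Covering interval of one or more (lower, upper) HPD intervals."""
    if not intervals:
        raise ValueError("no intervals to merge")
    for lo, hi in intervals:
        if lo > hi:
            raise ValueError(f"interval ({lo}, {hi}) has lower > upper")
    return (min(lo for lo, _ in intervals), max(hi for _, hi in intervals))


def polyploid_age_interval(
    mul_tree: dendropy.Tree, subgenome_leaves: list[str]
) -> tuple[float, float]:
    """Age interval of a polyploid: the covering interval of the 95% HPDs
    of its sub-genomes' divergence (attachment-node) times."""
    intervals = []
    for lab in subgenome_leaves:
        leaf = mul_tree.find_node_with_taxon_label(lab)
        if leaf is None:
            raise ValueError(f"sub-genome leaf {lab!r} missing from MUL-tree")
        parent = leaf.parent_node
        hpd = _hpd(parent)
        if hpd is None:
            if hasattr(parent, "age_ma"):
                hpd = (parent.age_ma, parent.age_ma)
            else:
                raise ValueError(f"no HPD or age on the parent of {lab!r}")
        intervals.append(hpd)
    return merge_hpd(intervals)


# ----------------------------------------------------------------------
# scenario ranking
# ----------------------------------------------------------------------


def rank_scenarios(
    gene_tree_samples: list[GeneTreeSample],
    diploid_map: dict[str, str],
    polyploid_alleles: dict[str, str],
    sample_ploidies: dict[str, int],
    scenarios: dict[str, list[list[str]]],
    iterations: int = 200,
    restarts: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank species-delimitation scenarios by their best assignment score.

    Each scenario is a partition of the polyploid samples into putative
    lineages; samples grouped together share sub-genome bins.  Scenarios
    are ordered by ascending total extra-lineage count (the surrogate for a
    marginal-likelihood comparison); ties share a rank.
    """
    rows = []
    for name, groups in scenarios.items():
        covered = [s for grp in groups for s in grp]
        if len(set(covered)) != len(covered):
            raise ValueError(f"scenario {name!r}: overlapping groups")
        lineages = []
        for grp in groups:
            ploidies = {sample_ploidies[s] for s in grp}
            if len(ploidies) != 1:
                raise ValueError(
                    f"scenario {name!r}: group {grp} mixes ploidy levels"
                )
            lineages.append(
                PolyploidLineage("+".join(sorted(grp)), sorted(grp), ploidies.pop())
            )
        model = SubgenomeModel(
            gene_tree_samples, diploid_map, polyploid_alleles, lineages
        )
        res = model.fit(iterations=iterations, restarts=restarts, seed=seed)
        rows.append(
            {
                "scenario": name,
                "n_lineages": len(groups),
                SCORE_COLUMN: res.score,
                "species_tree": res.species_tree,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        [SCORE_COLUMN, "scenario"], kind="stable"
    )
    df["rank"] = df[SCORE_COLUMN].rank(method="min").astype(int)
    ties = df[SCORE_COLUMN].duplicated(keep=False)
    if ties.any():
        tied = ", ".join(df.loc[ties, "scenario"])
        warnings.warn(f"scenarios tied on the surrogate score: {tied}")
    return df.reset_index(drop=True)


def network_to_edge_table(g: nx.DiGraph) -> pd.DataFrame:
    rows = []
    for u, v, data in g.edges(data=True):
        rows.append(
            {
                "parent": u,
                "child": v,
                "length": data.get("length"),
                "support": data.get("support"),
                "maternal": bool(data.get("maternal", False)),
                "subgenomes": ",".join(data.get("subgenomes", []) or []),
            }
        )
    return pd.DataFrame(rows)
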