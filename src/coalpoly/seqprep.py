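"""Alignment post-processing shared by all loci.

* simple indel coding: one binary character per distinct gap (identical
  start and end across sequences), with gaps strictly contained in a longer
  gap of another sequence scored as missing for that character;
* column masking, e.g. of a microsatellite motif region, with 1-based
  inclusive coordinates;
* a paralog screen on gene trees: well-supported clades on long stems whose
  members span several a-priori taxa are flagged for exclusion, never
  emptying a sample's allele set.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "Alignment",
    "ParalogScreenParams",
    "simple_gap_code",
    "mask_region",
    "flag_paralogs",
    "read_fasta_alignment",
    "write_fasta_alignment",
]

_IUPAC_GAP = set("ACGTUMRWSYKVHDBN-?")


@dataclass
class Alignment:
    sequences: dict[str, str]
    locus_id: str = ""

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment {self.locus_id}: unequal sequence lengths")
        bad = {
            c
            for s in self.sequences.values()
            for c in s.upper()
            if c not in _IUPAC_GAP
        }
        if bad:
            raise ValueError(f"non-IUPAC characters in alignment: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """1-based inclusive (start, end) of each contiguous '-' run."""
    runs, start = [], None
    for i, c in enumerate(seq, start=1):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def simple_gap_code(aln: Alignment) -> pd.DataFrame:
    """Simple indel coding of an alignment's gaps.

    One binary character per distinct (start, end) gap; a sequence scores
    '1' if it has exactly that gap, '?' (missing) if the gap lies strictly
    inside one of its longer gaps, else '0'.  Columns are ordered by gap
    position and named ``indel_<start>_<end>`` (1-based inclusive).
    """
    per_seq = {sid: _gap_runs(s) for sid, s in aln.sequences.items()}
    events = sorted({run for runs in per_seq.values() for run in runs})
    data: dict[str, list[str]] = {}
    for sid, runs in per_seq.items():
        run_set = set(runs)
        row = []
        for a, b in events:
            if (a, b) in run_set:
                row.append("1")
            elif any(c <= a and b <= d and (c, d) != (a, b) for c, d in runs):
                row.append("?")
            else:
                row.append("0")
        data[sid] = row
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[f"indel_{a}_{b}" for a, b in events]
    )


def mask_region(aln: Alignment, start: int, end: int) -> Alignment:
    """Remove columns ``start..end`` (1-based inclusive).

    ``end < start`` is the empty mask and returns the alignment unchanged.
    """
    if end < start:
        return Alignment(dict(aln.sequences), aln.locus_id)
    if start < 1 or end > aln.length:
        raise ValueError(
            f"mask {start}-{end} outside alignment of length {aln.length}"
        )
    if start == 1 and end == aln.length:
        warnings.warn("mask covers the whole alignment; sequences now empty")
    masked = {
        sid: s[: start - 1] + s[end:] for sid, s in aln.sequences.items()
    }
    return Alignment(masked, aln.locus_id)


@dataclass
class ParalogScreenParams:
    support_min: float = 0.95
    stem_factor: float = 3.0
    taxon_map: dict[str, str] = field(default_factory=dict)
    sample_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.support_min <= 1.0:
            raise ValueError("support_min must lie in (0, 1]")
        if self.stem_factor <= 0:
            raise ValueError("stem_factor must be positive")


def _default_sample(seq_id: str) -> str:
    for sep in ("|", "."):
        if sep in seq_id:
            return seq_id.split(sep)[0]
    return seq_id


def _node_support(node) -> float | None:
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            pass
    ann = node.annotations.get_value("posterior")
    if ann is not None:
        return float(ann)
    return None


def flag_paralogs(gene_tree, params: ParalogScreenParams) -> list[str]:
    """Sequence ids forming putative paralog clades.

    A clade is flagged when its support is at least ``support_min``, its
    stem is at least ``stem_factor`` times the median internal branch
    length, its members span two or more a-priori taxa, and dropping it
    leaves every affected sample with at least one sequence at the locus.
    """
    if isinstance(gene_tree, str):
        gene_tree = dendropy.Tree.get(
            data=gene_tree, schema="newick", rooting="force-rooted", preserve_underscores=True
        )
    sample_of = params.sample_map or {
        lf.taxon.label: _default_sample(lf.taxon.label)
        for lf in gene_tree.leaf_node_iter()
    }

    internal = [
        nd
        for nd in gene_tree.preorder_internal_node_iter()
        if nd.parent_node is not None
    ]
    if not internal:
        return []
    supports = [_node_support(nd) for nd in internal]
    if all(s is None for s in supports):
        raise ValueError("gene tree carries no support values")
    lengths = [nd.edge.length for nd in internal if nd.edge.length is not None]
    if not lengths:
        raise ValueError("gene tree carries no internal branch lengths")
    median_len = statistics.median(lengths)

    all_leaves = [lf.taxon.label for lf in gene_tree.leaf_node_iter()]
    per_sample_total: dict[str, int] = {}
    for leaf in all_leaves:
        s = sample_of.get(leaf, _default_sample(leaf))
        per_sample_total[s] = per_sample_total.get(s, 0) + 1

    candidates = []
    for nd, sup in zip(internal, supports):
        if sup is None or sup < params.support_min:
            continue
        stem = nd.edge.length or 0.0
        if stem < params.stem_factor * median_len:
            continue
        members = [lf.taxon.label for lf in nd.leaf_iter()]
        taxa = {
            params.taxon_map.get(m, _default_sample(m)) for m in members
        }
        if len(taxa) < 2:
            continue
        candidates.append((stem, members))

    flagged: set[str] = set()
    remaining = dict(per_sample_total)
    for stem, members in sorted(candidates, key=lambda t: -t[0]):
        new = [m for m in members if m not in flagged]
        hit: dict[str, int] = {}
        for m in new:
            s = sample_of.get(m, _default_sample(m))
            hit[s] = hit.get(s, 0) + 1
        if any(remaining[s] - n < 1 for s, n in hit.items()):
            continue  # would empty a sample's allele set
        for m in new:
            flagged.add(m)
        for s, n in hit.items():
            remaining[s] -= n
    return sorted(flagged)


# ----------------------------------------------------------------------


def read_fasta_alignment(path, locus_id: str = "") -> Alignment:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return Alignment(seqs, locus_id)


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences.items():
            fh.write(f">{sid}\n{seq}\n")
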