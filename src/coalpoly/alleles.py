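"""Ploidy-aware allele calling from amplicon reads.

The pipeline mirrors a two-step amplicon workflow: quality-filter reads,
cluster them into putative allelic variants, keep clusters large enough to
be real alleles given the sample's ploidy, screen for PCR chimeras
(prefix+suffix recombinants of two alleles), and collapse each surviving
cluster into an IUPAC consensus in which intra-allelic polymorphisms above
a frequency threshold are retained as wobble codes.

Also provides two small calculators used when designing such experiments:
the coupon-collector probability that ``n`` picked clones cover all alleles
of a polyploid locus, and ploidy classification from flow-cytometric
fluorescence ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Read",
    "ReadCluster",
    "AlleleSet",
    "QcParams",
    "qc_filter",
    "cluster_reads",
    "min_reads_cutoff",
    "detect_chimeras",
    "consensus_iupac",
    "call_alleles",
    "prob_all_alleles",
    "min_clones_for",
    "classify_ploidy",
    "read_fastq",
    "write_alleles_fasta",
    "read_ploidy_table",
    "DEFAULT_PLOIDY_RANGES",
]

IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Read:
    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class ReadCluster:
    members: list[Read]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AlleleSet:
    """Called (or true) alleles of one sample at one locus."""

    sample_id: str
    locus_id: str
    ploidy: int
    alleles: list[str]
    support: list[int]

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4, 6):
            raise ValueError("ploidy must be 2, 4 or 6")
        if len(self.alleles) != len(self.support):
            raise ValueError("alleles and support differ in length")
        if len(self.alleles) > self.ploidy:
            warnings.warn(
                f"{self.sample_id}/{self.locus_id}: {len(self.alleles)} alleles "
                f"exceed ploidy {self.ploidy} — possible paralogy"
            )

    @property
    def excess_alleles(self) -> bool:
        return len(self.alleles) > self.ploidy


@dataclass
class QcParams:
    phred_min: int = 20
    max_lowq_frac: float = 0.10
    wobble_threshold: float = 0.20
    sanger_minor_peak: float = 0.25
    min_read_factor: float = 0.5
    cluster_link_factor: float = 1.5

    def __post_init__(self) -> None:
        for name in ("max_lowq_frac", "wobble_threshold", "sanger_minor_peak",
                     "min_read_factor"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


# ----------------------------------------------------------------------
# QC and clustering
# ----------------------------------------------------------------------


def qc_filter(reads: list[Read], params: QcParams = QcParams()) -> list[Read]:
    """Drop reads with low-quality bases at more than ``max_lowq_frac`` of
    positions (strictly more than; the boundary fraction is retained)."""
    if not reads:
        warnings.warn("qc_filter: no reads supplied")
        return []
    kept = []
    for r in reads:
        q = np.asarray(r.quals)
        if (q < params.phred_min).mean() <= params.max_lowq_frac:
            kept.append(r)
    return kept


def _seq_matrix(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def _pairwise_distances(reads: list[Read]) -> np.ndarray:
    lengths = {len(r.seq) for r in reads}
    if len(lengths) == 1:
        mat = _seq_matrix([r.seq for r in reads])
        return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    import edlib  # unequal lengths: fall back to edit distance

    n = len(reads)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = edlib.align(reads[i].seq, reads[j].seq)["editDistance"]
    return d


def expected_error_distance(reads: list[Read]) -> float:
    """Expected Hamming distance between two error-bearing copies of one
    allele, from the reads' own Phred scores."""
    per_read = [sum(10 ** (-q / 10) for q in r.quals) for r in reads]
    return 2.0 * float(np.mean(per_read))


def cluster_reads(
    reads: list[Read], params: QcParams = QcParams()
) -> list[ReadCluster]:
    """Partition reads into putative allelic variants.

    Average-linkage agglomerative clustering on pairwise mismatch counts,
    cut at ``cluster_link_factor`` times the Phred-implied within-allele
    error distance.  Clusters are returned largest first.
    """
    if not reads:
        return []
    if len(reads) == 1:
        return [ReadCluster(list(reads))]
    d = _pairwise_distances(reads)
    cut = params.cluster_link_factor * max(expected_error_distance(reads), 1.0)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=cut, criterion="distance")
    clusters: dict[int, list[Read]] = {}
    for lab, read in zip(labels, reads):
        clusters.setdefault(int(lab), []).append(read)
    ordered = sorted(
        clusters.values(), key=lambda ms: (-len(ms), min(r.id for r in ms))
    )
    return [ReadCluster(ms) for ms in ordered]


def min_reads_cutoff(total_reads: int, ploidy: int, params: QcParams = QcParams()) -> int:
    """Minimum cluster size for an allele candidate:
    ``ceil(min_read_factor * total_reads / ploidy)``."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if ploidy not in (2, 4, 6):
        raise ValueError("ploidy must be 2, 4 or 6")
    return math.ceil(params.min_read_factor * total_reads / ploidy)


# ----------------------------------------------------------------------
# chimera detection
# ----------------------------------------------------------------------


def detect_chimeras(reads: list[Read], candidate_alleles: list[str]) -> set[str]:
    """Ids of reads better explained as a prefix+suffix recombinant of two
    different candidate alleles than by any single allele.

    A read is flagged when some breakpoint ``k`` and ordered allele pair
    (a, b), a != b, give ``mismatches(read, a[:k] + b[k:])`` strictly
    smaller than the read's mismatches to every single candidate.
    """
    if len(candidate_alleles) < 2:
        return set()
    amat = _seq_matrix(candidate_alleles)
    n_all, length = amat.shape
    flagged: set[str] = set()
    for read in reads:
        if len(read.seq) != length:
            continue
        r = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        mism = (amat != r[None, :]).astype(np.int32)
        prefix = np.zeros((n_all, length + 1), dtype=np.int32)
        np.cumsum(mism, axis=1, out=prefix[:, 1:])
        totals = prefix[:, -1]
        suffix = totals[:, None] - prefix
        best_single = int(totals.min())

        order_p = np.argsort(prefix, axis=0, kind="stable")
        p1_idx = order_p[0]
        p1 = prefix[p1_idx, np.arange(length + 1)]
        p2 = prefix[order_p[1], np.arange(length + 1)]
        order_s = np.argsort(suffix, axis=0, kind="stable")
        s1_idx = order_s[0]
        s1 = suffix[s1_idx, np.arange(length + 1)]
        s2 = suffix[order_s[1], np.arange(length + 1)]

        same = p1_idx == s1_idx
        combined = np.where(same, np.minimum(p1 + s2, p2 + s1), p1 + s1)
        if int(combined.min()) < best_single:
            flagged.add(read.id)
    return flagged


# ----------------------------------------------------------------------
# consensus
# ----------------------------------------------------------------------


def consensus_iupac(cluster: ReadCluster, params: QcParams = QcParams()) -> str:
    """Column-wise consensus retaining polymorphisms at frequency >=
    ``wobble_threshold`` as IUPAC wobble codes; ties in the majority base
    are coded as the wobble over the tied bases."""
    if cluster.size == 0:
        raise ValueError("cannot take the consensus of an empty cluster")
    lengths = {len(r.seq) for r in cluster.members}
    if len(lengths) != 1:
        raise ValueError("cluster members must be aligned to equal length")
    mat = _seq_matrix([r.seq for r in cluster.members])
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])  # (4, L)
    freqs = counts / np.maximum(counts.sum(axis=0, keepdims=True), 1)
    out = []
    for col in range(mat.shape[1]):
        above = [i for i in range(4) if freqs[i, col] >= params.wobble_threshold]
        if not above:  # only when the threshold exceeds the top frequency
            top = counts[:, col].max()
            above = [i for i in range(4) if counts[i, col] == top]
        out.append(IUPAC[frozenset("ACGT"[i] for i in above)])
    return "".join(out)


# ----------------------------------------------------------------------
# end-to-end calling
# ----------------------------------------------------------------------


def call_alleles(
    reads: list[Read],
    ploidy: int,
    params: QcParams = QcParams(),
    sample_id: str = "",
    locus_id: str = "",
) -> tuple[AlleleSet, dict]:
    """Full calling pipeline for one sample x locus.

    QC -> clustering -> ploidy-aware size cutoff -> chimera screen against
    the provisional alleles -> re-clustering of clean reads -> IUPAC
    consensus.  Returns the AlleleSet and a report dict with discarded and
    flagged read ids.
    """
    report: dict = {"n_input": len(reads)}
    passed = qc_filter(reads, params)
    report["qc_discarded"] = sorted({r.id for r in reads} - {r.id for r in passed})
    if not passed:
        return AlleleSet(sample_id, locus_id, ploidy, [], []), report

    clusters = cluster_reads(passed, params)
    cutoff = min_reads_cutoff(len(passed), ploidy, params)
    report["cutoff"] = cutoff
    candidates = [consensus_iupac(c, params) for c in clusters if c.size >= cutoff]

    flagged = detect_chimeras(passed, candidates)
    report["chimera_flagged"] = sorted(flagged)
    clean = [r for r in passed if r.id not in flagged]

    clusters = cluster_reads(clean, params)
    cutoff = min_reads_cutoff(len(clean), ploidy, params)
    alleles: dict[str, int] = {}
    for c in clusters:
        if c.size < cutoff:
            continue
        cons = consensus_iupac(c, params)
        alleles[cons] = alleles.get(cons, 0) + c.size
    ordered = sorted(alleles.items(), key=lambda kv: (-kv[1], kv[0]))
    aset = AlleleSet(
        sample_id,
        locus_id,
        ploidy,
        [a for a, _ in ordered],
        [s for _, s in ordered],
    )
    return aset, report


# ----------------------------------------------------------------------
# design calculators
# ----------------------------------------------------------------------


def prob_all_alleles(n_clones: int, n_alleles: int) -> float:
    """Probability that ``n_clones`` picked clones contain every one of
    ``n_alleles`` equally frequent alleles (coupon-collector
    inclusion-exclusion)."""
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if n_clones < n_alleles:
        return 0.0
    k = n_alleles
    p = sum(
        (-1) ** i * math.comb(k, i) * ((k - i) / k) ** n_clones for i in range(k + 1)
    )
    return min(max(p, 0.0), 1.0)


def min_clones_for(target: float, n_alleles: int) -> int:
    """Smallest clone number reaching the target coverage probability."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie in (0, 1)")
    n = n_alleles
    while prob_all_alleles(n, n_alleles) < target:
        n += 1
    return n


# Fluorescence-ratio intervals (sample/standard relative DNA content) for
# ploidy classification, bracketing the observed per-taxon means
# (diploids 3.27-3.87, tetraploids 5.76-6.28, hexaploids 7.43-7.86).
DEFAULT_PLOIDY_RANGES: dict[int, tuple[float, float]] = {
    2: (2.9, 4.3),
    4: (5.3, 6.7),
    6: (7.0, 8.3),
}


def classify_ploidy(
    fluorescence_ratio: float,
    reference: dict[int, tuple[float, float]] | None = None,
) -> int:
    """Ploidy whose reference fluorescence-ratio interval contains the
    measurement; out-of-range ratios are assigned to the nearest interval
    with a warning."""
    ref = DEFAULT_PLOIDY_RANGES if reference is None else reference
    intervals = sorted(ref.items(), key=lambda kv: kv[1][0])
    for (p1, (lo1, hi1)), (p2, (lo2, hi2)) in zip(intervals, intervals[1:]):
        if hi1 > lo2:
            raise ValueError(f"reference ranges for {p1}x and {p2}x overlap")
    for p, (lo, hi) in intervals:
        if lo <= fluorescence_ratio <= hi:
            return p

    def dist(item):
        _, (lo, hi) = item
        return min(abs(fluorescence_ratio - lo), abs(fluorescence_ratio - hi))

    nearest = min(intervals, key=dist)[0]
    warnings.warn(
        f"fluorescence ratio {fluorescence_ratio} outside all reference ranges; "
        f"assigned to nearest ({nearest}x)"
    )
    return nearest


# ----------------------------------------------------------------------
# IO helpers
# ----------------------------------------------------------------------


def read_fastq(path) -> list[Read]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            Read(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
        )
    return out


def write_alleles_fasta(allele_sets: list[AlleleSet], path) -> None:
    with open(path, "w") as fh:
        for aset in allele_sets:
            for k, (seq, sup) in enumerate(zip(aset.alleles, aset.support), start=1):
                fh.write(
                    f">{aset.sample_id}|{aset.locus_id}|allele_{k}|reads={sup}\n{seq}\n"
                )


def read_ploidy_table(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    return dict(
        zip(df[cols.get("sample", df.columns[0])], df[cols.get("ploidy", df.columns[1])])
    )
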