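"""Allele calling: QC, clustering, chimera screen, consensus, calculators."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalpoly.alleles import (
    AlleleSet,
    QcParams,
    Read,
    ReadCluster,
    call_alleles,
    classify_ploidy,
    cluster_reads,
    consensus_iupac,
    detect_chimeras,
    min_clones_for,
    min_reads_cutoff,
    prob_all_alleles,
    qc_filter,
)
from coalpoly.simulate import SimulationConfig, random_allele_set, simulate_reads


def _read(seq, q=40, rid="r"):
    return Read(rid, seq, [q] * len(seq))


class TestQcFilter:
    def _mixed_read(self, n_low, rid="r", length=100):
        quals = [35] * (length - n_low) + [10] * n_low
        return Read(rid, "A" * length, quals)

    def test_eleven_percent_low_quality_discarded(self):
        assert qc_filter([self._mixed_read(11)]) == []

    def test_ten_percent_boundary_retained(self):
        reads = [self._mixed_read(10)]
        assert qc_filter(reads) == reads

    def test_clean_reads_all_retained(self):
        reads = [_read("ACGT" * 25, rid=f"r{i}") for i in range(5)]
        assert qc_filter(reads) == reads

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            assert qc_filter([]) == []

    @given(st.integers(min_value=0, max_value=50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rule_is_exactly_the_fraction_threshold(self, n_low):
        read = self._mixed_read(n_low)
        kept = qc_filter([read])
        assert bool(kept) == (n_low / 100 <= 0.10)


class TestClustering:
    def test_single_allele_error_free_reads_form_one_cluster(self, rng):
        aset = random_allele_set("S", "L", 2, rng)
        reads = [_read(aset.alleles[0], rid=f"r{i}") for i in range(20)]
        clusters = cluster_reads(reads)
        assert len(clusters) == 1 and clusters[0].size == 20

    def test_divergent_singleton_gets_its_own_cluster(self, rng):
        aset = random_allele_set("S", "L", 2, rng)
        reads = [_read(aset.alleles[0], rid=f"r{i}") for i in range(10)]
        junk = _read("".join(rng.choice(list("ACGT"), 300)), rid="junk")
        clusters = cluster_reads(reads + [junk])
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 10]

    def test_two_alleles_recovered_from_noisy_reads(self, rng):
        aset = random_allele_set("S", "L", 2, rng, divergence=0.05)
        cfg = SimulationConfig(read_depth=200, error_rate=0.01, chimera_rate=0.0,
                               lowq_read_frac=0.0)
        reads = simulate_reads(aset, cfg, rng)
        clusters = cluster_reads(reads)
        majors = [c for c in clusters if c.size >= 50]
        assert len(majors) == 2
        consensi = {consensus_iupac(c) for c in majors}
        assert consensi == set(aset.alleles)

    def test_partition_is_exact(self, rng):
        aset = random_allele_set("S", "L", 4, rng)
        cfg = SimulationConfig(read_depth=100, error_rate=0.01, lowq_read_frac=0.0)
        reads = simulate_reads(aset, cfg, rng)
        clusters = cluster_reads(reads)
        ids = [r.id for c in clusters for r in c.members]
        assert sorted(ids) == sorted(r.id for r in reads)


class TestCutoff:
    @pytest.mark.parametrize(
        "total,ploidy,factor,expected",
        [(600, 6, 0.5, 50), (600, 2, 0.5, 150), (600, 4, 0.99, 149)],
    )
    def test_stated_rule(self, total, ploidy, factor, expected):
        p = QcParams(min_read_factor=factor)
        assert min_reads_cutoff(total, ploidy, p) == expected

    def test_bad_ploidy(self):
        with pytest.raises(ValueError):
            min_reads_cutoff(100, 3)


class TestChimeras:
    def test_exact_recombinant_is_flagged(self, rng):
        aset = random_allele_set("S", "L", 2, rng)
        a, b = aset.alleles
        chimera = a[:150] + b[150:]
        flagged = detect_chimeras([_read(chimera, rid="c")], [a, b])
        assert flagged == {"c"}

    def test_read_with_one_error_is_not_flagged(self, rng):
        aset = random_allele_set("S", "L", 2, rng)
        a = list(aset.alleles[0])
        a[10] = "A" if a[10] != "A" else "C"
        flagged = detect_chimeras([_read("".join(a), rid="e")], list(aset.alleles))
        assert flagged == set()

    def test_fewer_than_two_candidates_is_a_noop(self, rng):
        aset = random_allele_set("S", "L", 2, rng)
        assert detect_chimeras([_read(aset.alleles[0])], [aset.alleles[0]]) == set()


class TestConsensus:
    def _cluster(self, cols):
        # cols: list of per-position base strings, one char per read
        n = len(cols[0])
        seqs = ["".join(col[i] for col in cols) for i in range(n)]
        return ReadCluster([_read(s, rid=f"r{i}") for i, s in enumerate(seqs)])

    def test_twenty_percent_minor_becomes_wobble(self):
        c = self._cluster(["A" * 8 + "C" * 2])
        assert consensus_iupac(c) == "M"

    def test_below_threshold_minor_dropped(self):
        c = self._cluster(["A" * 81 + "C" * 19])
        assert consensus_iupac(c) == "A"

    def test_identical_reads_roundtrip(self):
        c = ReadCluster([_read("ACGTACGT", rid=f"r{i}") for i in range(4)])
        assert consensus_iupac(c) == "ACGTACGT"

    def test_majority_tie_coded_as_wobble(self):
        params = QcParams(wobble_threshold=0.6)  # both 50% bases below 0.6
        c = self._cluster(["A" * 5 + "G" * 5])
        assert consensus_iupac(c, params) == "R"

    def test_empty_cluster_is_an_error(self):
        with pytest.raises(ValueError):
            consensus_iupac(ReadCluster([]))


class TestCloneProbability:
    def test_twenty_seven_clones_cover_six_alleles(self):
        assert prob_all_alleles(27, 6) >= 0.95
        assert prob_all_alleles(26, 6) < 0.95

    def test_two_clones_two_alleles_by_enumeration(self):
        # 4 equiprobable outcomes; 2 contain both alleles
        assert prob_all_alleles(2, 2) == pytest.approx(0.5)

    def test_fewer_clones_than_alleles_is_impossible(self):
        assert prob_all_alleles(5, 6) == 0.0

    def test_single_allele_is_certain(self):
        assert prob_all_alleles(1, 1) == 1.0

    @given(st.integers(min_value=2, max_value=6))
    @settings(max_examples=5, deadline=None, derandomize=True)
    def test_nondecreasing_in_clones_and_limits_to_one(self, k):
        probs = [prob_all_alleles(n, k) for n in range(k, 120)]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 0.999

    def test_min_clones_matches_direct_search(self):
        n = min_clones_for(0.95, 6)
        assert prob_all_alleles(n, 6) >= 0.95 > prob_all_alleles(n - 1, 6)
        assert n == 27  # the design value for a hexaploid locus


class TestPloidyClassification:
    @pytest.mark.parametrize(
        "ratio,expected", [(3.278, 2), (5.804, 4), (7.431, 6), (7.861, 6)]
    )
    def test_reference_ratios(self, ratio, expected):
        assert classify_ploidy(ratio) == expected

    def test_out_of_range_goes_to_nearest_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_ploidy(4.8) in (2, 4)

    def test_overlapping_reference_is_an_error(self):
        with pytest.raises(ValueError):
            classify_ploidy(3.0, {2: (2.0, 4.0), 4: (3.5, 6.0)})


class TestEndToEnd:
    def test_clean_depth300_recovers_truth(self, rng):
        cfg = SimulationConfig(read_depth=300, error_rate=0.01, chimera_rate=0.0)
        hits = 0
        for ploidy in (2, 4, 6):
            aset = random_allele_set(f"S{ploidy}", "L1", ploidy, rng)
            reads = simulate_reads(aset, cfg, rng)
            called, _ = call_alleles(reads, ploidy)
            hits += set(called.alleles) == set(aset.alleles)
        assert hits == 3

    def test_excess_alleles_raise_warning_flag(self):
        with pytest.warns(UserWarning):
            aset = AlleleSet("s", "l", 2, ["AA", "AC", "AG"], [5, 4, 3])
        assert aset.excess_alleles
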