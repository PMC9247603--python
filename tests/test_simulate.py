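"""Planted-history simulator: structure, reproducibility and calibration."""

import math

import numpy as np
import pytest

from coalpoly.mdc import count_extra_lineages
from coalpoly.simulate import (
    PolyploidEvent,
    SimulationConfig,
    random_allele_set,
    simulate_alleles,
    simulate_gene_trees,
    simulate_history,
    simulate_reads,
    _encoded_to_newick,
)

from .conftest import FOUR_DIPLOID_NEWICK, make_history


class TestConfigValidation:
    def test_chimera_rate_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(chimera_rate=1.0)

    def test_origin_must_predate_crown(self):
        ev = PolyploidEvent("allo", "T1", ("D1", "D2"), origin_ma=5.0)
        with pytest.raises(ValueError):
            SimulationConfig(polyploid_events=[ev], crown_age_ma=4.39)

    def test_allo_parents_distinct(self):
        with pytest.raises(ValueError):
            PolyploidEvent("allo", "T1", ("D1", "D1"), origin_ma=1.0)

    def test_auto_takes_single_parent(self):
        with pytest.raises(ValueError):
            PolyploidEvent("auto", "A1", ("D1", "D2"), origin_ma=1.0)


class TestHistory:
    def test_no_events_gives_plain_species_tree(self):
        cfg = SimulationConfig(n_diploid_lineages=4, rng_seed=1)
        h = simulate_history(cfg)
        leaves = {lf.taxon.label for lf in h.mul_tree.leaf_node_iter()}
        assert leaves == {"D1", "D2", "D3", "D4"}
        # network equals the tree: no reticulation anywhere
        assert all(
            not d.get("reticulation") for _, d in h.network.nodes(data=True)
        )

    def test_auto_event_makes_a_subgenome_cherry(self):
        h, _ = make_history("auto4", seed=1)
        mrca = h.mul_tree.mrca(taxon_labels=["A1_sg1", "A1_sg2"])
        assert len(mrca.leaf_nodes()) == 2

    def test_default_crown_age_is_root_height(self):
        cfg = SimulationConfig(n_diploid_lineages=4, rng_seed=3)
        h = simulate_history(cfg)
        assert h.mul_tree.seed_node.age_ma == pytest.approx(4.39)

    def test_mul_leaf_count_is_sum_of_half_ploidies(self):
        h, _ = make_history("allo6", seed=2)
        n_leaves = len(h.mul_tree.leaf_nodes())
        assert n_leaves == 4 + 3  # four diploids + three hexaploid sub-genomes

    def test_truth_assignment_partitions_all_alleles(self):
        h, _ = make_history("allo4", seed=2)
        slots = [s for s in h.truth_assignment if s.startswith("T1:")]
        assert len(slots) == 4
        bins = {h.truth_assignment[s] for s in slots}
        assert bins == {"T1_sg1", "T1_sg2"}

    def test_extinct_parent_rejected(self):
        # D1 merges with D2 at 2.4 Ma; an origin above that has no D1 branch
        ev = PolyploidEvent("allo", "T1", ("D1", "D3"), origin_ma=3.0)
        cfg = SimulationConfig(
            species_tree_newick=FOUR_DIPLOID_NEWICK,
            polyploid_events=[ev],
        )
        with pytest.raises(ValueError, match="not extant"):
            simulate_history(cfg)

    def test_seeded_runs_are_bit_reproducible(self):
        h1, c1 = make_history("allo4", seed=9, n_trees_per_locus=5)
        h2, c2 = make_history("allo4", seed=9, n_trees_per_locus=5)
        g1 = simulate_gene_trees(h1)
        g2 = simulate_gene_trees(h2)
        for a, b in zip(g1, g2):
            assert np.array_equal(a.encoded.clades, b.encoded.clades)


class TestGeneTrees:
    def test_no_ils_limit_gives_concordant_trees(self):
        # huge population-size separation: origin/splits many coalescent
        # units deep -> every gene tree concordant with the species tree
        cfg = SimulationConfig(
            species_tree_newick="((D1:2.0,D2:2.0):2.39,D3:4.39):0.0;",
            pop_size=100.0,  # 2N gens = 600 y -> branches thousands of units
            n_nuclear_loci=3,
            n_trees_per_locus=20,
            rng_seed=4,
        )
        h = simulate_history(cfg)
        mapping = {}
        for g in simulate_gene_trees(h):
            if g.locus_id == "plastid":
                continue
            for ti in range(g.n_trees):
                nwk = _encoded_to_newick(g.encoded, ti)
                m = {a: a.split(".")[0] for a in g.alleles}
                assert (
                    count_extra_lineages(
                        nwk, "((D1,D2),D3);", m
                    )
                    == 0
                )

    def test_three_taxon_concordance_matches_closed_form(self):
        # internal branch of T coalescent units: P(concordant) = 1-(2/3)e^-T
        T = 1.0
        cu_ma = 2 * 5e4 * 3 / 1e6  # one coalescent unit in Ma
        t1, t2 = 1.0, 1.0 + T * cu_ma
        cfg = SimulationConfig(
            species_tree_newick=f"((D1:{t1},D2:{t1}):{t2 - t1},D3:{t2}):0.0;",
            n_nuclear_loci=1,
            n_trees_per_locus=3000,
            rng_seed=11,
        )
        h = simulate_history(cfg)
        g = [s for s in simulate_gene_trees(h) if s.locus_id == "L1"][0]
        enc = g.encoded
        # single lineage per species for a clean triplet: subsample leaf 0
        b = {d: enc.taxon_bit(f"{d}.L1.a0") for d in ("D1", "D2", "D3")}
        conc = 0
        for ti in range(enc.n_trees):
            lo, hi = enc.offsets[ti], enc.offsets[ti + 1]
            cl = enc.clades[lo:hi]
            hit = ((cl & b["D1"]) != 0) & ((cl & b["D2"]) != 0) & ((cl & b["D3"]) == 0)
            conc += bool(hit.any())
        p_hat = conc / enc.n_trees
        p_exp = 1 - (2 / 3) * math.exp(-T)
        assert p_hat == pytest.approx(p_exp, abs=0.03)  # ~3 MC standard errors

    def test_plastid_follows_maternal_parent(self):
        # deep parent divergence, maternal = D1: the plastid allele of T1
        # must coalesce with D1's plastid lineage before any other
        cfg = SimulationConfig(
            species_tree_newick="((D1:3.0,D2:3.0):1.39,D3:4.39):0.0;",
            polyploid_events=[
                PolyploidEvent("allo", "T1", ("D1", "D2"), origin_ma=0.3)
            ],
            pop_size=2000.0,  # minimal ILS
            n_nuclear_loci=1,
            n_trees_per_locus=50,
            rng_seed=6,
        )
        h = simulate_history(cfg)
        g = [s for s in simulate_gene_trees(h) if s.locus_id == "plastid"][0]
        enc = g.encoded
        bt = enc.taxon_bit("T1.plastid.a0")
        b1 = enc.taxon_bit("D1.plastid.a0")
        b2 = enc.taxon_bit("D2.plastid.a0")
        with_maternal = 0
        for ti in range(enc.n_trees):
            lo, hi = enc.offsets[ti], enc.offsets[ti + 1]
            cl = enc.clades[lo:hi]
            hit = ((cl & bt) != 0) & ((cl & b1) != 0) & ((cl & b2) == 0)
            with_maternal += bool(hit.any())
        assert with_maternal / enc.n_trees >= 0.9


class TestReadsAndAlleles:
    def test_error_free_reads_equal_alleles(self, rng):
        aset = random_allele_set("S1", "L1", 2, rng)
        cfg = SimulationConfig(read_depth=50, error_rate=0.0, chimera_rate=0.0,
                               lowq_read_frac=0.0)
        reads = simulate_reads(aset, cfg, rng)
        assert all(r.seq in aset.alleles for r in reads)

    def test_depth_split_is_binomial(self, rng):
        aset = random_allele_set("S1", "L1", 2, rng)
        cfg = SimulationConfig(read_depth=600, error_rate=0.0, chimera_rate=0.0,
                               lowq_read_frac=0.0)
        reads = simulate_reads(aset, cfg, rng)
        n0 = sum(r.id.endswith("allele=0") for r in reads)
        # 4-sigma band around Binomial(600, 1/2)
        assert abs(n0 - 300) < 4 * math.sqrt(600 * 0.25)

    def test_chimera_fraction_by_construction(self, rng):
        aset = random_allele_set("S1", "L1", 4, rng)
        cfg = SimulationConfig(read_depth=1000, error_rate=0.0, chimera_rate=0.1,
                               lowq_read_frac=0.0)
        reads = simulate_reads(aset, cfg, rng)
        frac = sum("chimera=" in r.id for r in reads) / len(reads)
        assert frac == pytest.approx(0.1, abs=0.04)

    def test_quality_strings_are_calibrated(self, rng):
        aset = random_allele_set("S1", "L1", 2, rng)
        cfg = SimulationConfig(read_depth=200, error_rate=0.01, chimera_rate=0.0,
                               lowq_read_frac=0.0)
        reads = simulate_reads(aset, cfg, rng)
        implied = np.mean(
            [np.mean([10 ** (-q / 10) for q in r.quals]) for r in reads]
        )
        assert implied == pytest.approx(0.01, rel=0.3)

    def test_divergence_controlled_alleles(self, rng):
        aset = random_allele_set("S1", "L1", 6, rng, length=300, divergence=0.08)
        for i in range(6):
            for j in range(i + 1, 6):
                d = sum(
                    a != b for a, b in zip(aset.alleles[i], aset.alleles[j])
                )
                assert d == round(0.08 * 300)

    def test_simulated_alleles_cover_every_sample_locus(self):
        h, cfg = make_history("allo4", seed=21, n_nuclear_loci=2)
        table = simulate_alleles(h)
        samples = {"D1", "D2", "D3", "D4", "T1"}
        assert {k[0] for k in table} == samples
        for (sample, locus), aset in table.items():
            assert sum(aset.support) == (4 if sample == "T1" else 2)
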