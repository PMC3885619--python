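import json

import numpy as np
import pytest
from scipy import stats

from coevokit import caps
from coevokit.distances import p_distance
from coevokit.io import read_alignment, read_clades, read_pairing, read_tree
from coevokit.mirrortree import tol_mirrortree
from coevokit.synthetic import (
    SimConfig,
    simulate_bundle,
    simulate_families,
    simulate_neutral_codon_pairs,
    simulate_tree,
    write_fixture_bundle,
)


class TestSimulateTree:
    def test_topology_counts(self):
        tree = simulate_tree(4, seed=0)
        assert len(tree.leaf_nodes()) == 4
        assert len(tree.internal_nodes()) == 3  # rooted binary

    def test_deterministic_under_seed(self):
        t1 = simulate_tree(10, seed=5).as_string(schema="newick")
        t2 = simulate_tree(10, seed=5).as_string(schema="newick")
        assert t1 == t2
        t3 = simulate_tree(10, seed=6).as_string(schema="newick")
        assert t1 != t3

    def test_branch_lengths_positive_tips_unique(self):
        tree = simulate_tree(50, seed=1)
        total = sum(e.length for e in tree.preorder_edge_iter() if e.length)
        assert total > 0
        labels = [l.taxon.label for l in tree.leaf_nodes()]
        assert len(set(labels)) == 50

    def test_depth_scaling(self):
        tree = simulate_tree(12, seed=2, depth=1.0)
        depths = [l.distance_from_root() for l in tree.leaf_nodes()]
        assert max(depths) == pytest.approx(1.0)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(2, seed=0)


class TestSimulateFamilies:
    def test_bundle_structure(self, coevolving_bundle):
        b = coevolving_bundle
        assert b.fam_a.n_cols == b.config.len_a
        assert b.marker.n_cols == b.config.marker_length
        orgs = {r.organism_id for r in b.fam_a.records}
        assert len(orgs) == b.config.n_organisms
        # duplicated organism contributes 2x2 pairing rows
        dup_rows = [r for r in b.pairing.rows if r.organism_id == "org03"]
        assert len(dup_rows) == 4

    def test_determinism(self):
        cfg = dict(n_organisms=8, coupled_pairs=[(3, 4)], compensation_prob=1.0,
                   marker_length=100, seed=42)
        b1 = simulate_bundle(SimConfig(**cfg))
        b2 = simulate_bundle(SimConfig(**cfg))
        assert [r.residues for r in b1.fam_a.records] == [r.residues for r in b2.fam_a.records]
        assert [r.residues for r in b1.marker.records] == [r.residues for r in b2.marker.records]

    def test_truth_lists_configured_pairs(self, coevolving_bundle):
        b = coevolving_bundle
        assert b.truth.coupled_pairs == b.config.coupled_pairs
        assert set(b.truth.duplications) == set(b.config.duplications)
        n_edges = sum(1 for n in b.tree.preorder_node_iter() if n.parent_node)
        assert len(b.truth.branch_multipliers) == n_edges

    def test_clades_form_balanced_bipartition(self, coevolving_bundle):
        b = coevolving_bundle
        assert set(b.clades.values()) == {"cladeL", "cladeR"}
        assert set(b.clades) == {r.organism_id for r in b.marker.records}
        sizes = [list(b.clades.values()).count(c) for c in ("cladeL", "cladeR")]
        assert min(sizes) >= 2  # both clades usable for clade contrasts

    def test_coupled_site_out_of_range(self):
        with pytest.raises(ValueError):
            SimConfig(len_a=10, coupled_pairs=[(11, 1)])

    def test_marker_distance_tracks_tree_distance(self):
        # clock-like marker: p-distance vs true patristic distance, rank corr
        rhos = []
        for seed in range(5):
            cfg = SimConfig(n_organisms=30, marker_length=1500, marker_rate=0.5,
                            seed=seed)
            b = simulate_bundle(cfg)
            pdm = p_distance(b.marker)
            pdc = b.tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in b.tree.taxon_namespace}
            mk, tr = [], []
            ids = pdm.ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    mk.append(pdm.values[i, j])
                    tr.append(pdc.patristic_distance(taxa[ids[i]], taxa[ids[j]]))
            rhos.append(stats.spearmanr(mk, tr).statistic)
        assert np.mean(rhos) > 0.9

    def test_uncoupled_uncorrelated_families_show_no_coevolution(self):
        # compensation 0 and rate correlation 0: corrected R centered on 0
        rs = []
        for seed in range(30):
            cfg = SimConfig(n_organisms=15, rate_correlation=0.0,
                            compensation_prob=0.0, marker_length=400, seed=seed)
            b = simulate_bundle(cfg)
            res = tol_mirrortree(b.fam_a, b.fam_b, b.pairing, marker=b.marker,
                                 n_perm=99, seed=seed)
            rs.append(res.corrected.r)
        assert abs(np.mean(rs)) < 0.1

    def test_recovery_monotone_in_compensation_probability(self):
        # mean planted-pair recovery never decreases as compensation rises
        planted = [(10, 15), (40, 50), (70, 80)]
        def recovery(comp):
            hit = 0
            tot = 0
            for seed in range(8):
                cfg = SimConfig(n_organisms=20, len_a=100, len_b=100,
                                coupled_pairs=planted, compensation_prob=comp,
                                marker_length=200, seed=seed)
                b = simulate_bundle(cfg)
                mat = caps.load_substitution_matrix("BLOSUM62")
                pa = caps.site_profiles(b.fam_a, caps.matched_sequence_pairs(b.pairing, "A"), mat)
                pb = caps.site_profiles(b.fam_b, caps.matched_sequence_pairs(b.pairing, "B"), mat)
                pairs = caps.intermolecular_correlations(pa, pb)
                if not pairs:
                    continue
                sig = caps.significance_filter(pairs, pa, pb, alpha=0.05,
                                               n_resample=500, seed=seed + 99)
                sigset = {(p.site_a, p.site_b) for p in sig}
                hit += len(sigset & set(planted))
                tot += len(planted)
            return hit / tot
        r0, r5, r1 = recovery(0.0), recovery(0.5), recovery(1.0)
        assert r0 <= r5 + 1e-9 <= r1 + 2e-9

    def test_neutral_codon_pairs_are_codon_clean(self):
        pairs = simulate_neutral_codon_pairs(3, 50, seed=1)
        from coevokit.io import STOP_CODONS
        for a, b in pairs:
            assert len(a) == len(b) == 150
            for seq in (a, b):
                codons = [seq[i:i + 3] for i in range(0, 150, 3)]
                assert not any(c in STOP_CODONS for c in codons)

    def test_neutral_pairs_deterministic(self):
        p1 = simulate_neutral_codon_pairs(2, 30, seed=7)
        p2 = simulate_neutral_codon_pairs(2, 30, seed=7)
        assert p1 == p2


class TestFixtureBundle:
    def test_round_trip_and_determinism(self, tmp_path):
        cfg = SimConfig(n_organisms=6, coupled_pairs=[(2, 3)], compensation_prob=1.0,
                        marker_length=60, duplications=[("org2", "B")], seed=9)
        b = simulate_bundle(cfg)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        paths = write_fixture_bundle(b, d1)
        write_fixture_bundle(simulate_bundle(cfg), d2)
        for name in ("famA.fasta", "tree.nwk", "pairing.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        fam = read_alignment(paths["fam_a"], paths["organisms_a"])
        assert [r.residues for r in fam.records] == [r.residues for r in b.fam_a.records]
        tree = read_tree(paths["tree"])
        assert len(tree.leaf_nodes()) == 6
        pairing = read_pairing(paths["pairing"])
        pairing.validate(fam, read_alignment(paths["fam_b"], paths["organisms_b"]))
        truth = json.loads((d1 / "truth.json").read_text())
        assert truth["coupled_pairs"] == [[2, 3]]
        clades = read_clades(paths["clades"])
        assert set(clades) == {r.organism_id for r in b.marker.records}
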