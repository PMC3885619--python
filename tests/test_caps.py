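import itertools

import numpy as np
import pytest

from coevokit import caps
from coevokit.caps import (
    CorrelatedPair,
    SiteProfileSet,
    build_groups,
    intermolecular_correlations,
    load_substitution_matrix,
    matched_sequence_pairs,
    region_overlap_counts,
    residue_region_report,
    significance_filter,
    site_profiles,
)
from coevokit.distances import poisson_correct
from coevokit.io import PairingRow, PairingTable, Region, RegionSet

from conftest import make_family


def _profiles(name, theta, n_sites=None):
    theta = np.asarray(theta, float)
    cols = list(range(1, theta.shape[0] + 1))
    pairs = [(f"s{i}", f"t{i}") for i in range(theta.shape[1])]
    return SiteProfileSet(name, cols, pairs, theta)


class TestSiteProfiles:
    def test_constant_columns_excluded(self):
        fam = make_family("f", {"a": "AAK", "b": "AAR", "c": "AAK", "d": "AAR"})
        prof = site_profiles(fam, [("a", "b"), ("a", "c"), ("b", "d")])
        assert prof.columns == [3]  # columns 1-2 are constant

    def test_two_sequences_single_pair(self):
        fam = make_family("f", {"a": "AK", "b": "AR"})
        prof = site_profiles(fam, [("a", "b")])
        assert prof.theta.shape == (1, 1)

    def test_hand_computed_theta(self):
        # 4 sequences differing only at the profiled column: "A A S S".
        # A second variable column makes distances equal across all pairs.
        fam = make_family(
            "f",
            {"s1": "ACD" + "A", "s2": "ACE" + "A", "s3": "ACD" + "S", "s4": "ACE" + "S"},
        )
        mat = load_substitution_matrix("BLOSUM62")
        pairs = list(itertools.combinations(["s1", "s2", "s3", "s4"], 2))
        prof = site_profiles(fam, pairs, mat)
        assert 4 in prof.columns
        k = prof.columns.index(4)
        # p-distances: s1-s2 share col4 -> p=1/4; others computed the same way
        expected = {}
        seqs = {"s1": "ACDA", "s2": "ACEA", "s3": "ACDS", "s4": "ACES"}
        for i, (a, b) in enumerate(pairs):
            p = np.mean([x != y for x, y in zip(seqs[a], seqs[b])])
            t = poisson_correct(p)
            expected[i] = mat[seqs[a][3], seqs[b][3]] / t
        for i, val in expected.items():
            assert prof.theta[k, i] == pytest.approx(val)

    def test_gapped_entries_are_nan(self):
        fam = make_family("f", {"a": "AK-D", "b": "ARKD", "c": "AKRE"})
        prof = site_profiles(fam, [("a", "b"), ("a", "c"), ("b", "c")])
        k = prof.columns.index(3)
        assert np.isnan(prof.theta[k, 0])  # a-b at gapped column


class TestCorrelations:
    def test_identical_profiles_give_rho_one(self):
        rng = np.random.default_rng(0)
        theta = rng.random((4, 8))
        pa = _profiles("A", theta)
        pb = _profiles("B", theta.copy())
        pairs = intermolecular_correlations(pa, pb)
        diag = {(p.site_a, p.site_b): p.rho for p in pairs}
        for k in range(1, 5):
            assert diag[(k, k)] == pytest.approx(1.0)

    def test_negated_profiles_give_rho_minus_one(self):
        rng = np.random.default_rng(1)
        theta = rng.random((4, 8))
        pairs = intermolecular_correlations(_profiles("A", theta), _profiles("B", -theta))
        diag = {(p.site_a, p.site_b): p.rho for p in pairs}
        for k in range(1, 5):
            assert diag[(k, k)] == pytest.approx(-1.0)

    def test_symmetric_under_family_swap(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.random((3, 10)), rng.random((5, 10))
        r_ab = {(p.site_a, p.site_b): p.rho
                for p in intermolecular_correlations(_profiles("A", ta), _profiles("B", tb))}
        r_ba = {(p.site_b, p.site_a): p.rho
                for p in intermolecular_correlations(_profiles("B", tb), _profiles("A", ta))}
        for k, v in r_ab.items():
            assert r_ba[k] == pytest.approx(v)

    def test_too_few_shared_entries_skipped(self):
        ta = np.array([[1.0, 2.0, np.nan, np.nan, np.nan]])
        tb = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        assert intermolecular_correlations(_profiles("A", ta), _profiles("B", tb)) == []

    def test_mismatched_pair_index_rejected(self):
        pa = _profiles("A", np.ones((2, 5)))
        pb = SiteProfileSet("B", [1], [("x", "y")], np.ones((1, 1)))
        with pytest.raises(ValueError):
            intermolecular_correlations(pa, pb)


class TestSignificance:
    def test_small_resample_refused(self):
        pa = _profiles("A", np.random.default_rng(0).random((4, 10)))
        with pytest.raises(ValueError, match="n_resample"):
            significance_filter([CorrelatedPair(1, 1, 0.5)], pa, pa, n_resample=50)

    def test_perfect_pair_retained_among_noise(self):
        rng = np.random.default_rng(3)
        ta = rng.random((20, 30))
        tb = rng.random((20, 30))
        tb[0] = ta[0] + rng.normal(0, 1e-6, 30)  # plant a perfect correlation
        pa, pb = _profiles("A", ta), _profiles("B", tb)
        pairs = intermolecular_correlations(pa, pb)
        sig = significance_filter(pairs, pa, pb, alpha=0.05, n_resample=500, seed=0)
        assert (1, 1) in {(p.site_a, p.site_b) for p in sig}

    def test_calibrated_on_random_profiles(self):
        rng = np.random.default_rng(4)
        pa = _profiles("A", rng.random((30, 40)))
        pb = _profiles("B", rng.random((30, 40)))
        pairs = intermolecular_correlations(pa, pb)
        sig = significance_filter(pairs, pa, pb, alpha=0.05, n_resample=2000, seed=1)
        frac = len(sig) / len(pairs)
        assert frac == pytest.approx(0.05, abs=0.03)


class TestGroups:
    def test_connected_components(self):
        pairs = [CorrelatedPair(1, 1, 0.9), CorrelatedPair(1, 2, 0.8),
                 CorrelatedPair(3, 7, 0.7)]
        groups = build_groups(pairs)
        assert len(groups) == 2
        assert groups[0].members_a == [1] and groups[0].members_b == [1, 2]
        assert groups[1].members_a == [3] and groups[1].members_b == [7]

    def test_cross_family_chain_merges(self):
        pairs = [CorrelatedPair(1, 1, 0.9), CorrelatedPair(2, 1, 0.8)]
        groups = build_groups(pairs)
        assert len(groups) == 1
        assert groups[0].members_a == [1, 2] and groups[0].members_b == [1]

    def test_empty_input_gives_no_groups(self):
        assert build_groups([]) == []

    def test_groups_partition_significant_pairs(self):
        rng = np.random.default_rng(5)
        pairs = [CorrelatedPair(int(a), int(b), 0.5)
                 for a, b in rng.integers(1, 15, size=(30, 2))]
        # dedupe
        seen = {}
        for p in pairs:
            seen[(p.site_a, p.site_b)] = p
        pairs = list(seen.values())
        groups = build_groups(pairs)
        assigned = [p for g in groups for p in g.pairs]
        assert len(assigned) == len(pairs)
        ids = {g.group_id for g in groups}
        assert ids == {f"G{k}" for k in range(1, len(groups) + 1)}

    def test_mean_dc_is_mean_site_variance(self):
        rng = np.random.default_rng(6)
        ta, tb = rng.random((3, 12)), rng.random((3, 12))
        pa, pb = _profiles("A", ta), _profiles("B", tb)
        groups = build_groups([CorrelatedPair(1, 2, 0.9)], pa, pb)
        expected = np.mean([ta[0].var(), tb[1].var()])
        assert groups[0].mean_dc == pytest.approx(expected)


class TestRegionReport:
    def test_counts_and_percentages(self):
        n_in, n, pct = region_overlap_counts([5, 20, 200], Region("core", "r", 16, 158))
        assert (n_in, n, pct) == (1, 3, 33.3)

    def test_zero_in_region(self):
        assert region_overlap_counts([1, 2], Region("core", "r", 16, 158))[2] == 0.0

    def test_full_report_on_toy_families(self):
        fam_a = make_family("A", {"refA": "MKVLDE", "a2": "MKVIDE"})
        fam_b = make_family("B", {"refB": "GHWSTY", "b2": "GHWATY"})
        groups = build_groups(
            [CorrelatedPair(4, 4, 0.9), CorrelatedPair(6, 2, 0.8)]
        )
        regions = RegionSet([Region("coreA", "refA", 2, 4), Region("rbdB", "refB", 3, 5)])
        rep = residue_region_report(groups, regions, fam_a, fam_b, "refA", "refB")
        per = rep.per_family.set_index(["family", "region"])
        assert per.loc[("A", "coreA"), "n_in_region"] == 1  # residue 4 in 2-4; 6 not
        assert per.loc[("A", "coreA"), "pct_in_region"] == 50.0
        assert per.loc[("B", "rbdB"), "n_in_region"] == 1  # residue 4 in 3-5; 2 not
        classes = dict(zip(rep.group_classes.group_id, rep.group_classes["class"]))
        assert classes["G1"] == "both-domain"  # (4,4) hits both regions
        assert classes["G2"] == "neither"
        conserved = rep.residues.set_index(["family", "column"]).conserved
        assert not conserved.loc[("A", 4)]  # L vs I varies
        assert conserved.loc[("B", 2)]


class TestEndToEndOnSimulatedFamilies:
    def test_planted_pairs_score_high(self, coevolving_bundle):
        b = coevolving_bundle
        mat = load_substitution_matrix("BLOSUM62")
        pa = site_profiles(b.fam_a, matched_sequence_pairs(b.pairing, "A"), mat)
        pb = site_profiles(b.fam_b, matched_sequence_pairs(b.pairing, "B"), mat)
        pairs = intermolecular_correlations(pa, pb)
        rhos = {(p.site_a, p.site_b): p.rho for p in pairs}
        all_rho = np.array([p.rho for p in pairs])
        found = [rhos[t] for t in map(tuple, b.truth.coupled_pairs) if t in rhos]
        assert found, "planted sites dropped from the profile set"
        # coupling signal present: planted pairs sit clearly above the
        # background (at least one in the top decile, all above the median)
        assert sum(r > np.quantile(all_rho, 0.9) for r in found) >= 1
        assert all(r > np.median(all_rho) for r in found)
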