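import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coevokit import distances as dst
from coevokit.distances import (
    PairRates,
    SaturationError,
    dnds_pair,
    kimura2p_from_pq,
    kimura2p_pair,
    mean_pairwise_identity,
    p_distance,
    poisson_correct,
    z_compare,
)

from conftest import make_family


class TestPDistance:
    def test_identical_sequences(self):
        fam = make_family("f", {"a": "AAAA", "b": "AAAA"})
        assert p_distance(fam).get("a", "b") == 0.0

    def test_one_mismatch_in_four(self):
        fam = make_family("f", {"a": "AAAA", "b": "AAAT"})
        assert p_distance(fam).get("a", "b") == 0.25

    def test_pairwise_deletion_drops_gapped_columns(self):
        fam = make_family("f", {"a": "A-AA", "b": "AGAT"})
        assert p_distance(fam).get("a", "b") == pytest.approx(1 / 3)

    def test_no_comparable_columns_flagged_not_zero(self):
        fam = make_family("f", {"a": "A--", "b": "-AA"})
        dm = p_distance(fam)
        assert np.isnan(dm.get("a", "b"))
        assert dm.missing[0, 1]

    def test_complete_deletion(self):
        fam = make_family("f", {"a": "A-CD", "b": "AGCE", "c": "AGCD"})
        dm = p_distance(fam, mode="complete")
        # gapped column 2 removed for everyone: 3 columns remain
        assert dm.get("a", "b") == pytest.approx(1 / 3)
        assert dm.get("b", "c") == pytest.approx(1 / 3)


class TestPoisson:
    @pytest.mark.parametrize(
        "p,expected", [(0.0, 0.0), (0.1, 0.1053605), (0.5, 0.6931472)]
    )
    def test_closed_form(self, p, expected):
        assert poisson_correct(p) == pytest.approx(expected, abs=1e-6)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            poisson_correct(1.0)

    @given(st.floats(min_value=0.0, max_value=0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_correction_at_least_p_and_increasing(self, p):
        d = poisson_correct(p)
        assert d >= p
        assert poisson_correct(min(p + 1e-3, 0.995)) > d


class TestIdentity:
    def test_identical_is_100(self):
        fam = make_family("f", {"a": "MKVL", "b": "MKVL"})
        assert mean_pairwise_identity(fam) == 100.0

    def test_three_of_four(self):
        fam = make_family("f", {"a": "AAAA", "b": "AAAT"})
        assert mean_pairwise_identity(fam) == 75.0


class TestKimura2P:
    def test_identical(self):
        assert kimura2p_pair("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_from_observed_counts(self):
        # 20 sites, 2 transitions (A<->G), 1 transversion (C<->A)
        a = "A" * 10 + "C" * 10
        b = "G" * 2 + "A" * 8 + "A" + "C" * 9
        n, ts, tv = dst.count_transitions_transversions(a, b)
        assert (n, ts, tv) == (20, 2, 1)
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 0.1)
        assert kimura2p_pair(a, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "P,Q,expected",
        [(0.1, 0.05, 0.1701812), (0.0, 0.05, 0.0519868)],
    )
    def test_known_values(self, P, Q, expected):
        assert kimura2p_from_pq(P, Q) == pytest.approx(expected, abs=1e-6)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            kimura2p_from_pq(0.45, 0.2)

    @given(st.floats(min_value=1e-4, max_value=0.05))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_jukes_cantor_in_equal_rate_limit(self, P):
        # equal rates: transitions are 1 of the 3 possible changes, so the
        # expected proportions satisfy Q = 2P and K2P collapses to JC
        p_total = 3 * P
        jc = -0.75 * math.log(1 - 4 * p_total / 3)
        assert kimura2p_from_pq(P, 2 * P) == pytest.approx(jc, abs=1e-12)


class TestDnDs:
    def test_identical_pair(self):
        r = dnds_pair("ATGAAA", "ATGAAA")
        assert r.dn == 0.0 and r.ds == 0.0 and r.omega is None

    def test_single_synonymous_transition(self):
        # Phe TTT -> TTC: purely synonymous; uncorrected counts keep dS > 0
        r = dnds_pair("TTT", "TTC", kappa=1.0, correction="none")
        assert r.dn == 0.0
        assert r.ds > 0.0

    def test_single_nonsynonymous_transition(self):
        # Lys AAA -> Arg AGA
        r = dnds_pair("ATGAAA", "ATGAGA")
        assert r.ds == 0.0
        assert r.dn > 0.0

    def test_hand_tabulated_ng86_counts(self):
        # one syn (GGC->GGT) and one nonsyn (ATC->ACC) change over 2 codons,
        # all single-step, no stop-adjacent codons involved
        r = dnds_pair("GGCATC", "GGTACC", kappa=1.0, correction="none")
        # syn sites: GGC 1.0 (3rd pos fourfold), ATC 2/3; GGT 1.0, ACC 1.0
        s_exp = ((1.0 + 2 / 3) + (1.0 + 1.0)) / 2
        assert r.s_sites == pytest.approx(s_exp)
        assert r.ds == pytest.approx(1.0 / s_exp)
        assert r.dn == pytest.approx(1.0 / (6 - s_exp))

    def test_matches_biopython_ng86_on_stop_free_codons(self):
        # independent oracle: Bio.codonalign NG86 (plain counting, JC correction)
        pytest.importorskip("Bio.codonalign")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        a = "GGCCTCATCCCTGTTCGC"
        b = "GGTCTTACCCATGTTCGC"
        dn_ref, ds_ref = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        r = dnds_pair(a, b, kappa=1.0, correction="jc")
        assert r.dn == pytest.approx(dn_ref, abs=1e-12)
        assert r.ds == pytest.approx(ds_ref, abs=1e-12)

    def test_symmetric_in_arguments(self):
        a, b = "GGCCTCATCCCTGTTCGC", "GGTCTTACCCATGTTCGC"
        r1, r2 = dnds_pair(a, b), dnds_pair(b, a)
        assert r1.dn == pytest.approx(r2.dn) and r1.ds == pytest.approx(r2.ds)

    def test_invariant_to_appending_identical_codons(self):
        a, b = "ATGAAATTT", "ATGAGATTC"
        r1 = dnds_pair(a, b, kappa=2.0)
        r2 = dnds_pair(a + "GGCGGC", b + "GGCGGC", kappa=2.0)
        # identical codons add sites but no differences; dN and dS shrink
        # proportionally -- the *counts* are what must be preserved, so check
        # via uncorrected proportions scaled back
        p1 = dnds_pair(a, b, kappa=2.0, correction="none")
        p2 = dnds_pair(a + "GGCGGC", b + "GGCGGC", kappa=2.0, correction="none")
        assert p1.ds * p1.s_sites == pytest.approx(p2.ds * p2.s_sites)
        assert p1.dn * p1.n_sites == pytest.approx(p2.dn * p2.n_sites)

    def test_saturated_ds_flags_omega_undefined(self):
        r = PairRates(0.1, float("nan"), None, 3, 6, ds_saturated=True)
        assert r.omega is None and r.ds_saturated


class TestZCompare:
    def test_identical_samples(self):
        z, p = z_compare([1, 2, 3], [1, 2, 3])
        assert z == 0.0 and p == 1.0

    def test_separated_samples(self):
        a = [0.0, 1e-6, -1e-6, 0.0]
        b = [1.0, 1.0 + 1e-6, 1.0 - 1e-6, 1.0]
        z, p = z_compare(a, b)
        assert abs(z) > 50 and p < 1e-10

    def test_calibration_under_null(self):
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.standard_normal(100)
            b = rng.standard_normal(100)
            _, p = z_compare(a, b)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)
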