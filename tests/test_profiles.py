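"""Consensus calls, reliability ranks, and two-group differential analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isoprobe.expression_calling import DetectionCall, ExpressionSignal
from isoprobe.io_formats import GroupDesign
from isoprobe.profiles import (
    benjamini_hochberg,
    consensus_call,
    consensus_profiles,
    differential_detection,
    differential_regulation,
    pairwise_comparisons,
    reliability_rank,
)

P, A, M = "present", "absent", "marginal"


class TestConsensusCall:
    def test_four_present_one_absent(self):
        prof = consensus_call([P, P, P, P, A])
        assert prof.status == "transcribed"
        assert prof.pct_detection == pytest.approx(80.0)

    def test_equal_present_absent_is_no_call(self):
        assert consensus_call([P, A]).status == "no-call"

    def test_marginals_count_in_denominator_not_in_vote(self):
        prof = consensus_call([A, A, A, M])
        assert prof.status == "not-detected"
        assert prof.pct_detection == pytest.approx(75.0)

    def test_marginal_denominator_configurable(self):
        prof = consensus_call([A, A, A, M], marginal_in_denominator=False)
        assert prof.pct_detection == pytest.approx(100.0)

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            consensus_call([P, "weird"])

    @given(st.lists(st.sampled_from([P, A, M]), min_size=1, max_size=40),
           st.randoms())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_permutation_invariance(self, calls, rnd):
        base = consensus_call(calls)
        shuffled = list(calls)
        rnd.shuffle(shuffled)
        other = consensus_call(shuffled)
        assert (base.status, base.pct_detection) == (other.status, other.pct_detection)

    @given(st.lists(st.sampled_from([P, A]), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_majority_share_at_least_half_without_marginals(self, calls):
        prof = consensus_call(calls)
        if prof.status != "no-call":
            assert prof.pct_detection >= 50.0
        n = len(calls)
        assert any(
            math.isclose(prof.pct_detection, 100.0 * k / n) for k in range(n + 1)
        )


class TestReliabilityRank:
    @pytest.mark.parametrize(
        "pct,rank",
        [(95, 1), (90, 1), (89.99, 2), (85, 2), (80, 2), (79.99, 3), (50, 5),
         (10, 9), (9.99, 10), (0, 10), (100, 1)],
    )
    def test_decile_bins(self, pct, rank):
        assert reliability_rank(pct) == rank

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reliability_rank(101)


def make_signals(values_by_acc, hyb_ids):
    out = []
    for acc, values in values_by_acc.items():
        out.extend(
            ExpressionSignal(acc, hid, float(v)) for hid, v in zip(hyb_ids, values)
        )
    return out


class TestDifferentialRegulation:
    HYB = [f"h{i}" for i in range(6)]
    A_IDS, B_IDS = HYB[:3], HYB[3:]

    def test_identical_groups_not_significant(self):
        signals = make_signals({"NM_1.1": [5, 6, 7, 5, 6, 7]}, self.HYB)
        (rec,) = differential_regulation(signals, self.A_IDS, self.B_IDS)
        assert rec.p_value == pytest.approx(1.0)
        assert rec.status == "not-significant"

    def test_constructed_two_fold_up(self):
        rng = np.random.default_rng(13)
        a = 10 + rng.normal(0, 1e-6, 3)
        b = 8 + rng.normal(0, 1e-6, 3)
        signals = make_signals({"NM_1.1": list(a) + list(b)}, self.HYB)
        (rec,) = differential_regulation(signals, self.A_IDS, self.B_IDS)
        assert rec.status == "up"
        assert rec.fold_change == pytest.approx(2.0, abs=1e-4)
        # hand-computed Welch t for the same numbers
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t = (a.mean() - b.mean()) / math.sqrt(va / 3 + vb / 3)
        df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        assert rec.p_value == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-9)

    def test_p_values_match_reference_welch(self):
        rng = np.random.default_rng(14)
        hyb = [f"h{i}" for i in range(10)]
        data = {f"NM_{k}.1": rng.normal(8, 1, 10) for k in range(20)}
        signals = make_signals(data, hyb)
        recs = differential_regulation(signals, hyb[:5], hyb[5:])
        for rec in recs:
            a, b = data[rec.accession][:5], data[rec.accession][5:]
            ref = stats.ttest_ind(a, b, equal_var=False).pvalue
            assert rec.p_value == pytest.approx(ref, abs=1e-9)

    def test_pooled_variant_matches_reference(self):
        rng = np.random.default_rng(15)
        hyb = [f"h{i}" for i in range(8)]
        data = {"NM_1.1": rng.normal(8, 1, 8)}
        signals = make_signals(data, hyb)
        (rec,) = differential_regulation(signals, hyb[:4], hyb[4:], test="pooled")
        ref = stats.ttest_ind(data["NM_1.1"][:4], data["NM_1.1"][4:]).pvalue
        assert rec.p_value == pytest.approx(ref, abs=1e-12)

    def test_group_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(16)
        signals = make_signals({"NM_1.1": rng.normal(8, 1, 6)}, self.HYB)
        (fwd,) = differential_regulation(signals, self.A_IDS, self.B_IDS)
        (rev,) = differential_regulation(signals, self.B_IDS, self.A_IDS)
        assert rev.fold_change == pytest.approx(-fwd.fold_change)
        assert rev.p_value == pytest.approx(fwd.p_value)
        flip = {"up": "down", "down": "up", "not-significant": "not-significant"}
        assert rev.status == flip[fwd.status]

    def test_singleton_group_rejected(self):
        signals = make_signals({"NM_1.1": [1, 2, 3]}, ["h0", "h1", "h2"])
        with pytest.raises(ValueError, match="group B"):
            differential_regulation(signals, ["h0", "h1"], ["h2"])

    def test_output_sorted_by_p(self):
        rng = np.random.default_rng(18)
        hyb = [f"h{i}" for i in range(6)]
        data = {f"NM_{k}.1": rng.normal(8, 1, 6) for k in range(10)}
        data["NM_99.1"] = [10, 10.1, 9.9, 5, 5.1, 4.9]  # strongly separated
        recs = differential_regulation(make_signals(data, hyb), hyb[:3], hyb[3:])
        ps = [r.p_value for r in recs]
        assert ps == sorted(ps)
        assert recs[0].accession == "NM_99.1"

    def test_bh_qvalues_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(19)
        p = rng.uniform(0, 1, 25)
        np.testing.assert_allclose(
            benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1]
        )


class TestDifferentialDetection:
    def _profiles(self, statuses):
        return [
            consensus_call([P] * 3 if s == "transcribed" else
                           [A] * 3 if s == "not-detected" else [P, A, M],
                           accession=f"NM_{i}.1")
            for i, s in enumerate(statuses)
        ]

    def test_opposite_statuses_flagged(self):
        a = self._profiles(["transcribed"])
        b = self._profiles(["not-detected"])
        (r,) = differential_detection(a, b)
        assert r.flagged

    def test_same_status_unflagged(self):
        (r,) = differential_detection(
            self._profiles(["transcribed"]), self._profiles(["transcribed"])
        )
        assert not r.flagged

    def test_no_call_reported_but_unflagged(self):
        (r,) = differential_detection(
            self._profiles(["no-call"]), self._profiles(["not-detected"])
        )
        assert not r.flagged and r.status_a == "no-call"

    def test_identical_groups_flag_nothing(self, mapped_study):
        from isoprobe.expression_calling import call_matrix

        calls, _ = call_matrix(mapped_study["clusters"], mapped_study["matrix"])
        hyb = mapped_study["matrix"].hybridization_ids
        pa = consensus_profiles(calls, hybridization_ids=hyb)
        pb = consensus_profiles(calls, hybridization_ids=hyb)
        assert sum(r.flagged for r in differential_detection(pa, pb)) == 0

    def test_mismatched_transcript_sets_rejected(self):
        with pytest.raises(ValueError):
            differential_detection(self._profiles(["transcribed"]), [])


class TestPairwise:
    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (4, 6)])
    def test_pair_counts(self, n, expected):
        design = GroupDesign(groups={f"g{i}": [f"h{i}"] for i in range(n)})
        pairs = pairwise_comparisons(design)
        assert len(pairs) == expected
        assert pairs[0] == ("g0", "g1")  # definition order

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_comparisons(GroupDesign(groups={"g": ["h"]}))
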