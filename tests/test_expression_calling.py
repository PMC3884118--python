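"""Detection-call machinery and the RMA-style signal path."""

import itertools

import numpy as np
import pytest
from scipy import stats

from isoprobe.cluster_builder import ProbeCluster
from isoprobe.expression_calling import (
    CallThresholds,
    background_correct_conv,
    call_detection,
    call_matrix,
    detection_p,
    discrimination_scores,
    median_polish,
    quantile_normalize,
    summarize_rma,
)
from isoprobe.io_formats import IntensityMatrix


def enumeration_p(scores, tau):
    """Independent oracle: explicit loop over all sign assignments."""
    d = np.asarray(scores, dtype=float) - tau
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        if np.dot(signs, ranks) >= w_obs - 1e-9:
            count += 1
    return count / 2**n


class TestDiscriminationScores:
    def test_arithmetic(self):
        assert discrimination_scores([200.0], [100.0])[0] == pytest.approx(1 / 3)

    def test_symmetry_pm_equals_mm(self):
        assert discrimination_scores([50.0], [50.0])[0] == 0.0

    def test_random_vectors_match_formula(self):
        rng = np.random.default_rng(5)
        pm = rng.uniform(1, 1000, size=64)
        mm = rng.uniform(1, 1000, size=64)
        np.testing.assert_allclose(
            discrimination_scores(pm, mm), (pm - mm) / (pm + mm)
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            discrimination_scores([0.0], [1.0])


class TestDetectionP:
    def test_six_scores_all_above_tau(self):
        assert detection_p([0.5] * 6 + [], 0.015) == pytest.approx(1 / 64)

    def test_distinct_scores_all_above_tau(self):
        # no ties: p = 1/2^6 for the maximal rank sum
        scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        assert detection_p(scores, 0.015) == pytest.approx(0.015625)

    def test_single_negative_score(self):
        assert detection_p([-0.2], 0.015) == 1.0

    def test_all_scores_equal_tau_degenerate(self):
        assert detection_p([0.015, 0.015], 0.015) == 1.0

    @pytest.mark.parametrize("n", range(1, 13))
    def test_matches_enumeration_for_small_n(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            scores = rng.normal(0.02, 0.1, size=n)
            # quantize to force occasional ties and zeros
            scores = np.round(scores, 2)
            assert detection_p(scores, 0.015) == pytest.approx(
                enumeration_p(scores, 0.015)
            )

    def test_matches_scipy_exact_one_sided_without_ties(self):
        rng = np.random.default_rng(17)
        d = rng.normal(0.05, 0.1, size=11)
        while len(np.unique(np.abs(d))) < len(d) or np.any(d == 0):
            d = rng.normal(0.05, 0.1, size=11)
        expected = stats.wilcoxon(d, alternative="greater", mode="exact").pvalue
        assert detection_p(d + 0.015, 0.015) == pytest.approx(expected)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        # n just above the enumeration cutoff: approximation within a few
        # percent of the exact tail
        rng = np.random.default_rng(23)
        d = rng.normal(0.03, 0.1, size=21)
        approx = detection_p(d + 0.015, 0.015)
        exact = stats.wilcoxon(d, alternative="greater", mode="exact").pvalue
        assert approx == pytest.approx(exact, abs=0.02)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            detection_p([], 0.015)


class TestCallDetection:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.05, "present"), (0.065, "absent"), (0.06, "marginal"),
         (0.0, "present"), (1.0, "absent")],
    )
    def test_threshold_semantics(self, p, expected):
        assert call_detection(p, CallThresholds()) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CallThresholds(alpha_present=0.1, alpha_absent=0.05)


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        x = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 3))
        np.testing.assert_allclose(quantile_normalize(x), x)

    def test_two_by_two_means_of_order_statistics(self):
        x = np.array([[1.0, 3.0], [2.0, 4.0]])
        np.testing.assert_allclose(
            quantile_normalize(x), np.array([[2.0, 2.0], [3.0, 3.0]])
        )

    def test_columns_share_sorted_vector_and_preserve_ranks(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(5, 1, size=(50, 4))
        out = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)
            assert np.array_equal(
                np.argsort(out[:, j], kind="stable"),
                np.argsort(x[:, j], kind="stable"),
            )

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(5, 1, size=(30, 3))
        once = quantile_normalize(x)
        np.testing.assert_allclose(quantile_normalize(once), once, rtol=1e-12)

    def test_single_column_unchanged(self):
        x = np.array([[5.0], [1.0]])
        np.testing.assert_allclose(quantile_normalize(x), x)


def cluster_of(n, acc="NM_1.1"):
    pairs = [((i, 0), (i, 1), i + 1, i + 25, "forward") for i in range(n)]
    return ProbeCluster(acc, "g1", "STG", pairs)


class TestMedianPolishSummary:
    def test_constant_matrix(self):
        x = np.full((4, 3), 7.5)
        signals = summarize_rma(cluster_of(4), x, ["a", "b", "c"])
        assert [s.signal for s in signals] == pytest.approx([7.5] * 3)

    def test_exactly_additive_matrix_recovered(self):
        probe_eff = np.array([0.0, 1.0, -0.5, 0.25])
        sample_eff = np.array([0.0, 2.0, -1.0])
        mu = 8.0
        x = mu + probe_eff[:, None] + sample_eff[None, :]
        signals = summarize_rma(cluster_of(4), x, ["a", "b", "c"])
        got = np.array([s.signal for s in signals])
        # additive model is exact: recovered up to the shared intercept split
        np.testing.assert_allclose(got - got[0], sample_eff, atol=1e-9)
        assert np.median(probe_eff) + mu + sample_eff[0] == pytest.approx(got[0])

    def test_single_probe_cluster_is_identity(self):
        x = np.array([[1.0, 2.0, 3.0]])
        signals = summarize_rma(cluster_of(1), x, ["a", "b", "c"])
        assert [s.signal for s in signals] == [1.0, 2.0, 3.0]

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(8, 1, size=(6, 4))
        base = [s.signal for s in summarize_rma(cluster_of(6), x, list("abcd"))]
        shifted = [
            s.signal for s in summarize_rma(cluster_of(6), x + 3.25, list("abcd"))
        ]
        np.testing.assert_allclose(np.array(shifted) - np.array(base), 3.25)

    def test_median_polish_decomposition_consistent(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, size=(7, 5))
        overall, row_eff, col_eff, resid = median_polish(x)
        np.testing.assert_allclose(
            overall + row_eff[:, None] + col_eff[None, :] + resid, x, atol=1e-12
        )


class TestCallMatrix:
    def test_shapes_one_cluster_one_hybridization(self):
        matrix = IntensityMatrix(
            hybridization_ids=["h1"],
            cells=[(0, 0), (0, 1)],
            values=np.array([[200.0], [100.0]]),
        )
        calls, signals = call_matrix([cluster_of(1)], matrix)
        assert len(calls) == 1 and len(signals) == 1
        assert calls[0].hybridization_id == "h1"

    def test_missing_cell_is_hard_error(self):
        matrix = IntensityMatrix(
            hybridization_ids=["h1"], cells=[(0, 0)], values=np.array([[200.0]])
        )
        with pytest.raises(KeyError, match="NM_1.1"):
            call_matrix([cluster_of(1)], matrix)

    def test_end_to_end_call_recovery(self, mapped_study):
        """Expressed transcripts called present, absent ones absent, at the
        recovery rates the simulation is designed to support."""
        truth = mapped_study["truth"]
        calls, signals = call_matrix(mapped_study["clusters"], mapped_study["matrix"])
        ok = {"expressed": [0, 0], "absent": [0, 0]}
        for c in calls:
            if truth.expressed[c.accession]:
                ok["expressed"][1] += 1
                ok["expressed"][0] += c.status == "present"
            else:
                ok["absent"][1] += 1
                ok["absent"][0] += c.status == "absent"
        assert ok["expressed"][0] / ok["expressed"][1] >= 0.95
        assert ok["absent"][0] / ok["absent"][1] >= 0.90

    def test_signals_track_expression_truth(self, mapped_study):
        truth = mapped_study["truth"]
        _, signals = call_matrix(mapped_study["clusters"], mapped_study["matrix"])
        by_acc: dict[str, list[float]] = {}
        for s in signals:
            by_acc.setdefault(s.accession, []).append(s.signal)
        mean_e = np.mean([np.mean(v) for a, v in by_acc.items() if truth.expressed[a]])
        mean_a = np.mean([np.mean(v) for a, v in by_acc.items() if not truth.expressed[a]])
        assert mean_e > mean_a + 1.0  # log2 separation

    def test_background_correction_keeps_positive_and_reduces_bias(self):
        rng = np.random.default_rng(12)
        x = rng.exponential(200, size=(300, 2)) + rng.normal(100, 20, size=(300, 2))
        corrected = background_correct_conv(x)
        assert np.all(corrected > 0)
        assert corrected.mean() < x.mean()  # background removed on average
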