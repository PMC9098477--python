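"""Activity scoring, shuffle nulls, classification, and event metrics."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from pharmaca.dataio import AnalysisConfig
from pharmaca.response import (DegenerateScoreError, EpochActivity,
                               activity_score, baseline_filter,
                               classify_response, classify_session,
                               compare_groups, epoch_totals, event_metrics,
                               score_null)


class TestEpochTotalsAndScore:
    def test_examples(self):
        assert epoch_totals(np.zeros(10), 5) == EpochActivity(0.0, 0.0)
        assert epoch_totals([1, 2, 3, 4], 2) == EpochActivity(3.0, 7.0)
        assert activity_score(EpochActivity(1000, 3000)) == pytest.approx(0.5)
        assert activity_score(EpochActivity(2000, 2000)) == 0.0
        assert activity_score(EpochActivity(4000, 0)) == -1.0

    def test_zero_total_is_degenerate(self):
        with pytest.raises(DegenerateScoreError):
            activity_score(EpochActivity(0, 0))

    def test_matches_bruteforce_summation(self, rng):
        for _ in range(50):
            n = rng.integers(4, 60)
            split = int(rng.integers(1, n))
            train = rng.exponential(3, n) * (rng.random(n) < 0.4)
            e = epoch_totals(train, split)
            assert e.a_before == pytest.approx(sum(train[t] for t in range(split)))
            assert e.a_after == pytest.approx(sum(train[t] for t in range(split, n)))

    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    def test_antisymmetric_under_epoch_swap(self, a, b):
        assert activity_score(EpochActivity(a, b)) == pytest.approx(
            -activity_score(EpochActivity(b, a)))


class TestBaselineFilter:
    @pytest.mark.parametrize("a_before,keep", [
        (999.9, False), (2500.0, True), (1000.0, True), (4000.0, True),
        (4000.1, False)])
    def test_inclusive_window(self, a_before, keep):
        assert baseline_filter(EpochActivity(a_before, 1.0), 1000, 4000) is keep


class TestScoreNull:
    def test_exhaustive_four_frame_enumeration(self, rng):
        """One event in four frames, split in half: exhaustive permutation of
        the frame order puts it before the injection in exactly half the
        4! orderings, so the null is {-1, +1} with equal mass."""
        train = np.array([5.0, 0.0, 0.0, 0.0])
        brute = [activity_score(epoch_totals(np.array(p), 2))
                 for p in itertools.permutations(train)]
        vals, counts = np.unique(np.round(brute, 12), return_counts=True)
        assert list(vals) == [-1.0, 1.0]
        assert list(counts) == [12, 12]
        null = score_null(train, 2, 4000, rng)
        assert set(np.unique(null)) == {-1.0, 1.0}
        assert np.mean(null == 1.0) == pytest.approx(0.5, abs=0.05)

    def test_matches_literal_permutation_oracle(self, rng):
        train = np.zeros(40)
        train[[3, 8, 11, 20, 33, 39]] = rng.exponential(5, 6)
        literal = np.array([
            activity_score(epoch_totals(rng.permutation(train), 15))
            for _ in range(4000)])
        fast = score_null(train, 15, 4000, rng)
        assert ks_2samp(literal, fast).pvalue > 1e-3

    def test_deterministic_under_seed(self, drug_session):
        train = drug_session[0].activity[0]
        a = score_null(train, 6000, 500, np.random.default_rng(4))
        b = score_null(train, 6000, 500, np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_mean_near_zero_for_equal_epochs(self, drug_session):
        train = drug_session[0].activity[1]
        null = score_null(train, 6000, 5000, np.random.default_rng(0))
        assert abs(null.mean()) < 0.02

    def test_circular_scheme_and_bad_scheme(self, drug_session):
        train = drug_session[0].activity[2]
        null = score_null(train, 6000, 500, np.random.default_rng(0),
                          scheme="circular")
        assert null.shape == (500,) and abs(null.mean()) < 0.3
        with pytest.raises(Exception):
            score_null(train, 6000, 10, np.random.default_rng(0), scheme="bogus")

    def test_degenerate_train_warns(self):
        train = np.zeros(100)
        train[3] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            null = score_null(train, 50, 200, np.random.default_rng(0))
        assert set(np.unique(null)) <= {-1.0, 1.0}


class TestClassification:
    def test_strict_inequality_at_threshold(self):
        null = np.linspace(-1, 1, 1001)  # upper 0.1% cutoff = max = 1.0
        assert classify_response(1.0, null, 0.001)[0] == "stable"
        assert classify_response(1.0000001, null, 0.001)[0] == "excited"
        assert classify_response(-1.0, null, 0.001)[0] == "stable"
        assert classify_response(-1.0000001, null, 0.001)[0] == "inhibited"
        assert classify_response(0.0, null, 0.001)[0] == "stable"

    def test_scores_and_labels_are_scale_invariant(self, drug_session):
        """Multiplying a train by c > 0 changes no score and no label."""
        session, _ = drug_session
        cfg = AnalysisConfig.fast(score_null_iters=400)
        train = session.activity[3]
        e1, e2 = epoch_totals(train, 6000), epoch_totals(train * 7.5, 6000)
        assert activity_score(e1) == pytest.approx(activity_score(e2))
        n1 = score_null(train, 6000, 400, np.random.default_rng(1))
        n2 = score_null(train * 7.5, 6000, 400, np.random.default_rng(1))
        assert np.allclose(n1, n2)
        s = activity_score(e1)
        lab1, lo1, hi1 = classify_response(s, n1, cfg.score_tail)
        lab2, lo2, hi2 = classify_response(s, n2, cfg.score_tail)
        assert lab1 == lab2
        assert lo1 == pytest.approx(lo2) and hi1 == pytest.approx(hi2)


class TestEventMetrics:
    def test_worked_example(self):
        m = event_metrics(np.array([2.0, 0.0, 4.0, 4.0]), 2)
        assert (m.f_before, m.f_after) == (1, 2)
        assert m.frequency_score == pytest.approx(1 / 3)
        assert np.allclose(m.sizes_post, [2.0, 2.0])
        assert np.mean(m.sizes_pre) == pytest.approx(1.0)

    def test_pre_normalisation_identity(self, rng):
        for _ in range(20):
            train = rng.exponential(4, 200) * (rng.random(200) < 0.3)
            m = event_metrics(train, 100)
            if m.sizes_pre is not None:
                assert np.mean(m.sizes_pre) == pytest.approx(1.0)

    def test_counts_match_bruteforce(self, rng):
        for _ in range(50):
            train = rng.exponential(4, 80) * (rng.random(80) < 0.25)
            m = event_metrics(train, 40)
            assert m.f_before == sum(1 for t in range(40) if train[t] > 0)
            assert m.f_after == sum(1 for t in range(40, 80) if train[t] > 0)

    def test_zero_pre_events_flagged(self):
        m = event_metrics(np.array([0.0, 0.0, 3.0, 1.0]), 2)
        assert m.sizes_pre is None and m.sizes_post is None
        assert m.frequency_score == pytest.approx(1.0)


def _results_df(scores, labels):
    n = len(scores)
    return pd.DataFrame({
        "neuron_id": range(n), "a_before": 2000.0, "a_after": 2000.0,
        "activity_score": scores, "null_lo": -0.1, "null_hi": 0.1,
        "label": labels, "f_before": 10, "f_after": 10,
        "frequency_score": scores})


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        df = _results_df([0.1, 0.2, 0.3, -0.1], ["excited"] * 4)
        out = compare_groups(df, df.copy())
        assert out["per_class"]["excited"]["activity_score"]["pvalue"] == pytest.approx(1.0)

    def test_separated_groups_small_sample_exact(self):
        a = _results_df([1, 2, 3], ["excited"] * 3)
        b = _results_df([4, 5, 6], ["excited"] * 3)
        res = compare_groups(a, b)["per_class"]["excited"]["activity_score"]
        assert res["statistic"] == 0.0
        assert res["pvalue"] == pytest.approx(0.1)
        assert "exact" in res["method"]

    def test_empty_class_skipped_with_note(self):
        a = _results_df([0.5, 0.6], ["excited", "excited"])
        b = _results_df([0.1, 0.2], ["stable", "stable"])
        with pytest.warns(UserWarning, match="empty"):
            out = compare_groups(a, b)
        assert "note" in out["per_class"]["excited"]

    def test_class_counts_reported(self):
        a = _results_df([0.1, 0.2, 0.3], ["excited", "inhibited", "excluded"])
        out = compare_groups(a, a.copy())
        assert out["class_counts"]["a"] == {
            "excited": 1, "inhibited": 1, "stable": 0, "excluded": 1}


def test_classify_session_universe_partition(stationary_session, fast_config):
    """Every neuron gets exactly one label; classified + excluded = all."""
    session, _ = stationary_session
    results, sizes = classify_session(session, fast_config, np.random.default_rng(0))
    assert len(results) == session.n_neurons
    assert set(results["label"]) <= {"excited", "inhibited", "stable", "excluded"}
    kept = results[results["label"] != "excluded"]
    assert ((kept["a_before"] >= 1000) & (kept["a_before"] <= 4000)).all()
    assert set(sizes["epoch"]) <= {"pre", "post"}
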