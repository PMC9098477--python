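"""Binning, SVM decoding, count matching, ablation, and paired comparison."""
import numpy as np
import pandas as pd
import pytest

from pharmaca.dataio import AnalysisConfig, SessionData
from pharmaca.decoding import (BinnedActivity, ablation_accuracy, bin_activity,
                               compare_accuracies, matched_population_accuracy,
                               single_neuron_accuracy, train_eval_decoder)
from pharmaca.synthgen import GeneratorConfig, generate_session


@pytest.fixture(scope="module")
def cfg():
    return AnalysisConfig.fast(subset_repeats=10)


class TestBinning:
    def test_default_design_forty_bins(self, stationary_session):
        session, _ = stationary_session
        binned = bin_activity(session)
        assert binned.X.shape == (session.n_neurons, 40)
        assert (binned.labels == "before").sum() == 20
        assert (binned.labels == "after").sum() == 20

    def test_constant_train_sums_to_bin_width(self):
        s = SessionData(np.ones((1, 1200)), 10.0, 600, np.zeros((1, 2)))
        binned = bin_activity(s)
        assert np.allclose(binned.X, 300.0)

    def test_matches_bruteforce_window_sums(self, rng):
        act = rng.exponential(2, (3, 1200)) * (rng.random((3, 1200)) < 0.3)
        s = SessionData(act, 10.0, 600, np.zeros((3, 2)))
        binned = bin_activity(s)
        for i in range(3):
            for b in range(4):
                assert binned.X[i, b] == pytest.approx(
                    sum(act[i, t] for t in range(b * 300, (b + 1) * 300)))

    def test_non_divisible_raises_unless_truncated(self, rng):
        s = SessionData(np.ones((1, 1250)), 10.0, 600, np.zeros((1, 2)))
        with pytest.raises(ValueError, match="truncate"):
            bin_activity(s)
        binned = bin_activity(s, truncate=True)
        assert binned.X.shape == (1, 4)

    def test_mean_reducer(self):
        s = SessionData(np.ones((1, 600)), 10.0, 300, np.zeros((1, 2)))
        assert np.allclose(bin_activity(s, reducer="mean").X, 1.0)


class TestDecoder:
    def test_separable_effect_decoded_perfectly(self, cfg):
        gc = GeneratorConfig(n_neurons=60, seed=60, frac_excited=1.0,
                             frac_inhibited=0.0, effect_excited=2.0)
        session, _ = generate_session(gc, "pitolisant")
        acc = train_eval_decoder(bin_activity(session), cfg, np.random.default_rng(0))
        assert acc == 1.0

    def test_chance_level_on_permuted_labels(self, stationary_session, cfg):
        session, _ = stationary_session
        binned = bin_activity(session)
        rng = np.random.default_rng(61)
        accs = []
        for _ in range(60):
            shuffled = BinnedActivity(binned.X, rng.permutation(binned.labels),
                                      binned.bin_seconds)
            accs.append(train_eval_decoder(shuffled, cfg, rng))
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_deterministic_under_seed(self, drug_session, cfg):
        session, _ = drug_session
        binned = bin_activity(session)
        a = train_eval_decoder(binned, cfg, np.random.default_rng(7))
        b = train_eval_decoder(binned, cfg, np.random.default_rng(7))
        assert a == b

    def test_zero_variance_single_neuron_at_chance(self, cfg):
        act = np.zeros((1, 1200))
        act[0, ::2] = 1.0  # constant bins -> no usable feature
        s = SessionData(act, 10.0, 600, np.zeros((1, 2)))
        out = single_neuron_accuracy(s, cfg, np.random.default_rng(1))
        assert out["mean_accuracy"] == pytest.approx(0.5, abs=0.25)

    def test_one_informative_neuron_lifts_mean(self, cfg, rng):
        n, frames = 5, 1200
        act = rng.exponential(1, (n, frames)) * (rng.random((n, frames)) < 0.3)
        act[0, 600:] *= 20.0  # strongly modulated neuron
        s = SessionData(act, 10.0, 600, np.zeros((n, 2)))
        out = single_neuron_accuracy(s, cfg, np.random.default_rng(2))
        assert out["per_neuron"][0] == 1.0
        assert out["mean_accuracy"] > 0.5


class TestMatching:
    def test_equal_sizes_only_split_randomness(self, drug_session, cfg):
        session, _ = drug_session
        out = matched_population_accuracy(session, session, cfg,
                                          np.random.default_rng(3))
        assert out["n_neurons_used"] == session.n_neurons
        assert out["n_repeats"] == cfg.subset_repeats

    def test_drug_effect_increases_accuracy(self, cfg):
        sal, _ = generate_session(GeneratorConfig(n_neurons=40, seed=70,
                                                  frac_excited=0.0,
                                                  frac_inhibited=0.0), "saline")
        drug, _ = generate_session(GeneratorConfig(n_neurons=40, seed=71),
                                   "pitolisant")
        out = matched_population_accuracy(sal, drug, cfg, np.random.default_rng(4))
        assert out["accuracy_b"] > out["accuracy_a"]
        assert out["accuracy_b"] > 0.9

    def test_deterministic_pair_of_means(self, drug_session, cfg):
        session, _ = drug_session
        a = matched_population_accuracy(session, session, cfg, np.random.default_rng(5))
        b = matched_population_accuracy(session, session, cfg, np.random.default_rng(5))
        assert (a["accuracy_a"], a["accuracy_b"]) == (b["accuracy_a"], b["accuracy_b"])

    def test_too_few_neurons_rejected(self, drug_session, cfg):
        session, _ = drug_session
        with pytest.raises(ValueError):
            matched_population_accuracy(session, session, cfg,
                                        np.random.default_rng(0), pool_a=[0])


class TestAblation:
    def _results(self, labels):
        return pd.DataFrame({"neuron_id": range(len(labels)), "label": labels})

    def test_excluding_absent_class_equals_unablated(self, drug_session, cfg):
        session, _ = drug_session
        labels = ["stable"] * session.n_neurons
        res = self._results(labels)
        abl = ablation_accuracy(session, session, res, res, "inhibited", cfg,
                                np.random.default_rng(8))
        base = matched_population_accuracy(session, session, cfg,
                                           np.random.default_rng(8))
        assert abl["accuracy_a"] == base["accuracy_a"]
        assert abl["accuracy_b"] == base["accuracy_b"]

    def test_ablating_to_nothing_raises(self, drug_session, cfg):
        session, _ = drug_session
        res = self._results(["stable"] * session.n_neurons)
        with pytest.raises(ValueError, match="fewer than 2"):
            ablation_accuracy(session, session, res, res, "stable", cfg,
                              np.random.default_rng(0))


class TestCompareAccuracies:
    def test_identical_vectors(self):
        res = compare_accuracies([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert (res.statistic, res.pvalue) == (0.0, 1.0)

    def test_zero_within_pair_variance_flagged(self):
        res = compare_accuracies([0.5] * 5, [0.9] * 5)
        assert np.isnan(res.pvalue) and "degenerate" in res.note

    def test_closed_form_oracle(self):
        x = np.array([0.70, 0.72, 0.68, 0.71, 0.69])
        y = np.array([0.90, 0.93, 0.91, 0.95, 0.92])
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = compare_accuracies(x, y)
        assert res.statistic == pytest.approx(t_oracle)
        assert res.pvalue < 1e-3
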