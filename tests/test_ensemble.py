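"""Session splits, network training, aggregation, reject rule, metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import specfinger as sf
from specfinger.ensemble import (
    ObservationSummary,
    make_session_split,
    reliability_call,
    train_session,
)
from specfinger.exceptions import CohortError, ConfigError, EvaluationError


def toy_ids_labels(n_pos, n_neg):
    ids = [f"x{i}" for i in range(n_pos + n_neg)]
    labels = np.array(["positive"] * n_pos + ["negative"] * n_neg, dtype=object)
    return ids, labels


class TestExpectedTestInclusions:
    @pytest.mark.parametrize(
        "n,frac,expected", [(67, 0.15, 10.05), (1, 1.0, 1.0), (10, 0.1, 1.0)]
    )
    def test_values(self, n, frac, expected):
        assert sf.expected_test_inclusions(n, frac) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ConfigError):
            sf.expected_test_inclusions(0, 0.15)


class TestMakeSessionSplit:
    def test_unstratified_sizes_394(self):
        ids, labels = toy_ids_labels(192, 202)
        config = sf.EnsembleConfig(master_seed=0, stratified=False)
        split = make_session_split(ids, labels, config, 0)
        assert (len(split.train), len(split.val), len(split.test)) == (276, 59, 59)

    def test_stratified_sizes_per_class(self):
        ids, labels = toy_ids_labels(192, 202)
        config = sf.EnsembleConfig(master_seed=0)
        split = make_session_split(ids, labels, config, 0)
        # per-class rounding: 192 -> 134/29/29, 202 -> 141/31/30
        assert (len(split.train), len(split.val), len(split.test)) == (275, 60, 59)
        for part in (split.train, split.val, split.test):
            assert (labels[part] == "positive").sum() in (29, 30, 31, 134)

    def test_partition_disjoint_and_complete(self):
        ids, labels = toy_ids_labels(50, 60)
        config = sf.EnsembleConfig(master_seed=3)
        split = make_session_split(ids, labels, config, 5)
        union = np.concatenate([split.train, split.val, split.test])
        assert sorted(union.tolist()) == list(range(110))

    def test_deterministic_in_seed_and_index(self):
        ids, labels = toy_ids_labels(40, 40)
        config = sf.EnsembleConfig(master_seed=9)
        a = make_session_split(ids, labels, config, 2)
        b = make_session_split(ids, labels, config, 2)
        c = make_session_split(ids, labels, config, 3)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)
        assert not np.array_equal(a.train, c.train)

    def test_small_class_rejected_when_stratified(self):
        ids, labels = toy_ids_labels(5, 40)
        with pytest.raises(CohortError):
            make_session_split(ids, labels, sf.EnsembleConfig(), 0)


def separable_toy(rng, n=60, shift=3.0, sd=0.3):
    n2 = n // 2
    X = np.vstack(
        [rng.normal(shift, sd, (n2, 2)), rng.normal(-shift, sd, (n2, 2))]
    )
    labels = np.array(["positive"] * n2 + ["negative"] * n2, dtype=object)
    return X, labels


class TestTrainSession:
    def test_separable_toy_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X, labels = separable_toy(rng)
        config = sf.EnsembleConfig(master_seed=0)
        split = make_session_split(list(range(60)), labels, config, 0)
        rec = train_session(X, labels, split, config, session_seed=1)
        assert rec.test_accuracy == 1.0
        assert np.all((rec.test_soft_outputs >= 0) & (rec.test_soft_outputs <= 1))

    def test_shuffled_labels_mean_accuracy_near_chance(self):
        rng = np.random.default_rng(1)
        X, labels = separable_toy(rng)
        accs = []
        for seed in range(20):
            shuffled = labels[np.random.default_rng(seed).permutation(60)]
            config = sf.EnsembleConfig(master_seed=seed, max_epochs=100)
            split = make_session_split(list(range(60)), shuffled, config, 0)
            rec = train_session(X, shuffled, split, config, session_seed=seed)
            accs.append(rec.test_accuracy)
        assert 0.2 <= np.mean(accs) <= 0.8


@pytest.fixture(scope="module")
def toy_run():
    rng = np.random.default_rng(2)
    X, labels = separable_toy(rng, n=80)
    config = sf.EnsembleConfig(n_sessions=6, master_seed=4, max_epochs=100)
    return X, labels, config, sf.run_ensemble(X, labels, config)


class TestRunEnsemble:
    def test_rerun_identical(self, toy_run):
        X, labels, config, run = toy_run
        again = sf.run_ensemble(X, labels, config)
        for a, b in zip(run.records, again.records):
            np.testing.assert_array_equal(a.test_soft_outputs, b.test_soft_outputs)
            np.testing.assert_array_equal(a.split.test, b.split.test)

    def test_appearance_conservation(self, toy_run):
        X, labels, config, run = toy_run
        summaries = sf.summarize_observations(run.records, labels, config)
        total_appearances = sum(s.n_test_appearances for s in summaries)
        assert total_appearances == sum(len(r.split.test) for r in run.records)

    def test_single_session_degenerates_gracefully(self):
        rng = np.random.default_rng(3)
        X, labels = separable_toy(rng, n=40)
        config = sf.EnsembleConfig(n_sessions=1, master_seed=0, max_epochs=60)
        run = sf.run_ensemble(X, labels, config)
        summaries = sf.summarize_observations(run.records, labels, config)
        assert len(run.records) == 1
        assert all(s.std == 0.0 and s.low_coverage for s in summaries)


class TestReliabilityRule:
    @pytest.mark.parametrize(
        "mean,std,call",
        [(0.8, 0.2, "positive"), (0.55, 0.10, "undefined"), (0.15, 0.25, "negative")],
    )
    def test_hand_cases(self, mean, std, call):
        assert reliability_call(mean, std) == call

    def test_tie_is_undefined(self):
        assert reliability_call(0.7, 0.2) == "undefined"

    @given(st.floats(0, 1), st.floats(0, 0.5))
    def test_trichotomy(self, mean, std):
        assert reliability_call(mean, std) in ("positive", "negative", "undefined")


def make_summary(label, call, mean=None, std=0.01, sid="s"):
    if mean is None:
        mean = {"positive": 0.9, "negative": 0.1, "undefined": 0.5}[call]
    return ObservationSummary(sid, label, 10, mean, std, call)


class TestClassificationTable:
    def test_printed_worked_example(self):
        # 63 positives: 60 assigned positive, 3 negative -> 95.2% / 4.8%
        summaries = [make_summary("positive", "positive", sid=f"p{i}") for i in range(60)]
        summaries += [make_summary("positive", "negative", sid=f"n{i}") for i in range(3)]
        table = sf.classification_table(summaries)
        assert table.counts.loc["positive", "positive"] == 60
        assert table.percentages.loc["positive", "positive"] == pytest.approx(95.2, abs=0.05)
        assert table.percentages.loc["positive", "negative"] == pytest.approx(4.8, abs=0.05)

    def test_counts_conserved_and_unknowns_excluded(self):
        summaries = (
            [make_summary("positive", "positive", sid=f"a{i}") for i in range(5)]
            + [make_summary("negative", "undefined", sid=f"b{i}") for i in range(4)]
            + [make_summary("unknown", "positive", sid="u0")]
        )
        table = sf.classification_table(summaries)
        assert table.counts.to_numpy().sum() == 9
        assert table.n_excluded_unknown == 1

    def test_all_correct_off_diagonals_zero(self):
        summaries = [make_summary("positive", "positive", sid=f"p{i}") for i in range(4)]
        summaries += [make_summary("negative", "negative", sid=f"n{i}") for i in range(4)]
        c = sf.classification_table(summaries).counts
        assert c.loc["positive", "negative"] == 0 and c.loc["negative", "positive"] == 0
        assert c["undefined"].sum() == 0


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "cp,fn,expected", [(58, 5, 92.06), (60, 3, 95.24), (0, 7, 0.0)]
    )
    def test_sensitivity(self, cp, fn, expected):
        assert sf.sensitivity(cp, fn) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "cn,fp,expected", [(189, 2, 98.95), (193, 9, 95.54), (5, 0, 100.0)]
    )
    def test_specificity(self, cn, fp, expected):
        assert sf.specificity(cn, fp) == pytest.approx(expected, abs=0.005)

    def test_zero_denominator(self):
        with pytest.raises(EvaluationError):
            sf.sensitivity(0, 0)
        with pytest.raises(EvaluationError):
            sf.specificity(0, 0)


class TestEvaluateExcludingUndefined:
    def build_perfect_with_undefined(self):
        summaries = [make_summary("positive", "positive", sid=f"p{i}") for i in range(187)]
        summaries += [make_summary("negative", "negative", sid=f"n{i}") for i in range(197)]
        summaries += [
            make_summary(lbl, "undefined", sid=f"u{i}")
            for i, lbl in enumerate(["positive"] * 5 + ["negative"] * 5)
        ]
        return summaries

    def test_perfect_reliable_calls(self):
        report = sf.evaluate_excluding_undefined(self.build_perfect_with_undefined())
        assert report.sensitivity == 100.0 and report.specificity == 100.0
        assert report.undefined_fraction == pytest.approx(10 / 394)
        assert report.n_reliable == 384

    def test_dropping_undefined_rows_leaves_reliable_counts(self):
        summaries = self.build_perfect_with_undefined()
        reliable_only = [s for s in summaries if s.call != "undefined"]
        a = sf.evaluate_excluding_undefined(summaries).table.counts
        b = sf.evaluate_excluding_undefined(reliable_only).table.counts
        cols = ["negative", "positive"]
        assert a[cols].equals(b[cols])

    def test_all_undefined_class_rejected(self):
        summaries = [make_summary("positive", "undefined", sid=f"p{i}") for i in range(5)]
        summaries += [make_summary("negative", "negative", sid=f"n{i}") for i in range(5)]
        with pytest.raises(EvaluationError):
            sf.evaluate_excluding_undefined(summaries)
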