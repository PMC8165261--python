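"""ROC-AUC, run aggregation, and the experiment harnesses."""

import numpy as np
import pytest

import qbcal as q
from qbcal.errors import ValidationError


def brute_force_auc(labels, scores):
    """All-pairs enumeration: P(score_pos > score_neg), ties 0.5."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert q.roc_auc([0, 1], [0.1, 0.9]) == 1.0

    def test_all_ties_are_chance(self):
        assert q.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="single class"):
            q.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_pair_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces some ties
            assert q.roc_auc(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        scores = rng.random(50)
        base = q.roc_auc(labels, scores)
        assert q.roc_auc(labels, np.exp(3 * scores)) == pytest.approx(base, abs=1e-12)
        assert q.roc_auc(labels, 5 * scores - 2) == pytest.approx(base, abs=1e-12)


class TestAggregateRuns:
    def runs(self, aucs):
        return [q.RunResult(a, "test", i) for i, a in enumerate(aucs)]

    def test_zero_variance(self):
        agg = q.aggregate_runs(self.runs([0.8] * 10))
        assert (agg.mean_auc, agg.ci_lo, agg.ci_hi) == (0.8, 0.8, 0.8)

    def test_two_run_half_width(self):
        """sd([0.7, 0.9]) = 0.141421; half-width = 1.96 * sd / sqrt(2) = 0.196."""
        agg = q.aggregate_runs(self.runs([0.7, 0.9]))
        assert agg.mean_auc == pytest.approx(0.8)
        assert agg.ci_hi - agg.mean_auc == pytest.approx(0.196, abs=1e-9)

    def test_half_width_shrinks_with_more_runs(self):
        """Repeating the same run pattern 4x shrinks the interval.

        Hand computation for [0.7, 0.9] x 4: sample sd = sqrt(0.08 / 7)
        = 0.10690450; half-width = 1.96 * sd / sqrt(8) = 0.07408104.
        """
        pattern = [0.7, 0.9]
        h2 = q.aggregate_runs(self.runs(pattern)).ci_hi - 0.8
        h8 = q.aggregate_runs(self.runs(pattern * 4)).ci_hi - 0.8
        assert h8 == pytest.approx(0.07408104, abs=1e-8)
        assert h8 < h2 / 2  # better than the fixed-sd 1/sqrt(n) rate (ddof shrinks sd too)

    def test_mean_is_exact_arithmetic_mean(self, rng):
        aucs = rng.random(10).tolist()
        assert q.aggregate_runs(self.runs(aucs)).mean_auc == pytest.approx(
            float(np.mean(aucs)), abs=1e-15)

    def test_single_run_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            q.aggregate_runs(self.runs([0.8]))

    def test_student_t_interval_is_wider_at_small_n(self):
        runs = self.runs([0.7, 0.8, 0.9, 0.75, 0.85])
        normal = q.aggregate_runs(runs, method="normal")
        student = q.aggregate_runs(runs, method="t")
        assert student.ci_hi > normal.ci_hi


@pytest.fixture(scope="module")
def harness_setup(planted_replicates):
    task, train, ranked = planted_replicates[0]
    return task, train, ranked


class TestRunExperiment:
    def test_single_run_rejected(self, harness_setup):
        task, train, _ = harness_setup
        with pytest.raises(ValidationError, match="n_runs"):
            q.run_experiment(train, train.sample_ids, eval_dataset=task.split_subset("test"),
                             n_runs=1)

    def test_deterministic_given_base_seed(self, harness_setup):
        task, train, _ = harness_setup
        ids = train.sample_ids[:120]
        kwargs = dict(eval_dataset=task.split_subset("test"), n_runs=2, base_seed=3)
        a = q.run_experiment(train, ids, **kwargs)
        b = q.run_experiment(train, ids, **kwargs)
        assert a == b

    def test_separable_task_reaches_high_auc(self, separable_task):
        train = separable_task.split_subset("train")
        test = separable_task.split_subset("test")
        full = q.run_experiment(train, train.sample_ids, eval_dataset=test, n_runs=2)
        subset = q.run_experiment(train, train.sample_ids[: len(train) // 2],
                                  eval_dataset=test, n_runs=2)
        assert full.mean_auc >= 0.9 and subset.mean_auc >= 0.9

    def test_single_class_subset_rejected(self, harness_setup):
        task, train, _ = harness_setup
        ones = train.manifest.loc[train.manifest["label"] == 1, "sample_id"].tolist()[:10]
        with pytest.raises(ValidationError, match="single class"):
            q.run_experiment(train, ones, eval_dataset=task.split_subset("test"), n_runs=2)


class TestRangeSweep:
    def test_unequal_widths_rejected(self, harness_setup):
        _, train, ranked = harness_setup
        with pytest.raises(ValidationError, match="width"):
            q.range_sweep(ranked, train, [q.RangeSpec(0.0, 0.3), q.RangeSpec(0.1, 0.5)])

    def test_equal_ranges_select_identical_ids(self, harness_setup):
        _, _, ranked = harness_setup
        a = q.select_range(ranked, q.RangeSpec(0.1, 0.4))
        b = q.select_range(ranked, q.RangeSpec(0.1, 0.4))
        assert a == b

    def test_produces_one_aggregate_per_range(self, harness_setup):
        task, train, ranked = harness_setup
        ranges = [q.RangeSpec(0.0, 0.3), q.RangeSpec(0.1, 0.4),
                  q.RangeSpec(0.6, 0.9), q.RangeSpec(0.7, 1.0)]
        results = q.range_sweep(ranked, train, ranges, eval_dataset=task.split_subset("test"),
                                n_runs=2, base_seed=0)
        assert set(results) == set(ranges)
        assert all(0.0 <= agg.mean_auc <= 1.0 for agg in results.values())


class TestSizeSweep:
    def test_off_grid_fraction_rejected(self, harness_setup):
        task, train, ranked = harness_setup
        with pytest.raises(ValidationError, match="0.10"):
            q.size_sweep(ranked, train, fractions=[0.85],
                         eval_dataset=task.split_subset("test"), n_runs=2)

    def test_arms_and_baseline_cardinality(self, harness_setup):
        task, train, ranked = harness_setup
        sweep = q.size_sweep(ranked, train, fractions=[0.1, 0.2],
                             eval_dataset=task.split_subset("test"), n_runs=2, base_seed=0)
        assert set(sweep.results) == {("uncertainty", 0.1), ("random", 0.1),
                                      ("uncertainty", 0.2), ("random", 0.2)}
        assert sweep.baseline.n_runs == 2
        frame = sweep.to_frame()
        assert len(frame) == 5

    def test_results_serialize(self, harness_setup, tmp_path):
        task, train, ranked = harness_setup
        sweep = q.size_sweep(ranked, train, fractions=[0.1],
                             eval_dataset=task.split_subset("test"), n_runs=2)
        q.evaluation.write_sweep_results(sweep, tmp_path / "sweep.tsv", tmp_path / "sweep.json")
        assert (tmp_path / "sweep.tsv").exists() and (tmp_path / "sweep.json").exists()
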