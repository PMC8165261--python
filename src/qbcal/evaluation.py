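"""ROC-AUC evaluation and the three experiment harnesses.

Every experiment reports the mean slice-level ROC-AUC of repeated
independent trainings together with a 95% confidence interval
(mean ± 1.96·sd/√n by default; a Student-t half-width is available).
The harnesses mirror the study designs: a selected-subset vs full-pool
comparison, a sweep over equal-width uncertainty ranges, and a
sample-size sweep pitting uncertainty sampling (after extreme exclusion)
against plain random sampling at matched subset sizes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .committee import TrainableProbabilisticClassifier, TrainingConfig, reference_classifier
from .errors import ValidationError
from .pipeline import SliceDataset
from .scoring import RankedScoreList
from .selection import (
    RangeSpec,
    SelectionPlan,
    exclude_extremes,
    proportion_to_count,
    random_baseline,
    sample_budget,
    select_range,
)

SWEEP_FRACTIONS = tuple(round(0.1 * i, 2) for i in range(1, 9))


def roc_auc(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> float:
    """Slice-level ROC-AUC (probability a positive outranks a negative; ties 0.5)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError(f"labels {y.shape} and scores {s.shape} differ in length")
    if np.unique(y).size < 2:
        raise ValidationError("ROC-AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, s))


@dataclass(frozen=True)
class RunResult:
    """One training run's AUC on one evaluation split."""

    auc: float
    split: str
    run_seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError(f"auc must be in [0, 1], got {self.auc}")


@dataclass(frozen=True)
class AggregateResult:
    """Mean AUC with a symmetric 95% confidence interval over runs."""

    mean_auc: float
    ci_lo: float
    ci_hi: float
    n_runs: int


def aggregate_runs(runs: Sequence[RunResult], method: str = "normal") -> AggregateResult:
    """Mean ± 95% CI over repeated runs (sample sd, n−1 denominator).

    ``method`` is "normal" (z = 1.96) or "t" (Student-t quantile at n−1
    degrees of freedom).
    """
    if len(runs) < 2:
        raise ValidationError(f"need >= 2 runs for a confidence interval, got {len(runs)}")
    aucs = np.array([r.auc for r in runs], dtype=float)
    mean = float(aucs.mean())
    sd = float(aucs.std(ddof=1))
    if method == "normal":
        crit = 1.96
    elif method == "t":
        crit = float(stats.t.ppf(0.975, len(aucs) - 1))
    else:
        raise ValidationError(f"unknown CI method {method!r}; use 'normal' or 't'")
    half = crit * sd / np.sqrt(len(aucs))
    return AggregateResult(mean, mean - half, mean + half, len(aucs))


def run_experiment(
    pool: SliceDataset,
    train_ids: Sequence[str],
    classifier_factory: Callable[[], TrainableProbabilisticClassifier] = reference_classifier,
    config: TrainingConfig = TrainingConfig(),
    eval_dataset: SliceDataset | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    validation: SliceDataset | None = None,
    ci_method: str = "normal",
) -> AggregateResult:
    """Train ``n_runs`` times on an id-subset and aggregate held-out AUC.

    Run r uses seed ``base_seed + r``; scores are the probability of
    class 1 on ``eval_dataset``. With ``validation`` supplied, each run
    keeps its best-validation-AUC epoch (early stopping).
    """
    if eval_dataset is None:
        raise ValidationError("run_experiment needs an eval_dataset")
    if n_runs < 2:
        raise ValidationError(f"n_runs must be >= 2 (CI undefined), got {n_runs}")
    if not train_ids:
        raise ValidationError("empty training id set")
    subset = pool.subset(list(train_ids))
    if np.unique(subset.labels).size < 2:
        raise ValidationError("training subset contains a single class")
    split_name = str(eval_dataset.manifest["split"].iloc[0]) if "split" in eval_dataset.manifest else "eval"
    runs = []
    for r in range(n_runs):
        cfg = dataclasses.replace(config, seed=base_seed + r)
        clf = classifier_factory()
        clf.fit(subset, cfg, validation=validation)
        probs = np.asarray(clf.predict_proba(eval_dataset))[:, 1]
        runs.append(RunResult(roc_auc(eval_dataset.labels, probs), split_name, cfg.seed))
    return aggregate_runs(runs, method=ci_method)


def range_sweep(
    ranked: RankedScoreList,
    pool: SliceDataset,
    ranges: Sequence[RangeSpec],
    classifier_factory: Callable[[], TrainableProbabilisticClassifier] = reference_classifier,
    config: TrainingConfig = TrainingConfig(),
    eval_dataset: SliceDataset | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    validation: SliceDataset | None = None,
) -> dict[RangeSpec, AggregateResult]:
    """Train on each uncertainty range of the ranked list (equal widths only).

    Equal widths keep the training-set size constant across ranges, so
    AUC differences reflect which part of the uncertainty distribution
    the samples came from, not how many there were.
    """
    if not ranges:
        raise ValidationError("range_sweep: no ranges given")
    widths = {round(r.width, 9) for r in ranges}
    if len(widths) != 1:
        raise ValidationError(f"ranges must share one width, got widths {sorted(widths)}")
    results = {}
    for r in ranges:
        ids = select_range(ranked, r)
        results[r] = run_experiment(pool, ids, classifier_factory, config, eval_dataset,
                                    n_runs=n_runs, base_seed=base_seed, validation=validation)
    return results


@dataclass(frozen=True)
class SweepResult:
    """Uncertainty-vs-random learning curves plus the full-pool baseline."""

    results: Mapping[tuple[str, float], AggregateResult]
    baseline: AggregateResult

    def arm(self, method: str) -> dict[float, AggregateResult]:
        return {f: agg for (m, f), agg in self.results.items() if m == method}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": m, "fraction": f, "mean_auc": a.mean_auc,
             "ci_lo": a.ci_lo, "ci_hi": a.ci_hi, "n_runs": a.n_runs}
            for (m, f), a in sorted(self.results.items())
        ]
        rows.append({"method": "baseline", "fraction": 1.0, "mean_auc": self.baseline.mean_auc,
                     "ci_lo": self.baseline.ci_lo, "ci_hi": self.baseline.ci_hi,
                     "n_runs": self.baseline.n_runs})
        return pd.DataFrame(rows)


def _validate_fraction_grid(fractions: Sequence[float]) -> list[float]:
    out = []
    for f in fractions:
        steps = round(f / 0.1)
        if not (1 <= steps <= 8) or abs(f - steps * 0.1) > 1e-9:
            raise ValidationError(f"fraction {f} not a multiple of 0.10 in [0.10, 0.80]")
        out.append(round(steps * 0.1, 2))
    return out


def size_sweep(
    ranked: RankedScoreList,
    pool: SliceDataset,
    fractions: Sequence[float] = SWEEP_FRACTIONS,
    methods: Sequence[str] = ("uncertainty", "random"),
    plan: SelectionPlan = SelectionPlan(),
    classifier_factory: Callable[[], TrainableProbabilisticClassifier] = reference_classifier,
    config: TrainingConfig = TrainingConfig(),
    eval_dataset: SliceDataset | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    validation: SliceDataset | None = None,
) -> SweepResult:
    """Learning-curve sweep: uncertainty sampling vs the random baseline.

    At each fraction of the full pool, the uncertainty arm draws from the
    ranked list with its extreme tails excluded, the random arm from the
    untouched pool; both subsets have exactly the same cardinality. The
    baseline trains once on the entire pool.
    """
    fractions = _validate_fraction_grid(fractions)
    unknown = set(methods) - {"uncertainty", "random"}
    if unknown:
        raise ValidationError(f"unknown sweep methods {sorted(unknown)}")
    pool_ids = ranked.sample_ids
    pool_size = len(pool_ids)
    retained = exclude_extremes(ranked, plan.exclude_top, plan.exclude_bottom)
    results: dict[tuple[str, float], AggregateResult] = {}
    for i, f in enumerate(fractions):
        arm_ids: dict[str, list[str]] = {}
        if "uncertainty" in methods:
            arm_ids["uncertainty"] = sample_budget(retained, pool_size, f, seed=base_seed + 1000 + i)
        if "random" in methods:
            arm_ids["random"] = random_baseline(pool_ids, f, seed=base_seed + 2000 + i)
        if len(arm_ids) == 2 and len(arm_ids["uncertainty"]) != len(arm_ids["random"]):
            raise ValidationError("sweep arms drew different subset sizes; comparison would be unfair")
        expected = proportion_to_count(f, pool_size)
        for method, ids in arm_ids.items():
            assert len(ids) == expected
            results[(method, f)] = run_experiment(pool, ids, classifier_factory, config, eval_dataset,
                                                  n_runs=n_runs, base_seed=base_seed,
                                                  validation=validation)
    baseline = run_experiment(pool, pool_ids, classifier_factory, config, eval_dataset,
                              n_runs=n_runs, base_seed=base_seed, validation=validation)
    return SweepResult(results, baseline)


def write_sweep_results(sweep: SweepResult, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    df = sweep.to_frame()
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(df.to_dict(orient="records"), indent=2))
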