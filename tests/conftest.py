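"""Shared fixtures: phantom cohorts, planted slice tasks, trained committees.

Everything is generated programmatically at test time from fixed seeds;
session scope keeps the committee trainings (the only non-trivial cost)
shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import qbcal as q

#: seeds used for the repeated planted-structure replicates
REPLICATE_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 phantom patients (2 HGG, 1 LGG) with at least 12 tumor planes each."""
    spec = q.PhantomSpec(n_hgg=2, n_lgg=1, shape=(24, 24, 16), min_tumor_planes=12, seed=11)
    return q.make_phantom_cohort(spec)


@pytest.fixture(scope="session")
def small_task():
    """A 120-sample planted task used where training speed matters."""
    return q.make_slice_task(q.SliceTaskSpec(n=120, seed=7))


@pytest.fixture(scope="session")
def separable_task():
    """Widely separated classes: the sanity case every classifier must ace."""
    return q.make_slice_task(q.SliceTaskSpec(n=200, class_sep=5.0,
                                             outlier_frac=0.0, duplicate_frac=0.0, seed=3))


def _rank_one_replicate(seed: int):
    task = q.make_slice_task(q.SliceTaskSpec(n=400, seed=seed))
    train = task.split_subset("train")
    seed_ids = q.random_baseline(train.sample_ids, 0.30, seed=seed)
    committee = q.build_committee(train.subset(seed_ids), config=q.TrainingConfig(seed=seed))
    ranked = q.score_dataset(q.predict_profiles(committee, train.without_labels()))
    return task, train, ranked


@pytest.fixture(scope="session")
def planted_replicates():
    """(task, train pool, ranked list) for each replicate seed; committee trained once."""
    return {seed: _rank_one_replicate(seed) for seed in REPLICATE_SEEDS}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def make_ranked(scores_by_id: dict[str, float]) -> q.RankedScoreList:
    """Build a RankedScoreList directly from id -> score (entropy only, kl 0)."""
    records = [q.UncertaintyRecord(sid, s, 0.0, s) for sid, s in scores_by_id.items()]
    records.sort(key=lambda r: (-r.score, r.sample_id))
    return q.RankedScoreList(tuple(records))
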