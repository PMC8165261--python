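"""Entropy, pairwise KL disagreement and the ranked uncertainty list."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qbcal as q
from qbcal.errors import ValidationError

LN2 = math.log(2.0)


def random_profiles(rng, n, m=3, c=2):
    """Valid random committee profiles via Dirichlet draws."""
    return [q.CommitteeProfile(f"s{i:03d}", rng.dirichlet(np.ones(c), size=m)) for i in range(n)]


class TestEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.5, 0.5], LN2),
            ([1.0, 0.0], 0.0),
            # independently hand-computed: -(0.8 ln 0.8 + 0.2 ln 0.2)
            ([0.8, 0.2], 0.5004024235381879),
            ([0.25, 0.25, 0.25, 0.25], math.log(4.0)),
        ],
    )
    def test_closed_forms(self, p, expected):
        assert q.entropy(p) == pytest.approx(expected, abs=1e-9)

    def test_invalid_entry_names_offending_index(self):
        with pytest.raises(ValidationError, match=r"p\[1\]"):
            q.entropy([0.5, -0.2, 0.7])

    def test_sum_violation_rejected(self):
        with pytest.raises(ValidationError, match="sums to"):
            q.entropy([0.6, 0.6])

    @pytest.mark.parametrize("c", [2, 3, 4])
    def test_uniform_maximizes_and_degenerate_vanishes(self, c, rng):
        uniform = np.full(c, 1.0 / c)
        h_max = q.entropy(uniform)
        assert h_max == pytest.approx(math.log(c), abs=1e-12)
        degenerate = np.zeros(c)
        degenerate[0] = 1.0
        assert q.entropy(degenerate) == 0.0
        for _ in range(200):
            p = rng.dirichlet(np.ones(c))
            assert 0.0 <= q.entropy(p) <= h_max + 1e-12


class TestKLDivergence:
    @pytest.mark.parametrize(
        "p, q_, expected",
        [
            ([0.5, 0.5], [0.5, 0.5], 0.0),
            # 0.5 ln 2 + 0.5 ln(2/3), hand-checked
            ([0.5, 0.5], [0.25, 0.75], 0.14384103622589045),
            ([1.0, 0.0], [1.0, 0.0], 0.0),
        ],
    )
    def test_closed_forms(self, p, q_, expected):
        assert q.kl_divergence(p, q_) == pytest.approx(expected, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            q.kl_divergence([0.5, 0.5], [0.2, 0.3, 0.5])

    def test_gibbs_inequality_on_random_pairs(self, rng):
        for _ in range(1000):
            c = int(rng.integers(2, 5))
            p, q_ = rng.dirichlet(np.ones(c)), rng.dirichlet(np.ones(c))
            assert q.kl_divergence(p, q_) >= 0.0

    def test_zero_iff_equal(self, rng):
        p = rng.dirichlet(np.ones(3))
        assert q.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-9)
        q_ = rng.dirichlet(np.ones(3))
        if not np.allclose(p, q_, atol=1e-9):
            assert q.kl_divergence(p, q_) > 0.0


class TestCommitteeScore:
    def test_unanimous_certain_committee_scores_zero(self):
        profile = q.CommitteeProfile("a", np.array([[1.0, 0.0]] * 3))
        rec = q.committee_score(profile)
        assert rec.entropy_sum == rec.kl_sum == rec.score == 0.0

    def test_unanimous_uniform_committee(self):
        profile = q.CommitteeProfile("a", np.full((3, 2), 0.5))
        rec = q.committee_score(profile)
        assert rec.entropy_sum == pytest.approx(3 * LN2, abs=1e-9)
        assert rec.kl_sum == pytest.approx(0.0, abs=1e-9)
        assert rec.score == pytest.approx(3 * LN2, abs=1e-9)

    def test_two_member_mixed_committee(self):
        """Frozen oracle: H(.5,.5)+H(.25,.75) and KL in both directions.

        Hand computation: entropy_sum = ln2 + 0.5623351446 = 1.2554823252;
        kl_sum = 0.1438410362 + 0.1308120089 = 0.2746530722.
        """
        profile = q.CommitteeProfile("a", np.array([[0.5, 0.5], [0.25, 0.75]]))
        rec = q.committee_score(profile)
        assert rec.entropy_sum == pytest.approx(1.2554823251787535, abs=1e-9)
        assert rec.kl_sum == pytest.approx(0.2746530721670274, abs=1e-9)
        assert rec.score == pytest.approx(rec.entropy_sum + rec.kl_sum, abs=0.0)

    def test_single_member_rejected(self):
        with pytest.raises(ValidationError, match="< 2"):
            q.committee_score(q.CommitteeProfile("a", np.array([[0.5, 0.5]])))

    def test_kl_sum_invariant_under_member_permutation(self, rng):
        for _ in range(25):
            members = rng.dirichlet(np.ones(3), size=4)
            base = q.committee_score(q.CommitteeProfile("a", members))
            perm = rng.permutation(4)
            permuted = q.committee_score(q.CommitteeProfile("a", members[perm]))
            assert permuted.kl_sum == pytest.approx(base.kl_sum, rel=1e-12)
            assert permuted.score == pytest.approx(base.score, rel=1e-12)


def _score_base2(profile: q.CommitteeProfile) -> float:
    """Independent recomputation of the committee score in bits (log base 2)."""
    total = 0.0
    rows = [np.clip(r, 1e-12, 1.0) for r in profile.members]
    for r in rows:
        total += float(-(np.where(r > 0, r * np.log2(r), 0.0)).sum())
    for a, b in itertools.permutations(range(len(rows)), 2):
        total += float((rows[a] * np.log2(rows[a] / rows[b])).sum())
    return total


class TestScoreDataset:
    def test_sorts_descending(self):
        profiles = [
            q.CommitteeProfile("x", np.array([[0.9, 0.1], [0.9, 0.1]])),
            q.CommitteeProfile("y", np.array([[0.5, 0.5], [0.5, 0.5]])),
            q.CommitteeProfile("z", np.array([[0.7, 0.3], [0.7, 0.3]])),
        ]
        ranked = q.score_dataset(profiles)
        scores = [r.score for r in ranked]
        assert scores == sorted(scores, reverse=True)
        assert ranked.sample_ids == ["y", "z", "x"]

    def test_ties_broken_by_ascending_id(self):
        same = np.array([[0.6, 0.4], [0.6, 0.4]])
        ranked = q.score_dataset([q.CommitteeProfile("b", same), q.CommitteeProfile("a", same)])
        assert ranked.sample_ids == ["a", "b"]

    def test_duplicate_ids_rejected(self):
        p = np.array([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValidationError, match="duplicate"):
            q.score_dataset([q.CommitteeProfile("a", p), q.CommitteeProfile("a", p)])

    def test_matches_brute_force_recomputation(self, rng):
        """Ranking equals an independent per-sample recomputation and re-sort."""
        profiles = random_profiles(rng, 100, m=3, c=3)
        ranked = q.score_dataset(profiles)

        def brute(profile):
            e = sum(float(-(r * np.log(r)).sum()) for r in profile.members)
            k = sum(
                float((profile.members[a] * np.log(profile.members[a] / profile.members[b])).sum())
                for a, b in itertools.permutations(range(profile.n_members), 2)
            )
            return e + k

        expected = sorted(((brute(p), p.sample_id) for p in profiles), key=lambda t: (-t[0], t[1]))
        assert ranked.sample_ids == [sid for _, sid in expected]
        for rec, (score, _) in zip(ranked, expected):
            assert rec.score == pytest.approx(score, rel=1e-9)

    def test_ranking_invariant_to_log_base(self, rng):
        """Switching every log to base 2 rescales scores but never reorders them."""
        profiles = random_profiles(rng, 60, m=3, c=2)
        ranked = q.score_dataset(profiles)
        base2 = sorted(((_score_base2(p), p.sample_id) for p in profiles), key=lambda t: (-t[0], t[1]))
        assert ranked.sample_ids == [sid for _, sid in base2]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=5))
def test_entropy_of_normalized_weights_bounded(weights):
    p = np.array(weights) / np.sum(weights)
    h = q.entropy(p)
    assert 0.0 <= h <= math.log(len(weights)) + 1e-9


class TestSerialization:
    def test_scores_tsv_round_trip(self, tmp_path, rng):
        ranked = q.score_dataset(random_profiles(rng, 20))
        path = tmp_path / "scores.tsv"
        q.write_scores_tsv(ranked, path)
        back = q.read_scores_tsv(path)
        assert back.sample_ids == ranked.sample_ids
        np.testing.assert_allclose([r.score for r in back], [r.score for r in ranked], rtol=1e-12)

    def test_profiles_hdf5_round_trip(self, tmp_path, rng):
        profiles = random_profiles(rng, 15, m=3, c=2)
        path = tmp_path / "profiles.h5"
        q.write_profiles_hdf5(profiles, path)
        back = q.read_profiles_hdf5(path)
        assert [p.sample_id for p in back] == [p.sample_id for p in profiles]
        for a, b in zip(back, profiles):
            np.testing.assert_allclose(a.members, b.members)

    def test_profiles_long_frame_round_trip(self, rng):
        from qbcal.scoring import profiles_from_long_frame, profiles_to_long_frame

        profiles = random_profiles(rng, 8, m=2, c=3)
        back = profiles_from_long_frame(profiles_to_long_frame(profiles))
        for a, b in zip(back, sorted(profiles, key=lambda p: p.sample_id)):
            assert a.sample_id == b.sample_id
            np.testing.assert_allclose(a.members, b.members)
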