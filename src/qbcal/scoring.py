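"""Committee-disagreement uncertainty scoring.

The informativeness of an unlabeled sample is measured from the class
probabilities assigned to it by a committee of M classifiers that were
trained on the same labeled seed set under different hyperparameters.
Each sample's score is

    score = sum_m H(p_m)  +  sum_{m != m'} D(p_m || p_m')

where ``H`` is Shannon entropy and ``D`` the Kullback-Leibler divergence.
Summing KL over all ordered member pairs symmetrizes the disagreement
term. All quantities are in nats (natural logarithm); the downstream use
is ranking, which is invariant to the log base.

Samples are ranked by descending score; ties are broken by ascending
``sample_id`` so that selection is fully deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ValidationError

#: probabilities are clipped to [EPS, 1] before any log or division
EPS = 1e-12
#: tolerance on sum(p) == 1
SUM_TOL = 1e-6


def _as_distribution(p: Sequence[float] | np.ndarray, name: str = "p") -> np.ndarray:
    """Validate and return a class-probability vector as a float array.

    Raises :class:`ValidationError` naming the offending index for a
    negative or >1 entry, or reporting the total if it is off by more
    than ``SUM_TOL``.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError(f"{name}: expected a 1-d vector of >= 2 class probabilities, got shape {arr.shape}")
    bad = np.where((arr < 0.0) | (arr > 1.0))[0]
    if bad.size:
        i = int(bad[0])
        raise ValidationError(f"{name}[{i}] = {arr[i]!r} is outside [0, 1]")
    total = float(arr.sum())
    if abs(total - 1.0) > SUM_TOL:
        raise ValidationError(f"{name} sums to {total!r}, expected 1 within {SUM_TOL}")
    return arr


def entropy(p: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy of a probability vector, in nats.

    ``0 * log 0`` is taken as 0, so degenerate distributions have entropy
    exactly 0. The result lies in ``[0, log C]`` for C classes.
    """
    arr = _as_distribution(p, "p")
    terms = np.where(arr > 0.0, arr * np.log(np.clip(arr, EPS, 1.0)), 0.0)
    return float(max(-terms.sum(), 0.0))


def kl_divergence(p: Sequence[float] | np.ndarray, q: Sequence[float] | np.ndarray) -> float:
    """Kullback-Leibler divergence D(p || q) in nats.

    ``q`` entries are clipped to ``>= EPS`` before the division so that
    saturated classifier outputs (exact zeros) yield large but finite
    divergences; ``p`` entries equal to zero contribute 0.
    """
    pa = _as_distribution(p, "p")
    qa = _as_distribution(q, "q")
    if pa.size != qa.size:
        raise ValidationError(f"dimension mismatch: p has {pa.size} classes, q has {qa.size}")
    qc = np.clip(qa, EPS, 1.0)
    terms = np.where(pa > 0.0, pa * (np.log(np.clip(pa, EPS, 1.0)) - np.log(qc)), 0.0)
    # clipping can introduce O(EPS) negative drift; KL is non-negative by Gibbs
    return float(max(terms.sum(), 0.0))


@dataclass(frozen=True)
class CommitteeProfile:
    """Per-sample class-probability vectors from the M committee members.

    ``members`` is an (M, C) array: row m is member m's predictive
    distribution for this sample.
    """

    sample_id: str
    members: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.members, dtype=float)
        if arr.ndim != 2:
            raise ValidationError(f"profile {self.sample_id!r}: members must be (M, C), got shape {arr.shape}")
        object.__setattr__(self, "members", arr)

    @property
    def n_members(self) -> int:
        return self.members.shape[0]

    @property
    def n_classes(self) -> int:
        return self.members.shape[1]


@dataclass(frozen=True)
class UncertaintyRecord:
    """Entropy, pairwise-KL disagreement and their sum for one sample (nats)."""

    sample_id: str
    entropy_sum: float
    kl_sum: float
    score: float


@dataclass(frozen=True)
class RankedScoreList:
    """Uncertainty records in descending-score order (ties: ascending id)."""

    records: tuple[UncertaintyRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("RankedScoreList: duplicate sample_ids")
        for a, b in zip(self.records, self.records[1:]):
            if a.score < b.score or (a.score == b.score and a.sample_id > b.sample_id):
                raise ValidationError("RankedScoreList: records not in ranked order")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "entropy_sum": [r.entropy_sum for r in self.records],
                "kl_sum": [r.kl_sum for r in self.records],
                "score": [r.score for r in self.records],
                "rank": np.arange(1, len(self.records) + 1),
            }
        )


def committee_score(profile: CommitteeProfile) -> UncertaintyRecord:
    """Score one sample from its committee probability profile.

    ``entropy_sum`` adds each member's predictive entropy; ``kl_sum`` adds
    the KL divergence over every ordered pair of distinct members. A
    unanimous, fully confident committee scores exactly 0.
    """
    if profile.n_members < 2:
        raise ValidationError(
            f"profile {profile.sample_id!r}: committee size {profile.n_members} < 2, pairwise disagreement undefined"
        )
    rows = [profile.members[m] for m in range(profile.n_members)]
    e_sum = sum(entropy(r) for r in rows)
    k_sum = sum(kl_divergence(rows[a], rows[b]) for a, b in itertools.permutations(range(len(rows)), 2))
    return UncertaintyRecord(profile.sample_id, float(e_sum), float(k_sum), float(e_sum + k_sum))


def score_dataset(profiles: Iterable[CommitteeProfile]) -> RankedScoreList:
    """Score every profile and return the descending-sorted uncertainty list."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("score_dataset: no profiles given")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"score_dataset: duplicate sample_ids {dup}")
    shapes = {(p.n_members, p.n_classes) for p in profiles}
    if len(shapes) != 1:
        raise ValidationError(f"score_dataset: inconsistent committee shapes {sorted(shapes)}")
    records = [committee_score(p) for p in profiles]
    records.sort(key=lambda r: (-r.score, r.sample_id))
    return RankedScoreList(tuple(records))


# ---------------------------------------------------------------------------
# serialization


def write_scores_tsv(ranked: RankedScoreList, path: str | Path) -> None:
    """Write the ranked list as TSV (sample_id, entropy_sum, kl_sum, score, rank)."""
    ranked.to_frame().to_csv(path, sep="\t", index=False)


def read_scores_tsv(path: str | Path) -> RankedScoreList:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    records = [
        UncertaintyRecord(str(r.sample_id), float(r.entropy_sum), float(r.kl_sum), float(r.score))
        for r in df.itertuples()
    ]
    return RankedScoreList(tuple(records))


def write_profiles_hdf5(profiles: Sequence[CommitteeProfile], path: str | Path) -> None:
    """Write profiles as HDF5 datasets ``sample_ids`` (N) and ``probs`` (M, N, C)."""
    profiles = list(profiles)
    probs = np.stack([p.members for p in profiles], axis=1)  # (M, N, C)
    with h5py.File(path, "w") as f:
        f.create_dataset("sample_ids", data=np.array([p.sample_id for p in profiles], dtype=object),
                         dtype=h5py.string_dtype())
        f.create_dataset("probs", data=probs)


def read_profiles_hdf5(path: str | Path) -> list[CommitteeProfile]:
    with h5py.File(path, "r") as f:
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][...]]
        probs = np.asarray(f["probs"][...], dtype=float)
    return [CommitteeProfile(sid, probs[:, i, :]) for i, sid in enumerate(ids)]


def profiles_to_long_frame(profiles: Sequence[CommitteeProfile]) -> pd.DataFrame:
    """Long TSV-friendly form: one row per (sample, member, class)."""
    rows = []
    for p in profiles:
        for m in range(p.n_members):
            for c in range(p.n_classes):
                rows.append((p.sample_id, m, c, float(p.members[m, c])))
    return pd.DataFrame(rows, columns=["sample_id", "member_index", "class_index", "prob"])


def profiles_from_long_frame(df: pd.DataFrame) -> list[CommitteeProfile]:
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        m = int(grp["member_index"].max()) + 1
        c = int(grp["class_index"].max()) + 1
        arr = np.zeros((m, c))
        arr[grp["member_index"].to_numpy(), grp["class_index"].to_numpy()] = grp["prob"].to_numpy()
        out.append(CommitteeProfile(str(sid), arr))
    return out
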