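"""Distance-based re-identification of individuals and MZ co-twins.

A target profile (e.g. a subject's retest vector) is matched against a
candidate pool by Euclidean distance over the z-scored measures; the target
is "identified" when its true candidate is the strict nearest neighbour.
Self-identification keeps the target's own original profile in the pool;
twin identification removes only the target itself.  Significance comes from
shuffling the target-to-candidate truth map.

Ranks use strict competition ranking: a distance tie with the true match
takes the worst tied rank and therefore counts as a failure for accuracy —
conservative and reproducible (exact ties have measure zero for continuous
data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .preprocess import zscore
from .synthetic_data import Cohort


class FingerprintError(ValueError):
    pass


def euclidean_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Plain L2 distance between two equal-length profile vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise FingerprintError(f"profile length mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((p - q) ** 2)))


@dataclass
class IdentificationResult:
    """Outcome of one identification run (optionally with a permutation null)."""

    n_targets: int
    n_correct: int
    accuracy: float
    ranks: pd.Series  # per-target rank of the true candidate (1 = identified)
    median_rank: float
    mean_rank: float
    n_candidates: int
    null_max_correct: np.ndarray | None = None
    null_n_correct: np.ndarray | None = None
    p_value: float | None = None
    p_report: str | None = None

    def summary(self) -> dict:
        out = {
            "n_targets": self.n_targets,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "median_rank": self.median_rank,
            "mean_rank": self.mean_rank,
            "n_candidates": self.n_candidates,
        }
        if self.p_value is not None:
            out["p_value"] = self.p_value
            out["p_report"] = self.p_report
        return out

    def to_tsv(self, path) -> None:
        frame = self.ranks.rename("rank").to_frame()
        frame.index.name = "target_id"
        frame.to_csv(path, sep="\t")


def _distance_and_mask(targets: pd.DataFrame, candidates: pd.DataFrame,
                       exclude_self: bool) -> tuple[np.ndarray, np.ndarray]:
    dist = cdist(targets.to_numpy(float), candidates.to_numpy(float))
    allowed = np.ones_like(dist, dtype=bool)
    if exclude_self:
        cand_pos = {cid: j for j, cid in enumerate(candidates.index)}
        for i, tid in enumerate(targets.index):
            j = cand_pos.get(tid)
            if j is not None:
                allowed[i, j] = False
    return dist, allowed


def identify(targets: pd.DataFrame, candidates: pd.DataFrame,
             truth: dict, exclude_self: bool = False) -> IdentificationResult:
    """Rank each target's true candidate by ascending Euclidean distance.

    ``truth`` maps target id -> candidate id.  Rank is the worst competition
    rank among allowed candidates (``#{d < d_true} + #{d == d_true}``), so a
    tie at the minimum is a failure.  Accuracy is the fraction of rank-1
    targets.
    """
    missing = set(truth.values()) - set(candidates.index)
    if missing:
        raise FingerprintError(f"truth candidates absent from pool: {sorted(missing)}")
    if set(targets.index) - set(truth):
        raise FingerprintError("every target needs a truth mapping")
    dist, allowed = _distance_and_mask(targets, candidates, exclude_self)
    cand_pos = {cid: j for j, cid in enumerate(candidates.index)}
    ranks = np.empty(len(targets), dtype=int)
    for i, tid in enumerate(targets.index):
        j = cand_pos[truth[tid]]
        if not allowed[i, j]:
            raise FingerprintError(f"true candidate for {tid} is excluded from its pool")
        d = dist[i, allowed[i]]
        d_true = dist[i, j]
        ranks[i] = int((d < d_true).sum() + (d == d_true).sum())
    n_correct = int((ranks == 1).sum())
    ranks_series = pd.Series(ranks, index=targets.index)
    return IdentificationResult(
        n_targets=len(targets),
        n_correct=n_correct,
        accuracy=n_correct / len(targets),
        ranks=ranks_series,
        median_rank=float(np.median(ranks)),
        mean_rank=float(np.mean(ranks)),
        n_candidates=int(allowed[0].sum()) if len(targets) else 0,
    )


def permutation_null(targets: pd.DataFrame, candidates: pd.DataFrame,
                     truth: dict, exclude_self: bool = False,
                     n_perm: int = 1000,
                     seed: int | np.random.Generator = 0) -> IdentificationResult:
    """Identification with a shuffled-identity permutation null.

    The truth map's candidate ids are permuted across targets ``n_perm``
    times; ``p = #{null n_correct >= observed} / n_perm``, reported as
    ``"< 1/n_perm"`` (never exactly 0) when no permutation reaches the
    observed count.
    """
    if n_perm < 1:
        raise FingerprintError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    result = identify(targets, candidates, truth, exclude_self=exclude_self)

    dist, allowed = _distance_and_mask(targets, candidates, exclude_self)
    # per target: position of the strict unique minimum (or -1 if tied)
    masked = np.where(allowed, dist, np.inf)
    order = np.argsort(masked, axis=1)
    best = order[:, 0]
    second_val = np.take_along_axis(masked, order[:, 1:2], axis=1).ravel() \
        if masked.shape[1] > 1 else np.full(len(targets), np.inf)
    best_val = np.take_along_axis(masked, order[:, 0:1], axis=1).ravel()
    strict_best = np.where(best_val < second_val, best, -1)

    cand_pos = {cid: j for j, cid in enumerate(candidates.index)}
    truth_pos = np.array([cand_pos[truth[tid]] for tid in targets.index])
    null = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        permuted = truth_pos[rng.permutation(len(truth_pos))]
        null[k] = int((permuted == strict_best).sum())

    count = int((null >= result.n_correct).sum())
    if count == 0:
        result.p_value = 1.0 / n_perm
        result.p_report = f"< {1.0 / n_perm:g}"
    else:
        result.p_value = count / n_perm
        result.p_report = f"{count / n_perm:g}"
    result.null_n_correct = null
    result.null_max_correct = null  # per-permutation best-count distribution
    return result


# ---------------------------------------------------------------------------
# cohort-level entry points

def identify_self(cohort: Cohort, n_perm: int | None = None,
                  seed: int = 0) -> IdentificationResult:
    """Re-identify retest subjects against every subject's original profile.

    The target's own original row stays in the candidate pool, matching the
    within-dataset re-identification design.
    """
    if cohort.retest is None or cohort.retest.empty:
        raise FingerprintError("cohort has no retest data for self-identification")
    z = zscore(cohort.phenotypes)
    mu, sd = cohort.phenotypes.mean(), cohort.phenotypes.std(ddof=0)
    z_retest = (cohort.retest - mu) / sd  # same scaling as the originals
    truth = {sid: sid for sid in z_retest.index}
    if n_perm:
        return permutation_null(z_retest, z, truth, n_perm=n_perm, seed=seed)
    return identify(z_retest, z, truth)


def identify_twin(cohort: Cohort, n_perm: int | None = None,
                  seed: int = 0) -> IdentificationResult:
    """Identify each MZ subject's co-twin among all other subjects."""
    z = zscore(cohort.phenotypes)
    pairs = cohort.twin_pairs("MZ")
    if not pairs:
        raise FingerprintError("cohort has no MZ pairs")
    truth: dict[str, str] = {}
    for t1, t2 in pairs:
        truth[t1] = t2
        truth[t2] = t1
    targets = z.loc[list(truth)]
    if n_perm:
        return permutation_null(targets, z, truth, exclude_self=True,
                                n_perm=n_perm, seed=seed)
    return identify(targets, z, truth, exclude_self=True)
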