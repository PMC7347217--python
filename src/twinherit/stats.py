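"""Cross-method agreement and the task-vs-questionnaire domain test.

Agreement between heritability profiles is summarized with a Spearman
rank-correlation matrix.  The domain test asks whether the mean estimate
differs between the task and questionnaire domains: the statistic is the
absolute difference of domain means and the null is built by randomly
reassigning measures to domains while preserving group sizes (a Monte Carlo
sample of the full label space; 15-of-37 already has ~9.4e9 assignments).
"More extreme" uses ``>=``, two-sided via the absolute statistic, and the
reported p-value is never exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


def spearman_matrix(profiles: dict[str, np.ndarray]) -> pd.DataFrame:
    """Symmetric Spearman rank-correlation matrix over named profiles.

    Average-rank tie handling; entries involving a constant profile are NaN
    (undefined) and the diagonal is 1 where defined.
    """
    names = list(profiles)
    if len(names) < 2:
        raise StatsError("need at least two profiles")
    lengths = {len(np.asarray(profiles[n]).ravel()) for n in names}
    if len(lengths) != 1:
        raise StatsError("profiles must have equal length")
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        va = np.asarray(profiles[a], dtype=float).ravel()
        const_a = np.unique(va).size < 2
        for b in names[i:]:
            vb = np.asarray(profiles[b], dtype=float).ravel()
            if const_a or np.unique(vb).size < 2:
                continue
            rho = float(sps.spearmanr(va, vb).statistic)
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def n_label_assignments(n_total: int, n_task: int) -> int:
    """Size of the domain-label space: C(n_total, n_task)."""
    return math.comb(n_total, n_task)


@dataclass
class DomainTestResult:
    observed_stat: float
    p_value: float
    p_report: str
    n_perm: int
    n_total_assignments: int
    mean_task: float
    mean_questionnaire: float
    exhaustive: bool = False
    null_stats: np.ndarray = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "mean_task": self.mean_task,
            "mean_questionnaire": self.mean_questionnaire,
            "p_value": self.p_value,
            "p_report": self.p_report,
            "n_perm": self.n_perm,
            "n_total_assignments": self.n_total_assignments,
            "exhaustive": self.exhaustive,
        }


def _domain_arrays(estimates, domain_labels):
    est = np.asarray(estimates, dtype=float).ravel()
    labels = np.asarray(domain_labels).ravel()
    if est.size != labels.size:
        raise StatsError("estimates and domain labels must have equal length")
    uniq = set(labels.tolist())
    if uniq != {"task", "questionnaire"}:
        missing = {"task", "questionnaire"} - uniq
        raise StatsError(f"both domains must be non-empty; missing {sorted(missing)}")
    return est, labels == "task"


def domain_permutation_test(estimates, domain_labels, n_perm: int = 100_000,
                            seed: int | np.random.Generator = 0
                            ) -> DomainTestResult:
    """Monte Carlo permutation test of the domain mean difference.

    ``p = #{null >= observed} / n_perm`` with the identity assignment always
    at least as extreme as itself in the exhaustive space, so the reported
    value is floored at ``1/n_perm`` rather than 0.
    """
    est, is_task = _domain_arrays(estimates, domain_labels)
    n, n_task = est.size, int(is_task.sum())
    observed = abs(est[is_task].mean() - est[~is_task].mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    total = est.sum()
    null = np.empty(n_perm)
    # vectorized in chunks: permute, take the first n_task as "task"
    chunk = max(1, min(n_perm, 20_000))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(est, (size, 1)), axis=1)
        task_sum = perm[:, :n_task].sum(axis=1)
        null[done:done + size] = np.abs(task_sum / n_task
                                        - (total - task_sum) / (n - n_task))
        done += size
    count = int((null >= observed).sum())
    if count == 0:
        p, report = 1.0 / n_perm, f"< {1.0 / n_perm:g}"
    else:
        p, report = count / n_perm, f"{count / n_perm:g}"
    return DomainTestResult(
        observed_stat=float(observed), p_value=p, p_report=report, n_perm=n_perm,
        n_total_assignments=n_label_assignments(n, n_task),
        mean_task=float(est[is_task].mean()),
        mean_questionnaire=float(est[~is_task].mean()),
        null_stats=null,
    )


def exhaustive_domain_test(estimates, domain_labels) -> DomainTestResult:
    """Exact version enumerating every same-size domain assignment."""
    est, is_task = _domain_arrays(estimates, domain_labels)
    n, n_task = est.size, int(is_task.sum())
    total_assign = n_label_assignments(n, n_task)
    if total_assign > 2_000_000:
        raise StatsError(f"label space too large to enumerate ({total_assign})")
    observed = abs(est[is_task].mean() - est[~is_task].mean())
    total = est.sum()
    stats = np.empty(total_assign)
    for i, idx in enumerate(combinations(range(n), n_task)):
        s = est[list(idx)].sum()
        stats[i] = abs(s / n_task - (total - s) / (n - n_task))
    count = int((stats >= observed - 1e-12).sum())
    return DomainTestResult(
        observed_stat=float(observed),
        p_value=count / total_assign,
        p_report=f"{count / total_assign:g}",
        n_perm=total_assign,
        n_total_assignments=total_assign,
        mean_task=float(est[is_task].mean()),
        mean_questionnaire=float(est[~is_task].mean()),
        exhaustive=True,
        null_stats=stats,
    )
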