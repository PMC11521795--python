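"""Pairwise spike synchrony at maze intersections.

For each pair of simultaneously recorded units, coincidences — unordered
cross-unit spike pairs within +-20 ms (sliding window, boundary inclusive) —
are counted inside 500 ms intersection trials.  Significance comes from a
trial-permutation null: trial i of unit a is re-paired with trial pi(i) of
unit b (spike times re-expressed relative to each trial's window start so
window offsets cancel), and the one-sided add-one p-value

    p = (1 + #{permuted count >= observed}) / (n_perm + 1)

is valid even though the identity permutation may be drawn.  Population
comparisons use one-sided Kolmogorov-Smirnov tests on the p-value
distributions (uniformity per group; two-sample between regions), jointly
Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coding import bh_adjust

logger = logging.getLogger(__name__)

COINCIDENCE_DELTA = 0.020  # s
N_PERMUTATIONS = 50_000


@dataclass
class SyncResult:
    pair: tuple
    intersection: str
    n_trials: int
    observed: int
    p_value: float
    n_perm: int


def count_coincidences(
    train_a: np.ndarray,
    train_b: np.ndarray,
    trials: list[tuple[float, float]],
    delta: float = COINCIDENCE_DELTA,
) -> int:
    """Number of cross-unit spike pairs within ``delta`` inside each trial.

    Pairs never straddle trials; boundary-inclusive (|s - t| <= delta).
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    total = 0
    for s, e in trials:
        a_tr = a[(a >= s) & (a < e)]
        b_tr = b[(b >= s) & (b < e)]
        if a_tr.size == 0 or b_tr.size == 0:
            continue
        hi = np.searchsorted(b_tr, a_tr + delta, side="right")
        lo = np.searchsorted(b_tr, a_tr - delta, side="left")
        total += int(np.sum(hi - lo))
    return total


def _aligned_trial_spikes(
    train: np.ndarray, trials: list[tuple[float, float]]
) -> list[np.ndarray]:
    t = np.asarray(train, dtype=float)
    return [t[(t >= s) & (t < e)] - s for s, e in trials]


def _coincidence_matrix(
    a_trials: list[np.ndarray], b_trials: list[np.ndarray], delta: float
) -> np.ndarray:
    """M[i, j] = coincidences between a's trial i and b's trial j, aligned."""
    n = len(a_trials)
    M = np.zeros((n, n), dtype=np.int64)
    for i, ai in enumerate(a_trials):
        if ai.size == 0:
            continue
        for j, bj in enumerate(b_trials):
            if bj.size == 0:
                continue
            hi = np.searchsorted(bj, ai + delta, side="right")
            lo = np.searchsorted(bj, ai - delta, side="left")
            M[i, j] = int(np.sum(hi - lo))
    return M


def permutation_pvalue(
    train_a: np.ndarray,
    train_b: np.ndarray,
    trials: list[tuple[float, float]],
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
    delta: float = COINCIDENCE_DELTA,
    intersection: str = "",
    pair: tuple = (0, 1),
) -> SyncResult | None:
    """One-sided trial-permutation p-value for excess coincidences.

    Returns None (with a log entry) when fewer than 2 trials are available.
    """
    if len(trials) < 2:
        logger.info("pair %s: fewer than 2 trials, synchrony test skipped", pair)
        return None
    rng = np.random.default_rng(seed)
    a_trials = _aligned_trial_spikes(train_a, trials)
    b_trials = _aligned_trial_spikes(train_b, trials)
    M = _coincidence_matrix(a_trials, b_trials, delta)
    observed = int(np.trace(M))
    n = len(trials)
    rows = np.arange(n)
    # vectorized batch of uniform random permutations
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    null_counts = M[rows[None, :], perms].sum(axis=1)
    p = (1.0 + np.sum(null_counts >= observed)) / (n_perm + 1.0)
    return SyncResult(
        pair=pair,
        intersection=intersection,
        n_trials=n,
        observed=observed,
        p_value=float(p),
        n_perm=n_perm,
    )


def pvalue_cdf_tests(
    groups: dict[tuple, np.ndarray],
    two_sample_keys: list[tuple[tuple, tuple]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """KS tests on grouped synchrony p-values, jointly BH-adjusted.

    Per group: one-sided KS of uniformity with the alternative that the
    empirical CDF lies *above* the diagonal (an excess of small p-values,
    i.e. synchrony).  Per pair in ``two_sample_keys``: one-sided two-sample
    KS with the alternative that the first group's CDF lies above the
    second's.  All resulting p-values enter one BH family.
    """
    rows = []
    for key, pvals in groups.items():
        pvals = np.asarray(pvals, dtype=float)
        if pvals.size == 0:
            raise ValueError(f"group {key!r} is empty")
        if pvals.size < 5:
            logger.warning("group %r has %d p-values (< 5)", key, pvals.size)
        stat = stats.kstest(pvals, "uniform", alternative="greater")
        rows.append({"test": "uniformity", "group": key, "other": None,
                     "statistic": float(stat.statistic), "p": float(stat.pvalue)})
    for k1, k2 in two_sample_keys or []:
        stat = stats.ks_2samp(groups[k1], groups[k2], alternative="greater")
        rows.append({"test": "two_sample", "group": k1, "other": k2,
                     "statistic": float(stat.statistic), "p": float(stat.pvalue)})
    df = pd.DataFrame(rows)
    adjusted, flags = bh_adjust(df["p"].to_numpy(), alpha=alpha)
    df["p_adj"] = adjusted
    df["significant"] = flags
    return df
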