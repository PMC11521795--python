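"""Cross-validated decoding of the traveled path from fitted point-process models.

Per eligible session, per-condition Poisson or Hawkes models are estimated
on 2/3 of each path's trials; each held-out trial is assigned the condition
whose fitted intensity minimizes the trial-restricted least-squares
contrast, summed over units:

    k_hat = argmin_{k'} sum_n C_trial(lambda_hat_{n,k'})

The decoding power is the fraction of held-out trials with ``k_hat == k``;
the chance reference is ``1 / NbPaths`` with NbPaths the number of retained
conditions.  A session is eligible when it has at least two full-path coding
units and at least two distinct paths each traveled at least three times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import UNCLASSIFIED, BehaviorSession, PathTraversal
from .networks import (
    HawkesParams,
    PoissonParams,
    _SharedDesign,
    fit_hawkes_network,
    fit_poisson_network,
    model_contrast,
)

logger = logging.getLogger(__name__)

MIN_TRIALS_PER_CONDITION = 3
MIN_CODING_UNITS = 2
TRAIN_FRACTION = 2.0 / 3.0


@dataclass
class DecodingResult:
    session_id: str
    model: str  # "poisson" | "hawkes"
    true_labels: list[str]
    predicted_labels: list[str]
    contrasts: list[dict[str, float]]
    power: float
    reference: float  # 1 / NbPaths
    n_paths: int
    n_units: int
    mean_rate: float
    extras: dict = field(default_factory=dict)


def session_eligibility(
    traversals: list[PathTraversal],
    coding_table: pd.DataFrame,
) -> tuple[bool, list[str]]:
    """Eligibility rule: >=2 full-path coders and >=2 paths with >=3 trials."""
    reasons: list[str] = []
    fp = coding_table[coding_table["mode"] == "full_path"]
    n_coders = int((fp["coding"] == True).sum())  # noqa: E712  (NaN-safe)
    if n_coders < MIN_CODING_UNITS:
        reasons.append(f"<{MIN_CODING_UNITS} full-path coding units ({n_coders})")
    counts: dict[str, int] = {}
    for tr in traversals:
        if tr.label != UNCLASSIFIED:
            counts[tr.label] = counts.get(tr.label, 0) + 1
    repeated = [k for k, c in counts.items() if c >= MIN_TRIALS_PER_CONDITION]
    if len(repeated) < 2:
        reasons.append(
            f"fewer than 2 distinct paths with >={MIN_TRIALS_PER_CONDITION} trials"
        )
    return not reasons, reasons


def split_trials(
    trials_by_condition: dict[str, list[PathTraversal]],
    fraction: float = TRAIN_FRACTION,
    policy: str = "chronological",
    seed: int = 0,
) -> tuple[dict[str, list[PathTraversal]], dict[str, list[PathTraversal]]]:
    """Per-condition train/test partition; conditions with <3 trials dropped.

    Default policy takes the first ``ceil(fraction * m)`` trials
    chronologically for training; ``policy="random"`` draws a seeded random
    subset of the same size.  Every retained condition keeps >=1 test trial.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: dict[str, list[PathTraversal]] = {}
    test: dict[str, list[PathTraversal]] = {}
    for label, trials in trials_by_condition.items():
        m = len(trials)
        if m < MIN_TRIALS_PER_CONDITION:
            logger.info("condition %r dropped (%d < %d trials)", label, m,
                        MIN_TRIALS_PER_CONDITION)
            continue
        ordered = sorted(trials, key=lambda tr: tr.start)
        n_train = min(math.ceil(fraction * m), m - 1)
        if policy == "chronological":
            idx = np.arange(n_train)
        elif policy == "random":
            idx = np.sort(rng.choice(m, size=n_train, replace=False))
        else:
            raise ValueError(f"unknown split policy {policy!r}")
        mask = np.zeros(m, dtype=bool)
        mask[idx] = True
        train[label] = [t for t, k in zip(ordered, mask) if k]
        test[label] = [t for t, k in zip(ordered, mask) if not k]
    return train, test


def decode_trial(
    models: dict[str, PoissonParams | HawkesParams],
    trains: list[np.ndarray],
    trial_interval: tuple[float, float],
) -> tuple[str, dict[str, float]]:
    """Argmin-contrast condition assignment for one held-out trial.

    The trial contrast of candidate k' is the sum over units of the
    least-squares contrast of that unit's fitted intensity restricted to the
    trial; ties break toward the smallest condition label (logged).
    """
    if not models:
        raise ValueError("no candidate models")
    hawkes = any(isinstance(p, HawkesParams) for p in models.values())
    shared = _SharedDesign(trains, [trial_interval]) if hawkes else None
    contrasts: dict[str, float] = {}
    for label in sorted(models):
        params = models[label]
        c = sum(
            model_contrast(params, trains, n, [trial_interval], shared=shared)
            for n in range(len(trains))
        )
        contrasts[label] = float(c)
    best = min(contrasts.values())
    winners = [k for k in sorted(contrasts) if contrasts[k] == best]
    if len(winners) > 1:
        logger.info("contrast tie among %s; taking %r", winners, winners[0])
    return winners[0], contrasts


def session_decoding_power(
    trains: list[np.ndarray],
    traversals: list[PathTraversal],
    model: str = "hawkes",
    session_id: str = "",
    split_policy: str = "chronological",
    seed: int = 0,
) -> DecodingResult:
    """Fit per-condition models on the train split and decode the test split."""
    if model not in ("poisson", "hawkes"):
        raise ValueError(f"unknown model {model!r}")
    by_label: dict[str, list[PathTraversal]] = {}
    for tr in traversals:
        if tr.label != UNCLASSIFIED:
            by_label.setdefault(tr.label, []).append(tr)
    train, test = split_trials(by_label, policy=split_policy, seed=seed)
    if len(train) < 2:
        raise ValueError("need >=2 retained conditions to decode")
    if not any(test.values()):
        raise ValueError("no test trials")

    models: dict[str, PoissonParams | HawkesParams] = {}
    for label, trials in train.items():
        intervals = [(t.start, t.end) for t in trials]
        if model == "poisson":
            models[label] = fit_poisson_network(trains, intervals)
        else:
            models[label] = fit_hawkes_network(trains, intervals)

    true_labels, predicted, contrasts = [], [], []
    for label in sorted(test):
        for trial in test[label]:
            k_hat, c = decode_trial(models, trains, (trial.start, trial.end))
            true_labels.append(label)
            predicted.append(k_hat)
            contrasts.append(c)
    hits = sum(1 for t, p in zip(true_labels, predicted) if t == p)
    power = hits / len(true_labels)

    all_train_ivs = [(t.start, t.end) for ts in train.values() for t in ts] + [
        (t.start, t.end) for ts in test.values() for t in ts
    ]
    total_dur = sum(e - s for s, e in all_train_ivs)
    mean_rate = float(
        np.mean(
            [
                sum(
                    np.searchsorted(tr, e) - np.searchsorted(tr, s)
                    for s, e in all_train_ivs
                )
                / total_dur
                for tr in trains
            ]
        )
    )
    return DecodingResult(
        session_id=session_id,
        model=model,
        true_labels=true_labels,
        predicted_labels=predicted,
        contrasts=contrasts,
        power=power,
        reference=1.0 / len(train),
        n_paths=len(train),
        n_units=len(trains),
        mean_rate=mean_rate,
    )


def decoding_table(results: list[DecodingResult], session_meta: dict | None = None) -> pd.DataFrame:
    """Tidy decoding.csv rows, the input of downstream group-level regressions."""
    meta = session_meta or {}
    rows = []
    for r in results:
        extra = meta.get(r.session_id, {})
        rows.append(
            {
                "session": r.session_id,
                "model": r.model,
                "power": r.power,
                "reference": r.reference,
                "NbPaths": r.n_paths,
                "NbNeurons": r.n_units,
                "mean_rate": r.mean_rate,
                "stage": extra.get("stage"),
                "region": extra.get("region"),
            }
        )
    return pd.DataFrame(rows)
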