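"""Coding-neuron detection by the chi-squared multinomial test.

Under the null, a unit fires at a constant rate, so its spike counts
``(N_1, ..., N_K)`` over K conditions follow a multinomial with cell
probabilities ``p_k = d_k / sum(d)`` proportional to the condition durations
``d_k``.  The Pearson statistic ``sum (N_k - n p_k)^2 / (n p_k)`` is referred
to a chi-squared with K-1 degrees of freedom.  The approximation is accepted
only when every expected count ``n p_k`` is at least 5; otherwise a
mode-specific policy merges or drops conditions, or discards the unit:

* ``task_event`` (K=30: six 500 ms events x five 100 ms bins): merge the
  five bins of each event into the six event-level conditions, then discard;
* ``left_right`` (K=2, central-stem activity by upcoming turn): discard;
* ``full_path`` (K <= 12 elementary paths): drop the offending condition
  (paths never taken contribute no condition at all); discard if fewer than
  two conditions survive.

Units tested within one analysis mode are pooled into a single
Benjamini-Hochberg family (configurable to per-session); a unit is *coding*
when its adjusted p-value is below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import (
    EVENTS,
    N_EVENT_BINS,
    BIN_DURATION,
    UNCLASSIFIED,
    BehaviorSession,
    EventWindow,
    extract_event_windows,
)

logger = logging.getLogger(__name__)

MODES = ("task_event", "left_right", "full_path")
MIN_EXPECTED = 5.0
ALPHA = 0.05


@dataclass
class ConditionCounts:
    """Per-condition spike counts and durations for one unit."""

    labels: list[str]
    counts: np.ndarray  # integer N_k
    durations: np.ndarray  # d_k in seconds, > 0 for retained conditions
    mode: str = "full_path"
    #: condition label -> merge group (used by the task_event merge step)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be >= 0")
        if np.any(self.durations <= 0):
            raise ValueError("retained conditions must have positive duration")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        return self.durations / self.durations.sum()

    @property
    def expected(self) -> np.ndarray:
        return self.n * self.p


@dataclass
class CodingTestResult:
    unit_id: int | str
    mode: str
    status: str  # "tested" | "discarded"
    statistic: float | None = None
    df: int | None = None
    p_value: float | None = None
    adjusted_p: float | None = None
    coding: bool | None = None
    policy_trace: list[str] = field(default_factory=list)


def _count_in_interval(spikes: np.ndarray, start: float, end: float) -> int:
    return int(np.searchsorted(spikes, end) - np.searchsorted(spikes, start))


def _stem_runs(session: BehaviorSession) -> list[tuple[float, float, str]]:
    """Central-stem runs [A-entry, B-entry) with the upcoming-turn label.

    A stem run occurs when intersection B immediately follows A in the zone
    timeline; the turn label ("left"/"right") is read from the next arm zone
    after B (F1 = left goal arm, F2 = right).
    """
    tl = session.zone_timeline
    runs = []
    for i in range(len(tl) - 2):
        (tA, zA), (tB, zB), (_, z_next) = tl[i], tl[i + 1], tl[i + 2]
        if zA == "A" and zB == "B" and z_next in ("F1", "F2"):
            turn = "left" if z_next == "F1" else "right"
            runs.append((tA, tB, turn))
    return runs


def build_condition_table(
    spikes: np.ndarray,
    session: BehaviorSession,
    mode: str,
    windows: list[EventWindow] | None = None,
) -> ConditionCounts:
    """Spike counts and durations per condition for one unit.

    ``task_event``: 30 conditions (event x 100 ms bin), d_k = 0.1 s times the
    number of passages through that event.  ``left_right``: 2 conditions from
    central-stem activity split by upcoming turn.  ``full_path``: one
    condition per path label actually taken (d_k = total time on that path).
    Zero-duration conditions are omitted at build time.
    """
    spikes = np.asarray(spikes, dtype=float)
    if mode == "task_event":
        if windows is None:
            windows = extract_event_windows(session)
        if not windows:
            raise ValueError("task_event mode requires event windows")
        labels, counts, durs, groups = [], [], [], {}
        for ev in EVENTS:
            ev_windows = [w for w in windows if w.event == ev]
            if not ev_windows:
                continue
            for j in range(N_EVENT_BINS):
                lab = f"{ev}:{j}"
                c = sum(_count_in_interval(spikes, *w.bins[j]) for w in ev_windows)
                labels.append(lab)
                counts.append(c)
                durs.append(BIN_DURATION * len(ev_windows))
                groups[lab] = ev
        if not labels:
            raise ValueError("no event passages in session")
        return ConditionCounts(labels, np.array(counts), np.array(durs), mode, groups)

    if mode == "left_right":
        runs = _stem_runs(session)
        if not runs:
            raise ValueError("left_right mode requires central-stem runs")
        labels = ["left", "right"]
        counts = np.zeros(2)
        durs = np.zeros(2)
        for t0, t1, turn in runs:
            k = labels.index(turn)
            counts[k] += _count_in_interval(spikes, t0, t1)
            durs[k] += t1 - t0
        keep = durs > 0
        return ConditionCounts(
            [l for l, k in zip(labels, keep) if k], counts[keep], durs[keep], mode
        )

    if mode == "full_path":
        by_label: dict[str, tuple[float, float]] = {}
        for tr in session.traversals:
            if tr.label == UNCLASSIFIED:
                continue
            c, d = by_label.get(tr.label, (0.0, 0.0))
            by_label[tr.label] = (
                c + _count_in_interval(spikes, tr.start, tr.end),
                d + tr.duration,
            )
        if not by_label:
            raise ValueError("full_path mode requires classified traversals")
        labels = sorted(by_label)
        counts = np.array([by_label[l][0] for l in labels])
        durs = np.array([by_label[l][1] for l in labels])
        return ConditionCounts(labels, counts, durs, mode)

    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def apply_validity_policy(
    counts: ConditionCounts, min_expected: float = MIN_EXPECTED
) -> tuple[ConditionCounts | None, list[str]]:
    """Enforce the expected-count rule n*p_k >= ``min_expected``.

    Returns ``(counts, trace)`` where counts is None when the unit is
    discarded.  The policy is mode-specific (see module docstring); validity
    is checked on expected counts, not observed ones.
    """
    trace: list[str] = []
    cc = counts
    if cc.n == 0:
        return None, ["discarded: zero spikes"]
    merged = False
    while True:
        bad = cc.expected < min_expected
        if not np.any(bad):
            return cc, trace
        if cc.mode == "task_event":
            if not merged and cc.groups:
                by_group: dict[str, tuple[float, float]] = {}
                order: list[str] = []
                for lab, c, d in zip(cc.labels, cc.counts, cc.durations):
                    g = cc.groups[lab]
                    if g not in by_group:
                        order.append(g)
                    cg, dg = by_group.get(g, (0.0, 0.0))
                    by_group[g] = (cg + c, dg + d)
                cc = ConditionCounts(
                    order,
                    np.array([by_group[g][0] for g in order]),
                    np.array([by_group[g][1] for g in order]),
                    mode=cc.mode,
                )
                merged = True
                trace.append("merged 100 ms bins into event-level conditions")
                continue
            trace.append("discarded: expected counts below threshold after merge")
            return None, trace
        if cc.mode == "left_right":
            trace.append("discarded: expected counts below threshold")
            return None, trace
        # full_path: drop the most offending condition
        drop = int(np.argmin(cc.expected))
        trace.append(f"dropped condition {cc.labels[drop]!r}")
        keep = np.ones(len(cc.labels), dtype=bool)
        keep[drop] = False
        if keep.sum() < 2:
            trace.append("discarded: fewer than 2 conditions remain")
            return None, trace
        cc = ConditionCounts(
            [l for l, k in zip(cc.labels, keep) if k],
            cc.counts[keep],
            cc.durations[keep],
            mode=cc.mode,
        )


def chi_square_multinomial_test(counts: ConditionCounts) -> tuple[float, int, float]:
    """Pearson statistic, degrees of freedom (K-1) and upper-tail p-value."""
    if counts.n == 0:
        raise ValueError("no spikes: unit should have been discarded")
    expected = counts.expected
    statistic = float(np.sum((counts.counts - expected) ** 2 / expected))
    df = len(counts.labels) - 1
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p


def bh_adjust(
    p_values: np.ndarray | list[float], alpha: float = ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and coding flags.

    Flags are ``adjusted < alpha`` (strict), matching the declaration rule.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    return adjusted, adjusted < alpha


def detect_coding_neurons(
    trains: dict[int, np.ndarray],
    session: BehaviorSession,
    mode: str,
    alpha: float = ALPHA,
    windows: list[EventWindow] | None = None,
) -> pd.DataFrame:
    """Run the full detector over all units of a session in one mode.

    Returns the ``coding.csv`` table: one row per unit with statistic, df,
    raw and BH-adjusted p, coding flag, status and policy trace.  The BH
    family is the set of tested units passed in (pool across sessions by
    concatenating results and re-running :func:`bh_adjust` if desired).
    """
    if mode == "task_event" and windows is None:
        windows = extract_event_windows(session)
    results: list[CodingTestResult] = []
    for unit_id, spikes in trains.items():
        res = CodingTestResult(unit_id=unit_id, mode=mode, status="discarded")
        try:
            cc = build_condition_table(spikes, session, mode, windows=windows)
        except ValueError as exc:
            res.policy_trace.append(f"discarded: {exc}")
            results.append(res)
            continue
        cc, trace = apply_validity_policy(cc)
        res.policy_trace.extend(trace)
        if cc is not None:
            res.statistic, res.df, res.p_value = chi_square_multinomial_test(cc)
            res.status = "tested"
        results.append(res)

    tested = [r for r in results if r.status == "tested"]
    if tested:
        adjusted, flags = bh_adjust([r.p_value for r in tested], alpha=alpha)
        for r, ap, fl in zip(tested, adjusted, flags):
            r.adjusted_p = float(ap)
            r.coding = bool(fl)
    out = pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in results],
            "mode": mode,
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "p_adj": [r.adjusted_p for r in results],
            "coding": [r.coding for r in results],
            "status": [r.status for r in results],
            "policy_trace": ["; ".join(r.policy_trace) for r in results],
        }
    )
    return out.astype(
        {"statistic": float, "df": float, "p": float, "p_adj": float, "coding": object}
    )
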