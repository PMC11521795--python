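"""Behavioral segmentation of continuous T-maze sessions.

A session is represented as a *zone timeline*: an ordered sequence of
``(entry_time_s, zone_id)`` pairs over the four coarse maze zones — the two
feeders ``F1``/``F2`` at the ends of the goal arms, and the two intersections
``A`` (base of the central stem) and ``B`` (top of the stem, on the
crossbar).  A zone's exit time is the entry time of the next zone, so the
timeline is a partition of the session into zone passages.

From the timeline this module derives

* elementary feeder-to-feeder *paths* (2 correct alternation paths and 10
  stereotyped incorrect ones), matched exactly against a configurable
  taxonomy of zone sequences; unmatched segments are kept as
  ``"unclassified"`` and excluded from every downstream statistic;
* per-session performance as correct / incorrect paths per minute;
* a four-stage learning label per session from the evolution of those rates;
* the six 500 ms task-event windows (intersections A/B, reward obtentions
  R1/R2, movement onsets O1/O2), each tiled by five 100 ms bins.

All intervals are half-open ``[start, end)`` in seconds, session-relative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

FEEDER_ZONES = ("F1", "F2")
ZONES = ("F1", "A", "B", "F2")

#: The 12 elementary paths: 2 correct alternations plus 10 stereotyped
#: errors (same-side stem returns, crossbar shortcuts and returns, base-rail
#: loops and crossings).  Keys are labels, values zone sequences that start
#: and end at a feeder.  Fully overridable by passing another taxonomy.
DEFAULT_TAXONOMY: dict[str, tuple[str, ...]] = {
    "correct_12": ("F1", "A", "B", "F2"),
    "correct_21": ("F2", "A", "B", "F1"),
    "stem_return_1": ("F1", "A", "B", "F1"),
    "stem_return_2": ("F2", "A", "B", "F2"),
    "crossbar_12": ("F1", "B", "F2"),
    "crossbar_21": ("F2", "B", "F1"),
    "crossbar_return_1": ("F1", "B", "F1"),
    "crossbar_return_2": ("F2", "B", "F2"),
    "base_return_1": ("F1", "A", "F1"),
    "base_return_2": ("F2", "A", "F2"),
    "base_cross_12": ("F1", "A", "F2"),
    "base_cross_21": ("F2", "A", "F1"),
}

CORRECT_LABELS = ("correct_12", "correct_21")

UNCLASSIFIED = "unclassified"

#: Canonical ordering of the six 500 ms task events.
EVENTS = ("A", "B", "R1", "R2", "O1", "O2")

EVENT_DURATION = 0.5
N_EVENT_BINS = 5
BIN_DURATION = EVENT_DURATION / N_EVENT_BINS  # 100 ms


class ConfigurationError(ValueError):
    """Invalid taxonomy, probability vector or stage rule configuration."""


@dataclass(frozen=True)
class PathTraversal:
    """One feeder-to-feeder maze traversal.

    ``start`` is the exit time of the starting feeder (entry into the first
    intermediate zone) and ``end`` the entry time into the terminal feeder,
    so ``[start, end)`` is the time actually spent on the track.
    """

    trial_id: int
    label: str
    correct: bool
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class EventWindow:
    """A 500 ms task-event window tiled by five 100 ms bins."""

    event: str  # one of EVENTS
    start: float
    end: float
    overlap_flag: bool = False

    @property
    def bins(self) -> list[tuple[float, float]]:
        edges = self.start + BIN_DURATION * np.arange(N_EVENT_BINS + 1)
        return [(float(edges[j]), float(edges[j + 1])) for j in range(N_EVENT_BINS)]


@dataclass
class BehaviorSession:
    session_id: str
    duration: float
    zone_timeline: list[tuple[float, str]]
    traversals: list[PathTraversal] = field(default_factory=list)
    stage: int | None = None

    def validate(self) -> None:
        times = [t for t, _ in self.zone_timeline]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("zone entry times must be strictly increasing")
        for t, z in self.zone_timeline:
            if not 0.0 <= t < self.duration:
                raise ValueError(f"zone entry at {t} outside [0, {self.duration})")


def validate_taxonomy(taxonomy: dict[str, tuple[str, ...]]) -> None:
    seen: dict[tuple[str, ...], str] = {}
    for label, seq in taxonomy.items():
        seq = tuple(seq)
        if len(seq) < 2 or seq[0] not in FEEDER_ZONES or seq[-1] not in FEEDER_ZONES:
            raise ConfigurationError(
                f"path {label!r} must start and end at a feeder zone: {seq}"
            )
        if seq in seen:
            raise ConfigurationError(
                f"duplicate node sequence {seq} for {label!r} and {seen[seq]!r}"
            )
        seen[seq] = label


def classify_paths(
    zone_timeline: list[tuple[float, str]],
    taxonomy: dict[str, tuple[str, ...]] | None = None,
    correct_labels: tuple[str, ...] = CORRECT_LABELS,
) -> list[PathTraversal]:
    """Segment a zone timeline at feeder visits and label each segment.

    Each feeder-to-feeder segment's zone sequence (both feeders included) is
    matched exactly against the taxonomy; segments absent from it are labeled
    ``"unclassified"`` and carry ``correct=False``.
    """
    if taxonomy is None:
        taxonomy = DEFAULT_TAXONOMY
    validate_taxonomy(taxonomy)
    lookup = {tuple(seq): label for label, seq in taxonomy.items()}

    if not zone_timeline:
        return []
    feeder_idx = [i for i, (_, z) in enumerate(zone_timeline) if z in FEEDER_ZONES]
    traversals: list[PathTraversal] = []
    trial_id = 0
    for i0, i1 in zip(feeder_idx, feeder_idx[1:]):
        seq = tuple(z for _, z in zone_timeline[i0 : i1 + 1])
        label = lookup.get(seq, UNCLASSIFIED)
        start = zone_timeline[i0 + 1][0]  # exit of the starting feeder
        end = zone_timeline[i1][0]
        traversals.append(
            PathTraversal(
                trial_id=trial_id,
                label=label,
                correct=label in correct_labels,
                start=start,
                end=end,
            )
        )
        trial_id += 1
    return traversals


def compute_performance(
    traversals: list[PathTraversal], duration: float
) -> tuple[float, float]:
    """Correct and incorrect path rates in paths/minute; unclassified excluded."""
    if duration <= 0:
        raise ValueError("session duration must be positive")
    n_correct = sum(1 for tr in traversals if tr.correct)
    n_incorrect = sum(
        1 for tr in traversals if not tr.correct and tr.label != UNCLASSIFIED
    )
    return n_correct / duration * 60.0, n_incorrect / duration * 60.0


def _centered_slopes(values: np.ndarray) -> np.ndarray:
    """Centered 3-point slopes (one-sided at the ends), per session step."""
    v = np.asarray(values, dtype=float)
    if len(v) == 1:
        return np.zeros(1)
    return np.gradient(v)


def assign_learning_stages(
    rates: list[tuple[float, float]],
    ratio_stage1: float = 1.25,
    slope_tol: float = 0.05,
    incorrect_share_stage4: float = 0.1,
) -> list[int]:
    """Label chronologically ordered sessions with learning stages 1-4.

    Stage 1 while the correct:incorrect ratio stays <= ``ratio_stage1``;
    stage 2 while the correct rate rises and the incorrect rate falls
    (sign of the centered 3-session slope); stage 3 once both slopes are
    within ``slope_tol`` in absolute value; stage 4 once the incorrect share
    of paths drops to <= ``incorrect_share_stage4``.  The output is made
    monotone non-decreasing by a running maximum.
    """
    if not rates:
        return []
    c = np.array([r[0] for r in rates], dtype=float)
    i = np.array([r[1] for r in rates], dtype=float)
    total = c + i
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(i > 0, c / np.where(i > 0, i, 1.0), np.inf)
        share = np.where(total > 0, i / np.where(total > 0, total, 1.0), 0.0)

    if len(rates) < 3:
        logger.warning(
            "fewer than 3 sessions: assigning stages by ratio thresholds only"
        )
        cand = np.where(share <= incorrect_share_stage4, 4,
                        np.where(ratio <= ratio_stage1, 1, 2))
    else:
        cs = _centered_slopes(c)
        ins = _centered_slopes(i)
        cand = np.empty(len(rates), dtype=int)
        for s in range(len(rates)):
            if share[s] <= incorrect_share_stage4:
                cand[s] = 4
            elif ratio[s] > ratio_stage1 and abs(cs[s]) < slope_tol and abs(ins[s]) < slope_tol:
                cand[s] = 3
            elif cs[s] > 0 and ins[s] < 0:
                cand[s] = 2
            else:
                cand[s] = 1
    return list(np.maximum.accumulate(cand))


def extract_event_windows(
    session: BehaviorSession,
    min_intersection_dwell: float = EVENT_DURATION,
) -> list[EventWindow]:
    """Derive the six 500 ms task-event windows from the zone timeline.

    Intersections A/B: central 500 ms of each passage ``[t0, t1)`` through
    the zone, i.e. ``[(t0+t1)/2 - 0.25, (t0+t1)/2 + 0.25)``; passages
    shorter than ``min_intersection_dwell`` are skipped with a log entry.
    Reward obtention R1/R2: first 500 ms after entering feeder 1/2.
    Movement onset O1/O2: last 500 ms before leaving feeder 1/2.
    Overlapping windows (short feeder dwells) are kept and flagged.
    """
    tl = session.zone_timeline
    windows: list[EventWindow] = []
    for (t0, z), (t1, _) in zip(tl, tl[1:]):
        if z in ("A", "B"):
            if t1 - t0 < min_intersection_dwell:
                logger.info(
                    "skipping %.3fs passage through %s at t=%.3f (< %.1fs)",
                    t1 - t0, z, t0, min_intersection_dwell,
                )
                continue
            mid = 0.5 * (t0 + t1)
            windows.append(EventWindow(z, mid - EVENT_DURATION / 2, mid + EVENT_DURATION / 2))
        elif z in FEEDER_ZONES:
            idx = "1" if z == "F1" else "2"
            overlap = (t1 - t0) < 2 * EVENT_DURATION
            if t0 + EVENT_DURATION <= session.duration:
                windows.append(EventWindow("R" + idx, t0, t0 + EVENT_DURATION, overlap))
            windows.append(EventWindow("O" + idx, t1 - EVENT_DURATION, t1, overlap))
            if overlap:
                logger.info("overlapping R/O windows at feeder %s, t=%.3f", z, t0)
    # terminal zone: a feeder visit at session end yields its R window only
    if tl and tl[-1][1] in FEEDER_ZONES:
        t0, z = tl[-1]
        if t0 + EVENT_DURATION <= session.duration:
            idx = "1" if z == "F1" else "2"
            windows.append(EventWindow("R" + idx, t0, t0 + EVENT_DURATION))
    windows.sort(key=lambda w: w.start)
    return windows
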