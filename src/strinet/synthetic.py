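"""Synthetic T-maze sessions and spike trains with ground-truth manifests.

No recordings are distributed with the analyses this package implements, so
every downstream stage is exercised on data generated here: behavior
sessions as draws from the 12-path taxonomy with stage-dependent
correct/incorrect mixes, spike trains as homogeneous or event-modulated
Poisson processes, condition-dependent multivariate Hawkes populations
with 60 ms piecewise-constant kernels (simulated by Ogata thinning), and
two-cluster waveform-feature tables (MSN-like vs FSI-like).

Everything is reproducible: one global seed expands to per-stream child
seeds (`numpy.random.SeedSequence`), so adding units or trials never
perturbs earlier random streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from .behavior import (
    CORRECT_LABELS,
    DEFAULT_TAXONOMY,
    BehaviorSession,
    ConfigurationError,
    EventWindow,
    classify_paths,
    extract_event_windows,
)

KERNEL_SUPPORT = 0.06  # s; six 10 ms plateaus
N_LAG_BINS = 6
LAG_BIN = 0.01  # s

#: Fraction of trials that are correct paths, per learning stage.  Stage 1
#: mixes correct and incorrect about equally; stage 4 is almost exclusively
#: correct.
STAGE_CORRECT_PROB = {1: 0.5, 2: 0.7, 3: 0.85, 4: 0.95}

#: Mean traversal durations (s) per default path, loosely graded by length
#: (full loops longer than crossbar shortcuts).
DEFAULT_PATH_DURATIONS = {
    "correct_12": 8.0, "correct_21": 8.0,
    "stem_return_1": 8.5, "stem_return_2": 8.5,
    "crossbar_12": 5.0, "crossbar_21": 5.0,
    "crossbar_return_1": 5.5, "crossbar_return_2": 5.5,
    "base_return_1": 5.5, "base_return_2": 5.5,
    "base_cross_12": 7.0, "base_cross_21": 7.0,
}


@dataclass
class ClusterSpec:
    """Mean/SD of (log firing rate, peak-valley distance, width) per type."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]


@dataclass
class SimConfig:
    seed: int = 0
    n_units: int = 8
    session_duration: float = 1200.0  # 20-minute training sessions
    #: label -> (mean duration s, selection probability); probabilities are
    #: the *incorrect-path* mixture weights when stage-dependent mixes apply.
    path_menu: dict[str, tuple[float, float]] = field(default_factory=dict)
    inter_trial_gap: float = 4.0  # feeder dwell; >= 0.5 s >> kernel support
    baseline_rates: tuple[float, ...] = ()
    event_gains: dict[str, Any] = field(default_factory=dict)
    #: condition label -> (mu vector Hz, kernel array a[m][n][i] Hz/spike)
    hawkes_spec: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    unit_cluster_spec: dict[str, ClusterSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.path_menu:
            p = 1.0 / len(DEFAULT_TAXONOMY)
            self.path_menu = {
                label: (DEFAULT_PATH_DURATIONS[label], p) for label in DEFAULT_TAXONOMY
            }
        if not self.unit_cluster_spec:
            # MSN-like: low rate, wide waveform; FSI-like: high rate, narrow.
            self.unit_cluster_spec = {
                "MSN": ClusterSpec(mean=(np.log(1.2), 550.0, 320.0), sd=(0.5, 60.0, 40.0)),
                "FSI": ClusterSpec(mean=(np.log(12.0), 250.0, 150.0), sd=(0.5, 60.0, 40.0)),
            }
        if self.inter_trial_gap < 0.5:
            raise ConfigurationError("inter_trial_gap must be >= 0.5 s")
        probs = np.array([p for _, p in self.path_menu.values()])
        if probs.size and (np.any(probs < 0) or not np.isclose(probs.sum(), 1.0)):
            raise ConfigurationError("path_menu probabilities must be >= 0 and sum to 1")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "path_menu" in raw:
            raw["path_menu"] = {
                k: (float(v[0]), float(v[1])) for k, v in raw["path_menu"].items()
            }
        if "hawkes_spec" in raw:
            raw["hawkes_spec"] = {
                k: (np.asarray(v[0], dtype=float), np.asarray(v[1], dtype=float))
                for k, v in raw["hawkes_spec"].items()
            }
        if "unit_cluster_spec" in raw:
            raw["unit_cluster_spec"] = {
                k: ClusterSpec(tuple(v["mean"]), tuple(v["sd"]))
                for k, v in raw["unit_cluster_spec"].items()
            }
        if "baseline_rates" in raw:
            raw["baseline_rates"] = tuple(raw["baseline_rates"])
        return cls(**raw)


@dataclass
class GroundTruthManifest:
    """Everything the generator knows: the oracle for every downstream test."""

    trial_labels: list[str] = field(default_factory=list)
    coding_truth: dict[str, dict[int, bool]] = field(default_factory=dict)
    hawkes_truth: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    unit_types: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "trial_labels": self.trial_labels,
            "coding_truth": {
                m: {str(u): bool(v) for u, v in d.items()}
                for m, d in self.coding_truth.items()
            },
            "hawkes_truth": {
                k: {"mu": np.asarray(mu).tolist(), "a": np.asarray(a).tolist()}
                for k, (mu, a) in self.hawkes_truth.items()
            },
            "unit_types": self.unit_types,
        }


def child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic per-stream generator derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


# ---------------------------------------------------------------------------
# Behavior generation
# ---------------------------------------------------------------------------

def gen_behavior_session(
    config: SimConfig,
    stage: int = 1,
    session_id: str = "sim",
    taxonomy: dict[str, tuple[str, ...]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BehaviorSession, GroundTruthManifest]:
    """Draw a session of elementary paths with a stage-dependent mix.

    Trials are drawn from ``config.path_menu`` restricted to paths starting
    at the rat's current feeder; the probability of picking a correct path is
    ``STAGE_CORRECT_PROB[stage]`` and the remaining mass is split over the
    eligible incorrect paths proportionally to their menu weights.  Zone
    dwell times are drawn so that intersection passages admit a centered
    500 ms window and feeder dwells realize ``inter_trial_gap``.
    """
    taxonomy = taxonomy or DEFAULT_TAXONOMY
    if not config.path_menu:
        raise ConfigurationError("path_menu must be nonempty")
    p_correct = STAGE_CORRECT_PROB.get(stage)
    if p_correct is None:
        raise ConfigurationError(f"unknown learning stage {stage!r}")
    rng = rng if rng is not None else child_rng(config.seed, 0)

    timeline: list[tuple[float, str]] = []
    labels: list[str] = []
    current_feeder = "F1"
    t = 0.0
    timeline.append((t, current_feeder))
    while True:
        eligible = [
            lab for lab in config.path_menu if taxonomy[lab][0] == current_feeder
        ]
        correct = [lab for lab in eligible if lab in CORRECT_LABELS]
        incorrect = [lab for lab in eligible if lab not in CORRECT_LABELS]
        weights = np.zeros(len(eligible))
        for j, lab in enumerate(eligible):
            if lab in CORRECT_LABELS:
                weights[j] = p_correct / max(len(correct), 1)
            else:
                w_inc = sum(config.path_menu[l][1] for l in incorrect)
                weights[j] = (1 - p_correct) * config.path_menu[lab][1] / w_inc
        weights /= weights.sum()
        label = eligible[rng.choice(len(eligible), p=weights)]
        seq = taxonomy[label]
        mean_dur = config.path_menu[label][0]

        # feeder dwell, then one passage per intermediate zone
        gap = config.inter_trial_gap * rng.uniform(1.0, 1.3)
        n_seg = len(seq) - 2  # intermediate zones
        shares = rng.dirichlet(np.full(n_seg, 8.0)) if n_seg > 1 else np.array([1.0])
        durs = np.maximum(0.7, shares * mean_dur * rng.uniform(0.85, 1.15))
        end_t = t + gap + float(durs.sum())
        if end_t >= config.session_duration:
            break
        t += gap
        for zone, d in zip(seq[1:-1], durs):
            timeline.append((t, zone))
            t += float(d)
        timeline.append((t, seq[-1]))
        labels.append(label)
        current_feeder = seq[-1]

    session = BehaviorSession(
        session_id=session_id,
        duration=config.session_duration,
        zone_timeline=timeline,
    )
    session.traversals = classify_paths(timeline, taxonomy)
    session.stage = stage
    session.validate()
    manifest = GroundTruthManifest(trial_labels=labels)
    return session, manifest


# ---------------------------------------------------------------------------
# Poisson spike trains
# ---------------------------------------------------------------------------

def gen_homogeneous_poisson(
    rate: float,
    intervals: list[tuple[float, float]],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Homogeneous Poisson spikes at ``rate`` Hz on disjoint intervals."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out: list[np.ndarray] = []
    for s, e in intervals:
        if e <= s:
            continue
        n = rng.poisson(rate * (e - s))
        out.append(s + rng.uniform(0.0, e - s, size=n))
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def _event_gain_bins(
    windows: list[EventWindow], gains: dict[str, np.ndarray] | np.ndarray
) -> list[tuple[float, float, float]]:
    """Flatten event windows into (start, end, gain) pieces, 100 ms each."""
    from .behavior import EVENTS, N_EVENT_BINS

    if not isinstance(gains, dict):
        flat = np.asarray(gains, dtype=float).reshape(len(EVENTS), N_EVENT_BINS)
        gains = {ev: flat[i] for i, ev in enumerate(EVENTS)}
    pieces = []
    for w in windows:
        g = np.asarray(gains.get(w.event, np.ones(N_EVENT_BINS)), dtype=float)
        if np.any(g < 0):
            raise ValueError("event gains must be >= 0")
        for (b0, b1), gj in zip(w.bins, g):
            pieces.append((b0, b1, float(gj)))
    pieces.sort()
    return pieces


def gen_event_modulated_train(
    baseline: float,
    gains: dict[str, np.ndarray] | np.ndarray,
    session: BehaviorSession,
    rng: np.random.Generator | int,
    windows: list[EventWindow] | None = None,
) -> np.ndarray:
    """Inhomogeneous Poisson train: rate = baseline*gain inside event bins,
    baseline elsewhere.  ``gains`` is either one array of 30 values (6 events
    x 5 bins, in canonical event order) or a dict event -> 5 gains."""
    if baseline < 0:
        raise ValueError("baseline rate must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if windows is None:
        windows = extract_event_windows(session)
    if not windows:
        raise ValueError("session has no event windows")
    pieces = _event_gain_bins(windows, gains)

    out: list[np.ndarray] = []
    cursor = 0.0
    for b0, b1, g in pieces:
        b0c = max(b0, cursor)  # overlapping R/O windows: first piece wins
        if b0c > cursor:
            out.append(gen_homogeneous_poisson(baseline, [(cursor, b0c)], rng))
        if b1 > b0c:
            out.append(gen_homogeneous_poisson(baseline * g, [(b0c, b1)], rng))
        cursor = max(cursor, b1)
    if cursor < session.duration:
        out.append(gen_homogeneous_poisson(baseline, [(cursor, session.duration)], rng))
    return np.sort(np.concatenate(out)) if out else np.empty(0)


# ---------------------------------------------------------------------------
# Hawkes simulation (Ogata thinning)
# ---------------------------------------------------------------------------

def branching_matrix(a: np.ndarray) -> np.ndarray:
    """L1 branching matrix: entry (m, n) = integral of |h_{m->n}|.

    ``a`` has shape (N, N, 6) in Hz per spike; the integral over the six
    10 ms plateaus is ``0.01 * sum_i |a[m, n, i]|`` expected extra spikes on
    n per spike of m.
    """
    return LAG_BIN * np.abs(np.asarray(a, dtype=float)).sum(axis=2)


def check_stability(a: np.ndarray, label: str = "") -> float:
    """Raise if the kernel's spectral radius is >= 1; return the radius."""
    A = branching_matrix(a)
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    if radius >= 1.0:
        name = f" for condition {label!r}" if label else ""
        raise ValueError(f"unstable Hawkes kernel{name}: spectral radius {radius:.3f}")
    return radius


def simulate_hawkes(
    mu: np.ndarray,
    a: np.ndarray,
    interval: tuple[float, float],
    rng: np.random.Generator,
    rectify: bool = False,
) -> list[np.ndarray]:
    """Simulate a multivariate Hawkes process on one interval by thinning.

    The intensity of unit n is ``mu[n] + sum over past spikes T of unit m of
    a[m, n, i]`` where i is the 10 ms lag bin of ``t - T`` (support 60 ms).
    The thinning bound is recomputed locally from the spikes currently inside
    the kernel window using each pair's maximal plateau, which remains an
    upper bound until the next accepted spike because spikes only leave the
    window.  Negative coefficients are only admitted with ``rectify=True``,
    in which case the intensity is ``max(0, .)`` (documented as approximate).
    """
    mu = np.asarray(mu, dtype=float)
    a = np.asarray(a, dtype=float)
    n_units = len(mu)
    if np.any(a < 0) and not rectify:
        raise ValueError("negative kernel coefficients require rectify=True")
    amax = np.maximum(a, 0.0).max(axis=2)  # (m, n) pairwise bound increments

    t0, t1 = interval
    spikes: list[list[float]] = [[] for _ in range(n_units)]
    # rolling history window: (time, unit) of spikes within kernel support
    hist_t: list[float] = []
    hist_u: list[int] = []
    t = t0
    mu_pos = np.maximum(mu, 0.0)
    base_bound = float(mu_pos.sum())
    while True:
        # drop history older than the kernel support
        while hist_t and t - hist_t[0] >= KERNEL_SUPPORT:
            hist_t.pop(0)
            hist_u.pop(0)
        bound = base_bound + sum(float(amax[m].sum()) for m in hist_u)
        if bound <= 0:
            break
        t = t + rng.exponential(1.0 / bound)
        if t >= t1:
            break
        lam = mu.copy()
        for T, m in zip(hist_t, hist_u):
            lag = t - T
            if 0.0 < lag < KERNEL_SUPPORT:
                lam += a[m, :, int(lag / LAG_BIN)]
        lam = np.maximum(lam, 0.0)
        lam_tot = float(lam.sum())
        if rng.uniform() * bound < lam_tot:
            n = int(rng.choice(n_units, p=lam / lam_tot))
            spikes[n].append(t)
            hist_t.append(t)
            hist_u.append(n)
    return [np.asarray(s) for s in spikes]


def gen_hawkes_session(
    spec: dict[str, tuple[np.ndarray, np.ndarray]],
    session: BehaviorSession,
    rng: np.random.Generator | int,
    rectify: bool = False,
) -> list[np.ndarray]:
    """Condition-dependent Hawkes spike trains over a session's trials.

    Within each classified traversal, spikes follow the Hawkes model of the
    trial's condition (path label); histories do not cross trials, which is
    exact for nonnegative kernels because the inter-trial gap exceeds the
    60 ms kernel support.  Time outside trials is silent.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for label, (_, a) in spec.items():
        check_stability(a, label)
    n_units = len(next(iter(spec.values()))[0])
    trains: list[list[np.ndarray]] = [[] for _ in range(n_units)]
    for tr in session.traversals:
        if tr.label not in spec:
            continue
        mu, a = spec[tr.label]
        trial = simulate_hawkes(mu, a, (tr.start, tr.end), rng, rectify=rectify)
        for n in range(n_units):
            trains[n].append(trial[n])
    return [
        np.sort(np.concatenate(ts)) if ts else np.empty(0) for ts in trains
    ]


# ---------------------------------------------------------------------------
# Waveform feature tables
# ---------------------------------------------------------------------------

def gen_unit_feature_table(
    spec: dict[str, ClusterSpec],
    n_msn: int,
    n_fsi: int,
    rng: np.random.Generator | int,
):
    """Two-cluster (log rate, PV, W) feature table with true type labels.

    Returns ``(DataFrame, labels)`` where the frame has columns
    ``unit_id, log_rate, pv_us, w_us`` and ``labels`` is the ground truth.
    """
    import pandas as pd

    if n_msn < 0 or n_fsi < 0 or n_msn + n_fsi < 1:
        raise ValueError("cluster counts must be >= 0 with at least one unit")
    for name, cs in spec.items():
        if any(s <= 0 for s in cs.sd):
            raise ValueError(f"cluster {name!r} SDs must be > 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows, labels = [], []
    for name, count in (("MSN", n_msn), ("FSI", n_fsi)):
        cs = spec[name]
        draws = rng.normal(loc=cs.mean, scale=cs.sd, size=(count, 3))
        for d in draws:
            rows.append(d)
            labels.append(name)
    df = pd.DataFrame(rows, columns=["log_rate", "pv_us", "w_us"])
    df.insert(0, "unit_id", np.arange(len(df)))
    return df, labels


# ---------------------------------------------------------------------------
# Full synthetic study bundles
# ---------------------------------------------------------------------------

def simulate_session_bundle(
    config: SimConfig,
    stage: int = 1,
    session_id: str = "sim",
) -> tuple[BehaviorSession, dict[int, np.ndarray], GroundTruthManifest]:
    """Session + per-unit spike trains + manifest, from one SimConfig.

    If ``hawkes_spec`` is set, trains come from the condition-dependent
    Hawkes generator; otherwise units are event-modulated Poisson with
    ``baseline_rates`` and ``event_gains`` (gain 1 everywhere by default).
    """
    session, manifest = gen_behavior_session(
        config, stage=stage, session_id=session_id, rng=child_rng(config.seed, 1)
    )
    trains: dict[int, np.ndarray] = {}
    if config.hawkes_spec:
        hk = gen_hawkes_session(config.hawkes_spec, session, child_rng(config.seed, 2))
        trains = {n: hk[n] for n in range(len(hk))}
        manifest.hawkes_truth = dict(config.hawkes_spec)
    else:
        rates = config.baseline_rates or tuple([2.0] * config.n_units)
        windows = extract_event_windows(session)
        for n in range(config.n_units):
            gains = config.event_gains.get(n) if config.event_gains else None
            if gains is None:
                trains[n] = gen_homogeneous_poisson(
                    rates[n], [(0.0, config.session_duration)], child_rng(config.seed, 3, n)
                )
                modulated = False
            else:
                trains[n] = gen_event_modulated_train(
                    rates[n], gains, session, child_rng(config.seed, 3, n), windows
                )
                modulated = bool(np.any(np.asarray(list(np.ravel(list(gains.values())))
                                                   if isinstance(gains, dict) else gains) != 1.0))
            manifest.coding_truth.setdefault("task_event", {})[n] = modulated
    return session, trains, manifest
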