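"""Poisson and multivariate Hawkes network estimation by least squares.

The intensity of unit n in condition k is either a constant (Poisson,
``lambda = nu_{n,k}``) or a Hawkes intensity

    lambda_{n,k}(t) = mu_{n,k} + sum_m sum_{T spikes of m, T < t} h_{m->n}(t - T)

with interaction kernels decomposed into six 10 ms plateaus ``a_{m,n,1..6}``
(support 60 ms); the value on lag bin i applies for ``t - T`` in
``[10(i-1), 10i) ms`` with lag 0 excluded, so a spike never predicts itself.
Per condition the Hawkes model has ``N + 6 N^2`` parameters, self-edges
included.

Both models are estimated by minimizing the least-squares contrast

    C(lambda) = -2 sum_{spikes T of n in K} lambda(T) + int_K lambda(t)^2 dt

over the union K of intervals where the condition holds.  The intensity is
linear in the parameters theta, so the minimizer solves the normal equations
``G theta = b`` with Gram matrix ``G_jl = int_K x_j x_l dt`` and moment
vector ``b_j = sum_T x_j(T)``; the predictors x are piecewise constant
(counts of recent spikes per lag bin), so G is computed *exactly* by a
breakpoint sweep — no discretization.  Spike history always uses the whole
session (only evaluation times are restricted to K), which matters near
interval edges.

Edge strengths are the L1 norms ``|h_{m->n}| = sum_i |a_{m,n,i}|`` of the
plateau coefficients; graphs are binarized at a quantile (default 70%) of
all strengths pooled over the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .behavior import UNCLASSIFIED, PathTraversal

logger = logging.getLogger(__name__)

N_LAG_BINS = 6
LAG_BIN = 0.01  # s
KERNEL_SUPPORT = N_LAG_BINS * LAG_BIN  # 60 ms
RIDGE_SCALE = 1e-8


@dataclass
class ConditionIntervals:
    """Disjoint [start, end) intervals per condition label."""

    intervals: dict[str, list[tuple[float, float]]]

    def duration(self, label: str) -> float:
        return float(sum(e - s for s, e in self.intervals[label]))


@dataclass
class PoissonParams:
    """Constant firing rates nu[n] (Hz) for one condition."""

    nu: np.ndarray

    @property
    def n_units(self) -> int:
        return len(self.nu)


@dataclass
class HawkesParams:
    """Spontaneous rates mu[n] and kernel plateaus a[m, n, i] for one condition."""

    mu: np.ndarray  # (N,)
    a: np.ndarray  # (N, N, 6); a[m, n, i] = effect of m's spikes on n
    ridge_flags: list[int] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.mu)

    @property
    def n_parameters(self) -> int:
        return self.n_units + N_LAG_BINS * self.n_units**2

    def strengths(self) -> np.ndarray:
        """L1 interaction strengths |h_{m->n}| = sum_i |a[m, n, i]|."""
        return np.abs(self.a).sum(axis=2)


@dataclass
class DesignSystem:
    """Normal-equation system for one target unit on one interval union.

    Predictor 0 is the constant term; predictor ``1 + 6*m + i`` counts
    spikes of unit m at lag bin i (i = 0..5).
    """

    G: np.ndarray  # (d, d)
    b: np.ndarray  # (d,)
    n_units: int
    target: int
    duration: float
    n_target_spikes: int


class _SharedDesign:
    """Gram matrix plus per-target moment vectors over one interval union.

    G does not depend on the target unit, so it is built once per
    (spike set, interval union) and shared across targets.
    """

    def __init__(
        self, trains: list[np.ndarray], intervals: list[tuple[float, float]]
    ):
        self.trains = [np.asarray(t, dtype=float) for t in trains]
        self.intervals = _merge_intervals(intervals)
        if not self.intervals:
            raise ValueError("empty interval union")
        self.n_units = len(self.trains)
        self.dim = 1 + N_LAG_BINS * self.n_units
        self.duration = float(sum(e - s for s, e in self.intervals))
        self.G = self._gram()

    def _segment_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Midpoints and lengths of the elementary constant segments of K."""
        all_spikes = (
            np.concatenate(self.trains) if any(t.size for t in self.trains) else np.empty(0)
        )
        mids, lens = [], []
        if all_spikes.size:
            # every spike creates breakpoints at T + i*10ms, i=0..6
            breaks_all = (all_spikes[:, None] + LAG_BIN * np.arange(N_LAG_BINS + 1)).ravel()
            breaks_all = np.sort(breaks_all)
        else:
            breaks_all = np.empty(0)
        for s, e in self.intervals:
            inner = breaks_all[(breaks_all > s) & (breaks_all < e)]
            pts = np.unique(np.concatenate(([s], inner, [e])))
            mids.append(0.5 * (pts[:-1] + pts[1:]))
            lens.append(np.diff(pts))
        return np.concatenate(mids), np.concatenate(lens)

    def _lag_counts(self, times: np.ndarray) -> np.ndarray:
        """x_{m,i}(t) for each time: shape (len(times), 6 * n_units).

        Counts spikes of unit m with lag t - T in [10(i-1), 10i) ms.
        Evaluated at segment midpoints, lags never hit bin edges exactly.
        """
        X = np.empty((times.size, N_LAG_BINS * self.n_units))
        edges = LAG_BIN * np.arange(N_LAG_BINS + 1)
        for m, sp in enumerate(self.trains):
            if sp.size == 0:
                X[:, N_LAG_BINS * m : N_LAG_BINS * (m + 1)] = 0.0
                continue
            # cumulative counts of spikes <= t - edge, per edge
            cum = np.stack(
                [np.searchsorted(sp, times - edge, side="right") for edge in edges]
            )
            X[:, N_LAG_BINS * m : N_LAG_BINS * (m + 1)] = (cum[:-1] - cum[1:]).T
        return X

    def _gram(self) -> np.ndarray:
        mids, lens = self._segment_grid()
        X = np.empty((mids.size, self.dim))
        X[:, 0] = 1.0
        X[:, 1:] = self._lag_counts(mids)
        return (X * lens[:, None]).T @ X

    def predictors_at(self, times: np.ndarray) -> np.ndarray:
        """Exact predictor rows at arbitrary times, zero lag excluded."""
        times = np.asarray(times, dtype=float)
        X = np.empty((times.size, self.dim))
        X[:, 0] = 1.0
        edges = LAG_BIN * np.arange(N_LAG_BINS + 1)
        for m, sp in enumerate(self.trains):
            block = slice(1 + N_LAG_BINS * m, 1 + N_LAG_BINS * (m + 1))
            if sp.size == 0:
                X[:, block] = 0.0
                continue
            # lag in [10(i-1), 10i) ms  <=>  T in (t - 10i, t - 10(i-1)] ms;
            # the zero-lag spike (T == t) is removed from bin 1
            cum = np.stack(
                [np.searchsorted(sp, times - edge, side="right") for edge in edges]
            )
            counts = (cum[:-1] - cum[1:]).T.astype(float)
            zero_lag = cum[0] - np.searchsorted(sp, times, side="left")
            counts[:, 0] -= zero_lag
            X[:, block] = counts
        return X

    def target_spikes(self, target: int) -> np.ndarray:
        sp = self.trains[target]
        keep = np.zeros(sp.size, dtype=bool)
        for s, e in self.intervals:
            keep |= (sp >= s) & (sp < e)
        return sp[keep]

    def moment_vector(self, target: int) -> tuple[np.ndarray, int]:
        ts = self.target_spikes(target)
        if ts.size == 0:
            return np.zeros(self.dim), 0
        return self.predictors_at(ts).sum(axis=0), int(ts.size)


def _merge_intervals(
    intervals: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    ivs = sorted((float(s), float(e)) for s, e in intervals if e > s)
    merged: list[tuple[float, float]] = []
    for s, e in ivs:
        if merged and s < merged[-1][1]:
            raise ValueError("intervals must be pairwise disjoint")
        if merged and s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def build_condition_intervals(
    traversals: list[PathTraversal],
) -> ConditionIntervals:
    """Group classified traversal time spans by path label.

    Unclassified trials contribute to no condition; overlapping traversals
    are a data error.
    """
    by_label: dict[str, list[tuple[float, float]]] = {}
    spans = sorted((tr.start, tr.end) for tr in traversals)
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("overlapping traversals")
    for tr in traversals:
        if tr.label == UNCLASSIFIED:
            continue
        by_label.setdefault(tr.label, []).append((tr.start, tr.end))
    return ConditionIntervals({k: sorted(v) for k, v in by_label.items()})


def fit_poisson(
    spikes: np.ndarray, intervals: list[tuple[float, float]]
) -> tuple[float, float]:
    """Closed-form Poisson rate and its optimal contrast on an interval union.

    The contrast ``-2 N nu + nu^2 D`` is minimized at ``nu = N / D`` where
    it equals ``-N^2 / D``.
    """
    ivs = _merge_intervals(intervals)
    D = float(sum(e - s for s, e in ivs))
    if D <= 0:
        raise ValueError("zero total duration")
    sp = np.asarray(spikes, dtype=float)
    N = sum(
        int(np.searchsorted(sp, e) - np.searchsorted(sp, s)) for s, e in ivs
    )
    nu = N / D
    return nu, -(N**2) / D


def build_design(
    trains: list[np.ndarray],
    target: int,
    intervals: list[tuple[float, float]],
) -> DesignSystem:
    """Gram matrix and moment vector for one target unit on one condition."""
    shared = _SharedDesign(trains, intervals)
    b, n_spk = shared.moment_vector(target)
    return DesignSystem(
        G=shared.G,
        b=b,
        n_units=shared.n_units,
        target=target,
        duration=shared.duration,
        n_target_spikes=n_spk,
    )


def _solve_normal_equations(
    G: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Solve G theta = b, falling back to a logged ridge when G is singular."""
    try:
        theta = np.linalg.solve(G, b)
        if np.all(np.isfinite(theta)):
            return theta, False
    except np.linalg.LinAlgError:
        pass
    ridge = RIDGE_SCALE * np.trace(G) / G.shape[0]
    if ridge <= 0:
        ridge = RIDGE_SCALE
    logger.warning("singular Gram matrix; adding ridge %.3e", ridge)
    theta = np.linalg.solve(G + ridge * np.eye(G.shape[0]), b)
    return theta, True


def fit_hawkes(design: DesignSystem) -> tuple[float, np.ndarray, bool]:
    """Least-squares Hawkes parameters for one target unit, one condition.

    Returns ``(mu, a_in, ridged)`` where ``a_in[m, i]`` is the incoming
    kernel from unit m; negative entries are permitted (inhibition).  With
    no target spikes the parameters are identically zero.
    """
    if design.n_target_spikes == 0:
        return 0.0, np.zeros((design.n_units, N_LAG_BINS)), False
    theta, ridged = _solve_normal_equations(design.G, design.b)
    mu = float(theta[0])
    a_in = theta[1:].reshape(design.n_units, N_LAG_BINS)
    return mu, a_in, ridged


def fit_hawkes_network(
    trains: list[np.ndarray], intervals: list[tuple[float, float]]
) -> HawkesParams:
    """Fit every unit's incoming kernels on one condition's interval union.

    The Gram matrix is shared across targets; only the moment vector is
    target-specific.
    """
    shared = _SharedDesign(trains, intervals)
    N = shared.n_units
    mu = np.zeros(N)
    a = np.zeros((N, N, N_LAG_BINS))
    ridge_flags: list[int] = []
    for n in range(N):
        b, n_spk = shared.moment_vector(n)
        if n_spk == 0:
            continue
        theta, ridged = _solve_normal_equations(shared.G, b)
        if ridged:
            ridge_flags.append(n)
        mu[n] = theta[0]
        a[:, n, :] = theta[1:].reshape(N, N_LAG_BINS)
    return HawkesParams(mu=mu, a=a, ridge_flags=ridge_flags)


def fit_poisson_network(
    trains: list[np.ndarray], intervals: list[tuple[float, float]]
) -> PoissonParams:
    nu = np.array([fit_poisson(t, intervals)[0] for t in trains])
    return PoissonParams(nu=nu)


def model_contrast(
    params: PoissonParams | HawkesParams,
    trains: list[np.ndarray],
    target: int,
    intervals: list[tuple[float, float]],
    shared: "_SharedDesign | None" = None,
) -> float:
    """Evaluate the least-squares contrast of a fitted intensity.

    ``C = -2 sum_{target spikes in K} lambda(T) + int_K lambda(t)^2 dt``
    with the full-session spike history and exact piecewise integration.
    For a Poisson rate this is the closed form ``-2 N nu + nu^2 D``.
    """
    if isinstance(params, PoissonParams):
        ivs = _merge_intervals(intervals)
        D = float(sum(e - s for s, e in ivs))
        sp = np.asarray(trains[target], dtype=float)
        N = sum(int(np.searchsorted(sp, e) - np.searchsorted(sp, s)) for s, e in ivs)
        nu = float(params.nu[target])
        return -2.0 * N * nu + nu**2 * D
    if shared is None:
        shared = _SharedDesign(trains, intervals)
    theta = np.concatenate(([params.mu[target]], params.a[:, target, :].ravel()))
    b, _ = shared.moment_vector(target)
    return float(-2.0 * theta @ b + theta @ shared.G @ theta)


def interaction_graph(
    params_list: list[HawkesParams],
    quantile: float = 0.70,
) -> tuple[float, list[np.ndarray]]:
    """Binarize edge strengths at a pooled quantile threshold.

    All strengths from every supplied network (sessions x conditions of the
    run, self-edges included) are pooled; edges strictly above the
    ``quantile`` quantile get a 1.  Returns the threshold and one adjacency
    matrix per input network.
    """
    if not params_list:
        raise ValueError("no estimated networks")
    pooled = np.concatenate([p.strengths().ravel() for p in params_list])
    if pooled.size == 0:
        raise ValueError("empty edge set")
    threshold = float(np.quantile(pooled, quantile))
    adjacency = [(p.strengths() > threshold).astype(int) for p in params_list]
    return threshold, adjacency


def to_digraph(params: HawkesParams, threshold: float):
    """Binarized interaction graph as a networkx DiGraph (edges above threshold)."""
    import networkx as nx

    g = nx.DiGraph()
    strengths = params.strengths()
    for n in range(params.n_units):
        g.add_node(n, mu=float(params.mu[n]))
    for m in range(params.n_units):
        for n in range(params.n_units):
            if strengths[m, n] > threshold:
                g.add_edge(m, n, strength=float(strengths[m, n]))
    return g
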