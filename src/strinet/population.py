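"""Population activity: z-score profiles, average curves and z-score entropy.

Each task-event coding unit gets a 30-bin firing-rate profile (six 500 ms
events x five 100 ms bins, averaged over passages) that is standardized over
bins: ``z_t = (f_t - mean(f)) / sd(f)`` with the sample (n-1) standard
deviation.  Population curves average z over units per group (brain region x
learning stage) with normal confidence bands Bonferroni-corrected over all
curves and bins.

The population *z-score entropy* is the binned plug-in functional

    sum over nonempty bins I of (Nz_I / Nz_tot) * log(Nz_I / (0.5 * Nz_tot))

with 18 bins of width 0.5 on [-3.5, 5.5] and the natural logarithm;
``Nz_I / (0.5 Nz_tot)`` estimates the z-score density on bin I, so the value
is the plug-in estimate of the *negative* differential entropy integral
(the sign convention is kept exactly as defined, not "corrected"): wider,
more uniform z distributions give smaller (more negative) values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import EVENTS, N_EVENT_BINS, BIN_DURATION, EventWindow

logger = logging.getLogger(__name__)

ENTROPY_LO = -3.5
ENTROPY_HI = 5.5
ENTROPY_BIN = 0.5
N_ENTROPY_BINS = int(round((ENTROPY_HI - ENTROPY_LO) / ENTROPY_BIN))  # 18

N_PROFILE_BINS = len(EVENTS) * N_EVENT_BINS  # 30


@dataclass
class EntropyEstimate:
    counts: np.ndarray  # Nz_I per bin, length 18
    total: int  # Nz_tot
    value: float  # nats


def bin_firing_rates(
    spikes: np.ndarray, windows: list[EventWindow]
) -> np.ndarray:
    """Mean firing rate (Hz) per 100 ms task-event bin, 30 values.

    ``f_t`` is the total spike count in bin t across passages, divided by
    0.1 s times the passage count.  Events with zero passages give NaN bins.
    """
    spikes = np.asarray(spikes, dtype=float)
    f = np.full(N_PROFILE_BINS, np.nan)
    for e, ev in enumerate(EVENTS):
        ev_windows = [w for w in windows if w.event == ev]
        if not ev_windows:
            logger.info("event %s has no passages; bins marked missing", ev)
            continue
        for j in range(N_EVENT_BINS):
            c = sum(
                np.searchsorted(spikes, b1) - np.searchsorted(spikes, b0)
                for w in ev_windows
                for b0, b1 in [w.bins[j]]
            )
            f[e * N_EVENT_BINS + j] = c / (BIN_DURATION * len(ev_windows))
    return f


def zscore_profile(f: np.ndarray) -> np.ndarray | None:
    """Standardize a rate profile over bins; None when sd = 0 (excluded)."""
    f = np.asarray(f, dtype=float)
    valid = f[~np.isnan(f)]
    if valid.size < 2:
        raise ValueError("need at least 2 bins to standardize")
    sd = float(np.std(valid, ddof=1))
    if sd == 0.0:
        return None
    return (f - valid.mean()) / sd


def population_curves(
    profiles: dict[str, np.ndarray],
    alpha: float = 0.05,
    n_comparisons: int = 8 * N_PROFILE_BINS,
) -> dict[str, dict[str, np.ndarray]]:
    """Mean z per bin and Bonferroni-corrected normal confidence bands.

    ``profiles`` maps group name -> array (n_units, 30).  The band is
    mean +/- q * sd / sqrt(n_units) with q the standard-normal quantile at
    1 - alpha / (2 * n_comparisons); the default corrects over 8 curves x
    30 bins = 240 comparisons.  Size-1 groups get NaN bands and a flag.
    """
    q = float(stats.norm.ppf(1 - alpha / (2 * n_comparisons)))
    out: dict[str, dict[str, np.ndarray]] = {}
    for group, z in profiles.items():
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.size == 0:
            raise ValueError(f"group {group!r} is empty")
        mean = z.mean(axis=0)
        if z.shape[0] < 2:
            logger.warning("group %r has a single unit: CI undefined", group)
            half = np.full(z.shape[1], np.nan)
            flagged = True
        else:
            half = q * z.std(axis=0, ddof=1) / np.sqrt(z.shape[0])
            flagged = False
        out[group] = {
            "mean": mean,
            "lo": mean - half,
            "hi": mean + half,
            "flagged": flagged,
        }
    return out


def zscore_entropy(z_values: np.ndarray) -> EntropyEstimate:
    """Binned plug-in z-score entropy functional (nats); see module docstring.

    Values outside [-3.5, 5.5] are clipped into the terminal bins so that
    the bin counts always sum to the population size.
    """
    z = np.asarray(z_values, dtype=float).ravel()
    z = z[~np.isnan(z)]
    if z.size == 0:
        raise ValueError("empty z-score population")
    idx = np.floor((z - ENTROPY_LO) / ENTROPY_BIN).astype(int)
    idx = np.clip(idx, 0, N_ENTROPY_BINS - 1)
    counts = np.bincount(idx, minlength=N_ENTROPY_BINS)
    total = int(counts.sum())
    nz = counts[counts > 0]
    value = float(np.sum((nz / total) * np.log(nz / (ENTROPY_BIN * total))))
    return EntropyEstimate(counts=counts, total=total, value=value)


def entropy_stage_contrast(
    groups: dict[tuple[str, int], list[np.ndarray]],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    n_contrasts: int = 8,
) -> dict[tuple[str, int], dict[str, float]]:
    """Entropy differences vs stage 1 per region, with bootstrap CIs.

    ``groups`` maps (region, stage) -> list of per-unit z arrays.  For each
    region with a stage-1 group, the contrast ``H(stage) - H(stage 1)`` is
    bootstrapped by resampling *units* with replacement in both groups; the
    percentile CI level is Bonferroni-corrected over ``n_contrasts`` group
    contrasts.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d < 100: bootstrap CIs will be unstable", n_boot)
    rng = np.random.default_rng(seed)
    level = alpha / n_contrasts
    qlo, qhi = 100 * level / 2, 100 * (1 - level / 2)

    def pooled(units: list[np.ndarray]) -> np.ndarray:
        return np.concatenate([np.ravel(u) for u in units])

    out: dict[tuple[str, int], dict[str, float]] = {}
    regions = sorted({r for r, _ in groups})
    for region in regions:
        if (region, 1) not in groups:
            raise ValueError(f"stage 1 group missing for region {region!r}")
        ref_units = groups[(region, 1)]
        h_ref = zscore_entropy(pooled(ref_units)).value
        for (r, stage), units in sorted(groups.items()):
            if r != region:
                continue
            delta = zscore_entropy(pooled(units)).value - h_ref
            boots = np.empty(n_boot)
            for b in range(n_boot):
                rs = [units[i] for i in rng.integers(len(units), size=len(units))]
                rr = [ref_units[i] for i in rng.integers(len(ref_units), size=len(ref_units))]
                boots[b] = zscore_entropy(pooled(rs)).value - zscore_entropy(pooled(rr)).value
            out[(region, stage)] = {
                "delta": float(delta),
                "lo": float(np.percentile(boots, qlo)),
                "hi": float(np.percentile(boots, qhi)),
            }
    return out
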