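"""Unit-type classification (putative MSN vs FSI) and cluster quality.

Striatal units separate into two clusters in the space of (log firing rate,
peak-valley distance PV, width at half height W): medium spiny projection
neurons (MSN; low rate, wide waveform) and fast-spiking interneurons (FSI;
high rate, narrow waveform).  Classification is a two-step procedure — a
Ward-linkage dendrogram cut at two clusters, whose centroids seed a k=2
k-means — which makes the assignment deterministic.

Cluster quality is reported with the L-ratio: the summed chi-squared tail
probabilities of noise spikes' Mahalanobis distances to the cluster center,
normalized by cluster size, plus a percentile against same-size random
clusters drawn from the remaining spikes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("log_rate", "pv_us", "w_us")
SILHOUETTE_WARN = 0.2


def extract_waveform_features(
    waveform: np.ndarray, dt: float
) -> tuple[float, float]:
    """Peak-valley distance and width at half height of a sampled waveform.

    PV is the time from the global peak to the next local minimum after it;
    W is the duration over which the amplitude stays at or above half the
    peak value, with linear interpolation at the crossings.  Assumes a
    zero-baseline waveform with a unique interior peak.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 3:
        raise ValueError("waveform too short")
    peak = int(np.argmax(w))
    if peak == 0 or peak == w.size - 1:
        raise ValueError("waveform has no interior peak (monotone?)")

    # next local minimum after the peak (fall back to the global minimum of
    # the tail when the waveform decays monotonically to the end)
    tail = w[peak:]
    minima = np.where((tail[1:-1] <= tail[:-2]) & (tail[1:-1] <= tail[2:]))[0]
    valley = peak + 1 + int(minima[0]) if minima.size else peak + int(np.argmin(tail))
    if valley == peak:
        raise ValueError("no valley after peak")
    pv = (valley - peak) * dt

    half = w[peak] / 2.0
    # left crossing
    i = peak
    while i > 0 and w[i - 1] >= half:
        i -= 1
    if i == 0:
        t_left = 0.0
    else:
        t_left = (i - 1 + (half - w[i - 1]) / (w[i] - w[i - 1])) * dt
    # right crossing
    j = peak
    while j < w.size - 1 and w[j + 1] >= half:
        j += 1
    if j == w.size - 1:
        t_right = (w.size - 1) * dt
    else:
        t_right = (j + (half - w[j]) / (w[j + 1] - w[j])) * dt
    return float(pv), float(t_right - t_left)


def classify_units(
    features: pd.DataFrame,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
) -> tuple[pd.DataFrame, dict]:
    """Label units MSN/FSI by Ward clustering followed by seeded k-means.

    Features are centered and scaled, a Ward tree on Euclidean distances is
    cut into two clusters, and k-means (k=2) is initialized at the two Ward
    centroids.  The cluster with higher mean log rate and narrower waveform
    is labeled FSI; the other MSN.  Returns the table with a ``type`` column
    plus a summary dict (linkage matrix, silhouette, warning flag).
    """
    X = features.loc[:, list(feature_columns)].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 units to classify")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    link = linkage(Z, method="ward")
    ward_labels = fcluster(link, t=2, criterion="maxclust")
    centroids = np.stack([Z[ward_labels == c].mean(axis=0) for c in (1, 2)])
    km = KMeans(n_clusters=2, init=centroids, n_init=1).fit(Z)
    labels = km.labels_

    # FSI = higher log rate, smaller PV and W, scored on standardized means
    score = np.empty(2)
    for c in (0, 1):
        m = Z[labels == c].mean(axis=0)
        score[c] = m[0] - m[1] - m[2]
    fsi_cluster = int(np.argmax(score))
    types = np.where(labels == fsi_cluster, "FSI", "MSN")

    sil = float(silhouette_score(Z, labels)) if len(set(labels)) == 2 else -1.0
    warn = sil < SILHOUETTE_WARN
    if warn:
        logger.warning("weak cluster separation (silhouette=%.3f < %.1f)", sil, SILHOUETTE_WARN)
    out = features.copy()
    out["type"] = types
    return out, {"linkage": link, "silhouette": sil, "weak_separation": warn}


def l_ratio(cluster: np.ndarray, noise: np.ndarray) -> float:
    """L-ratio of a cluster against noise spikes in the same feature space.

    ``L = sum over noise spikes of (1 - CDF_chi2_df(D^2))`` with ``D^2`` the
    Mahalanobis distance to the cluster center (df = feature dimension);
    the L-ratio is L divided by the cluster size.  Singular covariances get
    a ridge of 1e-8 * trace / d (logged).
    """
    cluster = np.atleast_2d(np.asarray(cluster, dtype=float))
    noise = np.atleast_2d(np.asarray(noise, dtype=float))
    n, d = cluster.shape
    if n < d + 1:
        raise ValueError("cluster size must exceed the feature dimension")
    center = cluster.mean(axis=0)
    cov = np.cov(cluster, rowvar=False)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(cov) / d
        logger.warning("singular cluster covariance; adding ridge %.3e", ridge)
        inv = np.linalg.inv(cov + ridge * np.eye(d))
    diff = noise - center
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    return float(np.sum(stats.chi2.sf(d2, df=d)) / n)


def l_ratio_percentile(
    cluster: np.ndarray,
    all_spikes: np.ndarray,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Observed L-ratio and its percentile under same-size random clusters.

    Random clusters are drawn (without replacement) from all spikes
    excluding the analyzed cluster; each pseudo-cluster is scored against
    every other spike (the remaining pool plus the analyzed cluster), so
    observed and null L-ratios see noise sets of equal size and the
    percentile is calibrated under exchangeability.  The percentile is the
    mid-rank of the observed L-ratio in the null distribution, in [0, 100].
    """
    rng = np.random.default_rng(seed)
    cluster = np.atleast_2d(np.asarray(cluster, dtype=float))
    pool = np.atleast_2d(np.asarray(all_spikes, dtype=float))
    observed = l_ratio(cluster, pool)
    n = cluster.shape[0]
    if pool.shape[0] < n + cluster.shape[1] + 1:
        raise ValueError("not enough non-cluster spikes for the bootstrap")
    null = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.choice(pool.shape[0], size=n, replace=False)
        mask = np.zeros(pool.shape[0], dtype=bool)
        mask[idx] = True
        null[it] = l_ratio(pool[mask], np.vstack([pool[~mask], cluster]))
    pct = 100.0 * (np.sum(null < observed) + 0.5 * np.sum(null == observed)) / n_iter
    return observed, float(pct)
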