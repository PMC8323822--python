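"""Spike sorting: PCA features + replicated k-means with automatic k.

One extracellular electrode often records several nearby neurons, so the
waveform snippets around detected threshold crossings must be assigned to
putative single units before any connectivity analysis.  The approach is
the standard one: mean-centred PCA compresses each snippet into the few
components that carry most of the waveform variance, then k-means (best
of ``replicates`` random restarts, judged by within-cluster sum of
point-to-centroid distances) partitions the feature cloud.  The candidate
number of units ranges from 1 to the retained component count plus one,
and the final k is the elbow of the within-cluster-sum curve.  Events far
from their centroid are flagged as outliers but never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from spikeconn.synthetic import SpikeTrainSet

__all__ = ["WaveformSet", "SortResult", "pca_features", "sort_spikes", "split_trains"]


@dataclass
class WaveformSet:
    """Waveform snippets (events x samples) with their event times (s)."""

    snippets: np.ndarray
    event_times: np.ndarray
    sample_interval: float = 0.05

    def __post_init__(self) -> None:
        self.snippets = np.atleast_2d(np.asarray(self.snippets, dtype=float))
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.snippets.shape[0] != self.event_times.size:
            raise ValueError("one event time per snippet required")
        if np.any(np.diff(self.event_times) < 0):
            raise ValueError("event times must be sorted")

    @property
    def n_events(self) -> int:
        return self.snippets.shape[0]


@dataclass
class SortResult:
    """Unit assignment per event plus the clustering objective."""

    labels: np.ndarray
    k: int
    within_cluster_ss: float
    outliers: np.ndarray

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.k:
            raise ValueError("labels must lie in [0, k)")


def pca_features(
    waveforms: WaveformSet, variance_target: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred PCA scores retaining >= ``variance_target`` variance.

    Returns the (events x components) feature matrix and the full
    explained-variance-ratio profile.  Constant snippet sets are rejected
    (zero variance carries no sorting information).
    """
    x = waveforms.snippets
    if x.shape[0] < 2:
        raise ValueError("need at least 2 events")
    if np.allclose(x, x[0]):
        raise ValueError("snippets are constant; nothing to sort")
    pca = PCA()
    scores = pca.fit_transform(x)
    profile = pca.explained_variance_ratio_
    n_keep = int(np.searchsorted(np.cumsum(profile), variance_target) + 1)
    n_keep = min(n_keep, scores.shape[1])
    return scores[:, :n_keep], profile


def _within_ss(features: np.ndarray, k: int, replicates: int, seed: int) -> tuple[float, np.ndarray]:
    km = KMeans(n_clusters=k, n_init=replicates, random_state=seed)
    labels = km.fit_predict(features)
    return float(km.inertia_), labels


def sort_spikes(
    features: np.ndarray,
    replicates: int = 20,
    k_init: int = 2,
    seed: int = 0,
    k_override: int | None = None,
) -> SortResult:
    """Cluster PCA features into putative units with automatic k.

    k-means is run for every candidate k in {1, ..., k_max} with
    ``replicates`` random restarts each, keeping the restart with the
    lowest within-cluster sum; k_max is the retained PCA component count
    plus one (capped by the number of events).  The clustering starts
    from ``k_init`` in the sense that k_init is always a candidate even
    for a single retained component.  The final k is chosen at the elbow
    of the within-cluster-sum curve (largest second difference), except
    that k = 1 is returned when splitting into two clusters barely
    reduces the objective (relative reduction below 40%), the signature
    of a single unit.  ``k_override`` forces k, mirroring manual curation
    of difficult electrodes.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    n_events = features.shape[0]
    k_max = max(features.shape[1] + 1, k_init)
    k_max = min(k_max, n_events)

    if k_override is not None:
        k = min(max(1, k_override), n_events)
        wss, labels = _within_ss(features, k, replicates, seed)
    else:
        candidates = list(range(1, k_max + 1))
        runs = {k: _within_ss(features, k, replicates, seed) for k in candidates}
        wss_curve = np.array([runs[k][0] for k in candidates])
        if len(candidates) == 1:
            k = 1
        elif wss_curve[0] <= 0 or wss_curve[1] > 0.6 * wss_curve[0]:
            # splitting barely helps: one unit
            k = 1
        elif len(candidates) == 2:
            k = 2
        else:
            second_diff = wss_curve[:-2] - 2 * wss_curve[1:-1] + wss_curve[2:]
            k = candidates[int(np.argmax(second_diff)) + 1]
        wss, labels = runs[k]

    # outliers: farther than 3x the cluster rms distance from its centroid
    outliers = np.zeros(n_events, dtype=bool)
    for c in range(k):
        member = labels == c
        if member.sum() < 2:
            continue
        centroid = features[member].mean(axis=0)
        dist = np.linalg.norm(features[member] - centroid, axis=1)
        rms = np.sqrt(np.mean(dist**2))
        if rms > 0:
            outliers[np.flatnonzero(member)[dist > 3 * rms]] = True
    return SortResult(labels=labels, k=int(k), within_cluster_ss=wss,
                      outliers=outliers)


def split_trains(waveforms: WaveformSet, result: SortResult) -> SpikeTrainSet:
    """Partition the event times into one spike train per sorted unit."""
    if waveforms.n_events != result.labels.size:
        raise ValueError("labels and waveforms disagree on event count")
    duration = float(waveforms.event_times.max()) + 1e-3 if waveforms.n_events else 1.0
    trains = [
        np.sort(waveforms.event_times[result.labels == c]) for c in range(result.k)
    ]
    return SpikeTrainSet(result.k, trains, duration)
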