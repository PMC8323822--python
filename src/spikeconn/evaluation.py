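"""Scoring against ground truth, graph descriptors, receiver probability.

Reconstruction quality is reported with the connectivity-independent
confidence indicator Delta = (TP - FP) / n_c alongside the conventional
accuracy ACC = (TP + TN) / n_tot, where n_c is the number of true edges
and n_tot = n (n - 1) the number of ordered off-diagonal pairs.  Note
that ACC inflates on sparse ground truth (TN dominates), which is why
Delta is the primary indicator.

Graph descriptors follow common practice for cultured-network studies:
in/out degree, hubs by in-degree centrality, mean shortest-path length
over the finite directed pairs, and the node-averaged clustering
coefficient of the undirected projection.

The receiver probability s- / (s+ + s-) estimates, purely from spike
timing, whether a neuron tends to fire after (receiver, near 1) or
before (initiator, near 0) the rest of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as _stats

from spikeconn.matrices import ConnectivityMatrix
from spikeconn.synthetic import NetworkModel, SpikeTrainSet

__all__ = [
    "EvaluationResult",
    "GraphMetrics",
    "ReceiverEstimate",
    "score",
    "degree_metrics",
    "path_clustering",
    "receiver_probability",
    "receiver_vs_indegree",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts over ordered off-diagonal pairs and derived rates."""

    TP: int
    FP: int
    TN: int
    FN: int
    n_c: int

    @property
    def n_tot(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def tp_rate(self) -> float:
        return self.TP / self.n_c

    @property
    def fp_rate(self) -> float:
        return self.FP / self.n_c

    @property
    def delta(self) -> float:
        """(TP - FP) / n_c, the confidence indicator."""
        return (self.TP - self.FP) / self.n_c

    @property
    def acc(self) -> float:
        return (self.TP + self.TN) / self.n_tot

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "n_c": self.n_c, "n_tot": self.n_tot,
            "tp_rate": self.tp_rate, "fp_rate": self.fp_rate,
            "delta": self.delta, "acc": self.acc,
        }


@dataclass
class GraphMetrics:
    """Per-node degree structure of a directed adjacency matrix.

    ``in_degree_fraction`` is in/(in+out) per node (NaN for isolated
    nodes).  Hubs are nodes whose in-degree exceeds the configured
    threshold; ``max_hub_size`` is the largest hub in-degree (0 if no hub).
    """

    in_degree: np.ndarray
    out_degree: np.ndarray
    in_degree_fraction: np.ndarray
    hubs: np.ndarray
    max_hub_size: int


@dataclass
class ReceiverEstimate:
    """Per-neuron spike counts of other neurons before (s-) and after (s+)
    each of the neuron's own spikes, within +/- window ms."""

    s_plus: np.ndarray
    s_minus: np.ndarray
    window: float

    @property
    def receiver_prob(self) -> np.ndarray:
        """s- / (s+ + s-); NaN where the denominator is zero."""
        denom = self.s_plus + self.s_minus
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.s_minus / denom, np.nan)


def score(predicted: ConnectivityMatrix, truth: NetworkModel) -> EvaluationResult:
    """Confusion counts of a reconstruction against the generating network."""
    if predicted.n_neurons != truth.n_neurons:
        raise ValueError("predicted and truth have different sizes")
    if truth.n_c == 0:
        raise ValueError("ground truth has no edges; Delta is undefined")
    pred = predicted.entries.astype(bool)
    true = truth.adjacency().astype(bool)
    off = ~np.eye(truth.n_neurons, dtype=bool)
    tp = int(np.sum(pred & true & off))
    fp = int(np.sum(pred & ~true & off))
    fn = int(np.sum(~pred & true & off))
    tn = int(np.sum(~pred & ~true & off))
    return EvaluationResult(TP=tp, FP=fp, TN=tn, FN=fn, n_c=truth.n_c)


def degree_metrics(
    matrix: ConnectivityMatrix,
    hub_z: float = 2.0,
    hub_percentile: float | None = None,
) -> GraphMetrics:
    """Degrees, in-degree fractions and hub flags.

    By default a hub is a node with in-degree >= mean + ``hub_z`` standard
    deviations of the in-degree distribution; passing ``hub_percentile``
    (e.g. 95) switches to a top-percentile rule instead.
    """
    m = matrix.entries
    in_deg = m.sum(axis=0).astype(int)
    out_deg = m.sum(axis=1).astype(int)
    tot = in_deg + out_deg
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, in_deg / np.maximum(tot, 1), np.nan)
    if hub_percentile is not None:
        cut = np.percentile(in_deg, hub_percentile)
        hubs = (in_deg >= cut) & (in_deg > 0)
    elif in_deg.std() == 0:
        # uniform in-degree: nobody is disproportionately connected
        hubs = np.zeros_like(in_deg, dtype=bool)
    else:
        cut = in_deg.mean() + hub_z * in_deg.std()
        hubs = (in_deg >= cut) & (in_deg > 0)
    max_hub = int(in_deg[hubs].max()) if hubs.any() else 0
    return GraphMetrics(in_deg, out_deg, frac, hubs, max_hub)


def path_clustering(matrix: ConnectivityMatrix) -> tuple[float, float]:
    """Mean shortest-path length and mean clustering coefficient.

    Path length averages the unweighted directed shortest-path distance
    over every ordered pair with a finite path (self-pairs and unreachable
    pairs excluded); it is NaN when no finite pair exists.  Clustering is
    the node-averaged fraction of triangles around each node, computed on
    the undirected projection; nodes with fewer than two neighbours
    contribute zero.
    """
    g = nx.from_numpy_array(matrix.entries, create_using=nx.DiGraph)
    lengths = []
    for src, dists in nx.all_pairs_shortest_path_length(g):
        lengths.extend(d for dst, d in dists.items() if dst != src)
    mean_pl = float(np.mean(lengths)) if lengths else float("nan")
    und = nx.Graph(g.to_undirected())
    mean_cc = float(np.mean(list(nx.clustering(und).values()))) if und else 0.0
    return mean_pl, mean_cc


def receiver_probability(
    trains: SpikeTrainSet, window: float = 15.0
) -> ReceiverEstimate:
    """Count other-neuron spikes around each neuron's spikes.

    For every spike at time t of neuron j, spikes of every other neuron
    falling in [t - window, t) increment s-, and spikes in (t, t + window]
    increment s+ (window in ms; coincident spikes at exactly t are counted
    on neither side).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    w = window / 1000.0
    n = trains.n_neurons
    s_plus = np.zeros(n, dtype=int)
    s_minus = np.zeros(n, dtype=int)
    for j in range(n):
        own = trains.spike_times[j]
        if own.size == 0:
            continue
        for k in range(n):
            if k == j:
                continue
            other = trains.spike_times[k]
            if other.size == 0:
                continue
            # spikes in [t-w, t): left-closed, right-open at t
            s_minus[j] += int(
                np.sum(np.searchsorted(other, own, side="left")
                       - np.searchsorted(other, own - w, side="left"))
            )
            # spikes in (t, t+w]: open at t, closed at t+w
            s_plus[j] += int(
                np.sum(np.searchsorted(other, own + w, side="right")
                       - np.searchsorted(other, own, side="right"))
            )
    return ReceiverEstimate(s_plus, s_minus, window)


def receiver_vs_indegree(
    est: ReceiverEstimate, metrics: GraphMetrics
) -> tuple[float, float, float]:
    """OLS fit of in-degree fraction on receiver probability.

    Returns (slope, intercept, r_squared) over the neurons for which both
    quantities are defined.  A near-unit slope indicates that the timing-
    based receiver estimate agrees with the reconstructed connectivity.
    """
    x = est.receiver_prob
    y = metrics.in_degree_fraction
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 neurons with both quantities defined")
    if np.ptp(x[ok]) == 0:
        raise ValueError("receiver probability is constant; fit is degenerate")
    fit = _stats.linregress(x[ok], y[ok])
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
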