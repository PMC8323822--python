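"""Correlation-triangle super-selection.

A *correlation triangle* is a cyclic triplet of correlation delays
(tau_jk, tau_km, tau_mj) drawn from the detected peaks of the three pairs
of a neuron triplet {j, k, m}.  If the delays close — their sum is within
epsilon of zero — one of the three correlations is the combination of the
other two, i.e. an indirect (multi-neuron pathway) or apparent (shared
input/output) link.  Because phase noise accumulates along longer paths,
that dependent correlation has the smallest peak amplitude, so the
minimum-amplitude peak of every closing triangle is discarded.  Repeating
until no closing triangle survives reduces the functional peak graph G'
toward the effective connectivity G (G is always a subset of G').
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from spikeconn.correlation import CorrelationPeak, PeakGraph
from spikeconn.matrices import ConnectivityMatrix

__all__ = [
    "CorrelationTriangle",
    "enumerate_triangles",
    "flag_triangles",
    "prune_peaks",
    "peaks_to_matrix",
]


@dataclass
class CorrelationTriangle:
    """One cyclic combination of peaks over a neuron triplet (j < k < m).

    ``delays`` are oriented cyclically j -> k -> m -> j; a stored peak of
    the pair (j, m) enters as tau_mj = -tau_jm (delay antisymmetry).
    ``closure`` is |tau_jk + tau_km + tau_mj|.
    """

    neurons: tuple[int, int, int]
    delays: tuple[float, float, float]
    amplitudes: tuple[float, float, float]
    peak_indices: tuple[int, int, int]
    flagged: bool = False

    @property
    def closure(self) -> float:
        return float(abs(sum(self.delays)))


def enumerate_triangles(peak_graph: PeakGraph) -> list[CorrelationTriangle]:
    """Every combination of one surviving peak per pair, for every neuron
    triplet whose three pairs all carry at least one surviving peak.

    With n_jk, n_km and n_mj peaks on the three pairs this yields
    n_jk * n_km * n_mj triangles for the triplet.
    """
    groups = peak_graph.by_pair()
    # neurons that appear in at least one peak-carrying pair
    nodes = sorted({i for pair in groups for i in pair})
    peaks = peak_graph.peaks
    triangles: list[CorrelationTriangle] = []
    for j, k, m in itertools.combinations(nodes, 3):
        jk = groups.get((j, k))
        km = groups.get((k, m))
        jm = groups.get((j, m))
        if not (jk and km and jm):
            continue
        for i_jk, i_km, i_jm in itertools.product(jk, km, jm):
            p_jk, p_km, p_jm = peaks[i_jk], peaks[i_km], peaks[i_jm]
            triangles.append(
                CorrelationTriangle(
                    neurons=(j, k, m),
                    delays=(p_jk.tau, p_km.tau, -p_jm.tau),
                    amplitudes=(p_jk.amplitude, p_km.amplitude, p_jm.amplitude),
                    peak_indices=(i_jk, i_km, i_jm),
                )
            )
    return triangles


def flag_triangles(
    triangles: list[CorrelationTriangle], epsilon: float
) -> list[CorrelationTriangle]:
    """Mark triangles whose closure is strictly below epsilon (ms)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    for t in triangles:
        t.flagged = t.closure < epsilon
    return triangles


def _select_removal(
    peaks: list[CorrelationPeak],
    indices: tuple[int, int, int],
    grid_dt: float = 0.0,
) -> int:
    """Index of the peak to discard from a flagged triangle: minimum
    amplitude, ties broken by largest width (quantized to the lag grid),
    then largest |tau|, then lexicographically last pair (indirect peaks
    are lower, wider and later than direct ones)."""
    best = None
    best_key = None
    for i in indices:
        key = _victim_key(peaks[i], grid_dt)
        if best_key is None or key < best_key:
            best_key = key
            best = i
    return best


def _victim_key(p: CorrelationPeak, grid_dt: float = 0.0):
    """Static total order over peaks: the triangle victim is its minimum.

    Widths are quantized to the lag-grid step — sub-sample width
    differences are measurement noise and must not decide ties (on
    noise-free fixtures all widths agree up to float round-off and the
    tie should fall through to the |tau| rule).
    """
    width = round(p.width / grid_dt) if grid_dt > 0 else p.width
    return (p.amplitude, -width, -abs(p.tau), tuple(-x for x in p.pair), -p.tau)


def _prune_pass(graph: PeakGraph, epsilon: float) -> int:
    """One vectorized super-selection pass over the surviving peaks.

    Enumerates every peak combination of every triplet whose three pairs
    carry surviving peaks, flags combinations with closure < epsilon, and
    removes the minimum-rank (victim) peak of each.  Equivalent to
    visiting the flagged triangles one by one, because the victim order
    is a static property of the peaks.
    """
    peaks = graph.peaks
    groups = graph.by_pair()
    if not groups:
        return 0
    grid_dt = float(graph.parameters.get("dt", 0.0))
    alive = sorted({i for lst in groups.values() for i in lst})
    order = sorted(alive, key=lambda i: _victim_key(peaks[i], grid_dt))
    rank = {i: r for r, i in enumerate(order)}
    arr = {
        pair: (
            np.array(lst),
            np.array([peaks[i].tau for i in lst]),
            np.array([rank[i] for i in lst]),
        )
        for pair, lst in groups.items()
    }
    partners: dict[int, set[int]] = {}
    for a, b in groups:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    victims: set[int] = set()
    for j in sorted(partners):
        for k in sorted(x for x in partners[j] if x > j):
            for m in sorted(x for x in (partners[j] & partners[k]) if x > k):
                i_jk, t_jk, r_jk = arr[(j, k)]
                i_km, t_km, r_km = arr[(k, m)]
                i_jm, t_jm, r_jm = arr[(j, m)]
                # cyclic orientation j -> k -> m -> j: tau_mj = -tau_jm
                closure = np.abs(
                    t_jk[:, None, None] + t_km[None, :, None]
                    - t_jm[None, None, :]
                )
                f1, f2, f3 = np.nonzero(closure < epsilon)
                if f1.size == 0:
                    continue
                ranks = np.stack([r_jk[f1], r_km[f2], r_jm[f3]])
                idx = np.stack([i_jk[f1], i_km[f2], i_jm[f3]])
                victims.update(
                    idx[ranks.argmin(axis=0), np.arange(f1.size)].tolist()
                )
    for v in victims:
        peaks[v].removed = True
        peaks[v].removal_reason = "triangle"
    return len(victims)


def prune_peaks(peak_graph: PeakGraph, epsilon: float) -> PeakGraph:
    """Apply the super-selection rule until a fixed point is reached.

    Every flagged triangle independently discards its minimum-amplitude
    peak (a no-op when that peak was already removed by another
    triangle).  Because the victim depends only on the triangle's own
    static amplitudes, the result is independent of processing order.
    Passes repeat on the surviving peaks until one removes nothing; a
    single pass already reaches the fixed point (any triangle left
    intact after a pass would have had its victim removed by that very
    pass), so the second pass only confirms it.  The output graph keeps
    every peak with its removal audit trail; no peak is ever added.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    out = peak_graph.copy()
    out.parameters["epsilon"] = epsilon
    while _prune_pass(out, epsilon):
        pass
    return out


def peaks_to_matrix(peak_graph: PeakGraph) -> ConnectivityMatrix:
    """Binary directed adjacency implied by the surviving peaks.

    Entry (j, k) is 1 iff some surviving peak implies tau_jk > 0: a stored
    (j, k) peak with positive lag, or equivalently a stored (k, j) peak
    with negative lag.  Peaks at exactly tau = 0 contribute nothing (their
    direction is undefined).
    """
    m = np.zeros((peak_graph.n_neurons, peak_graph.n_neurons), dtype=int)
    for p in peak_graph.surviving():
        j, k = p.pair
        if p.tau > 0:
            m[j, k] = 1
        elif p.tau < 0:
            m[k, j] = 1
    return ConnectivityMatrix(m)
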