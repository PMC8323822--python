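"""Readers and writers for the plain-text formats used by the toolbox.

Conventions: times are seconds on disk (milliseconds are used internally
for lags and delays), neuron ids are 0-based integers, and every CSV has
a header row.  Matrices carry neuron ids as both header row and index
column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from spikeconn.correlation import PeakGraph, CorrelationPeak
from spikeconn.matrices import ConnectivityMatrix, FrequencyMatrix
from spikeconn.synthetic import NetworkModel, SpikeTrainSet

__all__ = [
    "RunConfig",
    "read_spikes",
    "write_spikes",
    "read_truth",
    "write_truth",
    "read_adjacency",
    "write_adjacency",
    "read_frequency",
    "write_frequency",
    "write_peaks",
    "read_peaks",
    "write_triangles",
    "write_graphml",
]


@dataclass
class RunConfig:
    """Validated reconstruction configuration (YAML-loadable).

    Flags given on the command line override values loaded from a file.
    """

    profile: str = "sim"
    dt_ms: float = 0.1
    mode: str = "raw"
    T_values: list[float] = field(default_factory=list)
    sigma_values: list[float] = field(default_factory=list)
    epsilon: float | None = None
    d: float = 1.0
    min_prominence_frac: float = 0.05
    window_ms: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in ("sim", "mea"):
            raise ValueError("profile must be 'sim' or 'mea'")
        if self.mode not in ("raw", "pearson"):
            raise ValueError("mode must be 'raw' or 'pearson'")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if not 0 <= self.d <= 1:
            raise ValueError("d must lie in [0, 1]")
        if not 0 < self.min_prominence_frac <= 1:
            raise ValueError("min_prominence_frac must be in (0, 1]")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if any(t <= 0 for t in self.T_values) or any(s <= 0 for s in self.sigma_values):
            raise ValueError("T and sigma values must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.index[out.isna() & df[col].notna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines}")
    return out


def read_spikes(
    path: str | Path,
    duration: float | None = None,
    n_neurons: int | None = None,
    one_based: bool = False,
) -> SpikeTrainSet:
    """Read a spikes CSV (columns neuron_id, time_s).

    Unsorted rows are sorted with a warning; duration defaults to the last
    spike time plus one millisecond.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["neuron_id", "time_s"], path)
    ids = _numeric(df, "neuron_id", path).astype(int)
    times = _numeric(df, "time_s", path).astype(float)
    if one_based:
        ids = ids - 1
    if len(ids) and ids.min() < 0:
        raise ValueError(f"{path}: negative neuron id")
    n = int(ids.max()) + 1 if len(ids) else 0
    if n_neurons is not None:
        if n_neurons < n:
            raise ValueError(f"{path}: ids exceed declared n_neurons={n_neurons}")
        n = n_neurons
    if duration is None:
        duration = float(times.max()) + 1e-3 if len(times) else 1.0
    trains = []
    for i in range(n):
        t = times[ids == i].to_numpy()
        if t.size and np.any(np.diff(t) < 0):
            warnings.warn(f"{path}: spike times of neuron {i} were unsorted",
                          stacklevel=2)
        trains.append(np.unique(t))
    return SpikeTrainSet(n, trains, duration)


def write_spikes(trains: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        (i, t)
        for i in range(trains.n_neurons)
        for t in trains.spike_times[i]
    ]
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(path, index=False)


def read_truth(
    path: str | Path, n_neurons: int | None = None, one_based: bool = False
) -> NetworkModel:
    """Read an edge-list CSV (columns src, dst, weight, delay_ms)."""
    df = pd.read_csv(path)
    _require_columns(df, ["src", "dst", "weight", "delay_ms"], path)
    src = _numeric(df, "src", path).astype(int)
    dst = _numeric(df, "dst", path).astype(int)
    if one_based:
        src, dst = src - 1, dst - 1
    weight = _numeric(df, "weight", path)
    delay = _numeric(df, "delay_ms", path)
    edges = list(zip(src, dst, weight.astype(float), delay.astype(float)))
    n = max((max(s, d) for s, d, _w, _dl in edges), default=-1) + 1
    if n_neurons is not None:
        if n_neurons < n:
            raise ValueError(f"{path}: ids exceed declared n_neurons={n_neurons}")
        n = n_neurons
    return NetworkModel(n, edges)


def write_truth(model: NetworkModel, path: str | Path) -> None:
    pd.DataFrame(
        model.edges, columns=["src", "dst", "weight", "delay_ms"]
    ).to_csv(path, index=False)


def read_adjacency(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=int))


def write_adjacency(matrix: ConnectivityMatrix, path: str | Path) -> None:
    ids = range(matrix.n_neurons)
    pd.DataFrame(matrix.entries, index=ids, columns=ids).to_csv(path)


def read_frequency(path: str | Path, K: int | None = None) -> FrequencyMatrix:
    """Read a frequency matrix; K is inferred as the smallest denominator
    (<= 1024) under which all entries are multiples of 1/K, unless given."""
    df = pd.read_csv(path, index_col=0)
    f = df.to_numpy(dtype=float)
    if K is None:
        for cand in range(1, 1025):
            if np.allclose(f * cand, np.round(f * cand), atol=1e-6):
                K = cand
                break
        else:
            raise ValueError(f"{path}: could not infer grid size K")
    return FrequencyMatrix(f, K=K)


def write_frequency(freq: FrequencyMatrix, path: str | Path) -> None:
    ids = range(freq.n_neurons)
    pd.DataFrame(freq.entries, index=ids, columns=ids).to_csv(
        path, float_format="%.8f"
    )


def write_peaks(peak_graph: PeakGraph, path: str | Path) -> None:
    rows = [
        (p.pair[0], p.pair[1], p.tau, p.amplitude, p.width, p.removed,
         p.removal_reason)
        for p in peak_graph.peaks
    ]
    pd.DataFrame(
        rows,
        columns=["j", "k", "tau_ms", "amplitude", "width_ms", "removed",
                 "removal_reason"],
    ).to_csv(path, index=False)


def read_peaks(path: str | Path, n_neurons: int) -> PeakGraph:
    df = pd.read_csv(path)
    _require_columns(df, ["j", "k", "tau_ms", "amplitude", "width_ms"], path)
    peaks = [
        CorrelationPeak(
            pair=(int(r.j), int(r.k)), tau=float(r.tau_ms),
            amplitude=float(r.amplitude), width=float(r.width_ms),
            removed=bool(getattr(r, "removed", False)),
            removal_reason=str(getattr(r, "removal_reason", "") or ""),
        )
        for r in df.itertuples()
    ]
    return PeakGraph(n_neurons, peaks)


def write_triangles(
    triangles,
    path: str | Path,
    peak_graph: PeakGraph | None = None,
) -> None:
    """Triangle audit CSV: one row per correlation triangle.

    When the (pruned) ``peak_graph`` is supplied, the ``removed_pair``
    column names the pair whose peak the super-selection discarded from
    that triangle (empty if none of its peaks was removed).
    """
    rows = []
    for t in triangles:
        removed_pair = ""
        if peak_graph is not None:
            for i in t.peak_indices:
                if peak_graph.peaks[i].removed:
                    j, k = peak_graph.peaks[i].pair
                    removed_pair = f"{j}-{k}"
                    break
        rows.append((
            *t.neurons, *t.delays, t.closure, t.flagged, removed_pair,
        ))
    pd.DataFrame(
        rows,
        columns=["j", "k", "m", "tau_jk", "tau_km", "tau_mj",
                 "closure_ms", "flagged", "removed_pair"],
    ).to_csv(path, index=False)


def write_graphml(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Export the directed graph with per-node in/out degree attributes."""
    g = nx.from_numpy_array(matrix.entries, create_using=nx.DiGraph)
    for node in g.nodes:
        g.nodes[node]["in_degree"] = int(matrix.entries[:, node].sum())
        g.nodes[node]["out_degree"] = int(matrix.entries[node, :].sum())
    nx.write_graphml(g, path)
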