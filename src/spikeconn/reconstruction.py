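"""Full-pipeline reconstruction across a (T, sigma) parameter grid.

A single parameter point p = (T, sigma) yields one binary connectivity
matrix M_p: detect peaks, prune closing triangles at threshold epsilon,
convert the survivors to directed edges.  True connections are detected
consistently across points (their peak does not move), while false
positives fluctuate from point to point, so the per-edge occurrence
frequency

    f_jk = (1/K) sum_p M_p[j, k]

concentrates near 1 for real edges and near 1/K for spurious ones.  A
discrimination threshold d in [0, 1] applied to f yields the final
effective connectivity; d = 1 demands unanimity across the grid and is
the shipped default.

Two grids are provided: ``SIMULATION_PROFILE`` (sub-millisecond delays,
as in the bundled Izhikevich benchmark) and ``MEA_PROFILE`` (cortical
6-14 ms conduction delays, for in vitro multi-electrode recordings).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from spikeconn.correlation import (
    DEFAULT_BIN_MS,
    DEFAULT_PROMINENCE_FRAC,
    PeakGraph,
    _detect_with_reference,
    _pair_values,
    _window_bins,
)
from spikeconn.matrices import ConnectivityMatrix, FrequencyMatrix
from spikeconn.superselection import peaks_to_matrix, prune_peaks
from spikeconn.synthetic import SpikeTrainSet

__all__ = [
    "ParameterPoint",
    "ConnectivityMatrix",
    "FrequencyMatrix",
    "SIMULATION_PROFILE",
    "MEA_PROFILE",
    "build_grid",
    "reconstruct",
    "threshold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterPoint:
    """One point of the reconstruction grid.

    ``T`` (ms) is the half-width of the peak-search window (-T, +T),
    ``sigma`` (ms) the Gaussian smoothing sd, ``epsilon`` (ms) the
    triangle-closure threshold shared across the grid.
    """

    T: float
    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.T <= 0 or self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("T, sigma and epsilon must all be positive")
        if self.T <= self.epsilon:
            warnings.warn(
                f"T={self.T} ms does not exceed epsilon={self.epsilon} ms; "
                "the closure test may out-range the peak search window",
                stacklevel=2,
            )


def build_grid(
    T_values: list[float],
    sigma_values: list[float],
    epsilon: float,
) -> list[ParameterPoint]:
    """Cartesian product of T and sigma values with a shared epsilon."""
    if not T_values or not sigma_values:
        raise ValueError("T_values and sigma_values must be non-empty")
    return [
        ParameterPoint(T, sigma, epsilon)
        for T, sigma in itertools.product(T_values, sigma_values)
    ]


#: 9-point grid used with the Izhikevich benchmark (epsilon = 0.7 ms).
SIMULATION_PROFILE = build_grid([2.25, 3.5, 4.5], [0.013, 0.1, 0.63], 0.7)
#: 9-point grid for cortical MEA recordings (epsilon = 3 ms).
MEA_PROFILE = build_grid([16.0, 17.5, 20.0], [0.4, 0.55, 0.7], 3.0)


def reconstruct(
    trains: SpikeTrainSet,
    grid: list[ParameterPoint] = SIMULATION_PROFILE,
    dt: float = DEFAULT_BIN_MS,
    mode: str = "raw",
    min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> tuple[FrequencyMatrix, list[ConnectivityMatrix]]:
    """Run peak detection + super-selection at every grid point.

    Returns the frequency matrix f together with the per-point binary
    matrices M_p (in grid order) for auditing.  A point at which no peak
    is detected contributes an all-zero matrix.

    In ``raw`` mode the per-pair correlations are computed once on the
    widest window any point needs and sliced per point, which is exact:
    peak search inside (-T, +T) only sees lags within T plus the kernel
    support, all of which the slice retains.
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    active = trains.active_neurons()
    if len(active) < 2:
        raise ValueError("need at least 2 active neurons")
    n = trains.n_neurons

    matrices: list[ConnectivityMatrix] = []
    L_max = max(_window_bins(p.T, p.sigma, dt) for p in grid)
    pair_corr = _pair_values(trains, dt, L_max, mode)
    for point in grid:
        L = _window_bins(point.T, point.sigma, dt)
        lags = np.arange(-L, L + 1) * dt
        sl = slice(L_max - L, L_max + L + 1)
        peaks = []
        for (j, k), full in pair_corr.items():
            peaks.extend(
                _detect_with_reference(full[sl], lags, (j, k), mode,
                                       point.T, point.sigma,
                                       min_prominence_frac)
            )
        graph = PeakGraph(n, peaks, {"T": point.T, "sigma": point.sigma,
                                     "dt": dt, "mode": mode})
        matrices.append(_point_matrix(graph, point))

    stack = np.stack([m.entries for m in matrices])
    freq = FrequencyMatrix(stack.mean(axis=0), K=len(grid))
    return freq, matrices


def _point_matrix(graph: PeakGraph, point: ParameterPoint) -> ConnectivityMatrix:
    if not graph.peaks:
        logger.info("no peaks detected at T=%s sigma=%s", point.T, point.sigma)
        return ConnectivityMatrix(np.zeros((graph.n_neurons,) * 2, dtype=int))
    pruned = prune_peaks(graph, point.epsilon)
    return peaks_to_matrix(pruned)


def threshold(freq: FrequencyMatrix, d: float) -> ConnectivityMatrix:
    """Edges asserted by at least a fraction d of the grid points.

    Entry (j, k) is 1 iff f_jk >= d and f_jk > 0, so d = 0 returns every
    edge any point saw and d = 1 requires unanimity.
    """
    if not 0 <= d <= 1:
        raise ValueError("d must lie in [0, 1]")
    f = freq.entries
    return ConnectivityMatrix(((f >= d) & (f > 0)).astype(int))
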