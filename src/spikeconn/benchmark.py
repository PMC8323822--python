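"""Izhikevich-network validation protocol.

One benchmark run generates a sparse random excitatory network (mean
out-degree 2, preserved across sizes), simulates spontaneous noise-driven
activity, reconstructs the effective connectivity on the 9-point
simulation grid (T in {2.25, 3.5, 4.5} ms, sigma in {0.013, 0.1, 0.63}
ms, epsilon = 0.7 ms) in Pearson mode, and scores the result against the
generating network at each discrimination threshold d in {1/9, ..., 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spikeconn.evaluation import EvaluationResult, score
from spikeconn.matrices import FrequencyMatrix
from spikeconn.reconstruction import SIMULATION_PROFILE, reconstruct, threshold
from spikeconn.synthetic import (
    NetworkModel,
    SpikeTrainSet,
    generate_random_network,
    simulate_izhikevich,
)

__all__ = ["BenchmarkRun", "run_benchmark", "benchmark_recording"]

#: Correlogram bin width (ms) used by the benchmark; matches the
#: simulator's integration step so one bin holds at most a few spikes.
BENCH_BIN_MS = 0.25
BENCH_MODE = "pearson"


@dataclass
class BenchmarkRun:
    """Scores of one simulated network across discrimination thresholds."""

    model: NetworkModel
    freq: FrequencyMatrix
    per_point: list[EvaluationResult]
    per_d: dict[float, EvaluationResult]

    @property
    def at_unanimity(self) -> EvaluationResult:
        return self.per_d[max(self.per_d)]


def benchmark_recording(
    n_neurons: int, seed: int, duration: float = 300.0
) -> tuple[NetworkModel, SpikeTrainSet]:
    """Generate one benchmark network and its simulated recording."""
    model = generate_random_network(n_neurons, mean_out_degree=2.0,
                                    seed=seed)
    trains = simulate_izhikevich(model, duration, seed=seed + 1)
    return model, trains


def run_benchmark(
    n_neurons: int,
    n_networks: int,
    seed: int = 0,
    duration: float = 300.0,
    grid=SIMULATION_PROFILE,
) -> list[BenchmarkRun]:
    """Run the full protocol over ``n_networks`` random networks."""
    runs = []
    K = len(grid)
    for i in range(n_networks):
        model, trains = benchmark_recording(n_neurons, seed + 1000 * i,
                                            duration)
        freq, mats = reconstruct(trains, grid, dt=BENCH_BIN_MS,
                                 mode=BENCH_MODE)
        per_point = [score(m, model) for m in mats]
        per_d = {
            (q + 1) / K: score(threshold(freq, (q + 1) / K), model)
            for q in range(K)
        }
        runs.append(BenchmarkRun(model, freq, per_point, per_d))
    return runs


def mean_delta(runs: list[BenchmarkRun], d: float = 1.0) -> float:
    """Mean confidence indicator Delta (percent) at threshold d."""
    return 100.0 * float(np.mean([r.per_d[d].delta for r in runs]))


def mean_acc(runs: list[BenchmarkRun], d: float) -> float:
    """Mean accuracy ACC (percent) at threshold d."""
    return 100.0 * float(np.mean([r.per_d[d].acc for r in runs]))
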