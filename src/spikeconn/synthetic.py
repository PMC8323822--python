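"""Ground-truth networks and synthetic spike recordings.

Two generators live here.  :func:`simulate_izhikevich` integrates a sparse
random network of Izhikevich point neurons driven by per-step Gaussian
noise current, producing recordings that mimic spontaneously active
in vitro cultures (sustained firing with burst-like episodes).
:func:`generate_delta_motif` builds tiny deterministic spike motifs
(chains, common-input / common-output forks, single pairs) whose
cross-correlation structure is known in closed form; these serve as exact
oracles for the correlation and super-selection stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "IzhikevichParams",
    "NetworkModel",
    "SpikeTrainSet",
    "REGULAR_SPIKING",
    "INTRINSICALLY_BURSTING",
    "generate_random_network",
    "simulate_izhikevich",
    "generate_delta_motif",
]

SPIKE_CUTOFF_MV = 30.0


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of one Izhikevich point neuron.

    ``a`` (1/ms) sets the recovery-variable time scale, ``b``
    (dimensionless) its sensitivity to the membrane potential, ``c`` (mV)
    the post-spike reset potential and ``d_reset`` (mV) the post-spike
    recovery increment.  ``d_reset`` is named to avoid a clash with the
    discrimination threshold ``d`` used at reconstruction time.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d_reset: float = 8.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"recovery time scale a must be positive, got {self.a}")
        if self.c >= SPIKE_CUTOFF_MV:
            raise ValueError(
                f"reset potential c={self.c} must lie below the spike cutoff "
                f"({SPIKE_CUTOFF_MV} mV)"
            )

    def resting_state(self) -> tuple[float, float]:
        """Stable fixed point (v*, u*) of the noise-free subthreshold dynamics.

        Solves 0.04 v^2 + (5 - b) v + 140 = 0 and returns the lower
        (stable) root together with u* = b v*.  Starting simulations here
        makes the zero-input network exactly quiescent.
        """
        disc = (5.0 - self.b) ** 2 - 4 * 0.04 * 140.0
        if disc < 0:  # no subthreshold equilibrium: tonically active cell
            v_star = -65.0
        else:
            v_star = ((self.b - 5.0) - math.sqrt(disc)) / 0.08
        return v_star, self.b * v_star


#: Cortical excitatory phenotypes from the standard Izhikevich taxonomy.
REGULAR_SPIKING = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d_reset=8.0)
INTRINSICALLY_BURSTING = IzhikevichParams(a=0.02, b=0.2, c=-55.0, d_reset=4.0)


@dataclass
class NetworkModel:
    """Ground-truth directed weighted graph with per-edge conduction delays.

    ``edges`` holds ``(src, dst, weight_mv, delay_ms)`` tuples; ``n_c`` is
    the number of true edges.  Self-loops are forbidden.
    """

    n_neurons: int
    edges: list[tuple[int, int, float, float]]
    neuron_params: list[IzhikevichParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.neuron_params:
            self.neuron_params = [REGULAR_SPIKING] * self.n_neurons
        if len(self.neuron_params) != self.n_neurons:
            raise ValueError("one IzhikevichParams entry per neuron required")
        seen = set()
        for src, dst, _w, delay in self.edges:
            if src == dst:
                raise ValueError(f"self-loop on neuron {src}")
            if not (0 <= src < self.n_neurons and 0 <= dst < self.n_neurons):
                raise ValueError(f"edge ({src},{dst}) outside [0, {self.n_neurons})")
            if delay <= 0:
                raise ValueError(f"edge ({src},{dst}) has non-positive delay {delay}")
            seen.add((src, dst))

    @property
    def n_c(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Binary directed adjacency matrix (row = source, column = target)."""
        adj = np.zeros((self.n_neurons, self.n_neurons), dtype=int)
        for src, dst, _w, _d in self.edges:
            adj[src, dst] = 1
        return adj

    def edge_set(self) -> set[tuple[int, int]]:
        return {(src, dst) for src, dst, _w, _d in self.edges}


@dataclass
class SpikeTrainSet:
    """Spike times per neuron over a fixed recording duration.

    Times are in seconds, sorted strictly increasing within each neuron and
    contained in ``[0, duration)``.  This is the universal input of the
    reconstruction pipeline.
    """

    n_neurons: int
    spike_times: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        if len(self.spike_times) != self.n_neurons:
            raise ValueError("one spike-time array per neuron required")
        clean = []
        for i, times in enumerate(self.spike_times):
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValueError(
                    f"neuron {i} has spikes outside [0, {self.duration}) s"
                )
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"neuron {i} spike times not strictly increasing")
            clean.append(t)
        self.spike_times = clean

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))

    def firing_rates(self) -> np.ndarray:
        """Mean rate per neuron in Hz."""
        return np.array([t.size / self.duration for t in self.spike_times])

    def active_neurons(self) -> list[int]:
        return [i for i, t in enumerate(self.spike_times) if t.size > 0]


def generate_random_network(
    n_neurons: int,
    mean_out_degree: float = 2.0,
    delay_range: tuple[float, float] = (0.8, 1.0),
    weight_range: tuple[float, float] = (50.0, 70.0),
    seed: int = 0,
    bursting_fraction: float = 0.0,
) -> NetworkModel:
    """Draw a sparse directed Erdos-Renyi-style network.

    Exactly ``ceil(mean_out_degree * n_neurons)`` directed edges are drawn
    uniformly without replacement over the ordered off-diagonal pairs, so
    the expected in- and out-degree per node equals ``mean_out_degree``
    independent of network size (the sparse regime n_c << n(n-1)).
    Per-edge conduction delays and excitatory synaptic weights are uniform
    in their ranges.  ``bursting_fraction`` assigns that share of neurons
    the intrinsically-bursting phenotype (the default network is all
    regular spiking: doublet-firing cells imprint inter-spike-interval
    echoes on the correlograms that have nothing to do with connectivity).

    Parameters
    ----------
    delay_range : (ms, ms)
        Axonal + synaptic conduction delay bounds.  Together with the
        ~0.6-0.8 ms spike-initiation latency of a strongly driven neuron,
        the default places every direct correlation peak near 1.5 ms —
        inside the shortest peak-search window of the shipped simulation
        profile (T = 2.25 ms), mirroring the rule that the search window
        should span 2-3 times the effective delay.
    weight_range : (mV, mV)
        Postsynaptic depolarization per presynaptic spike.  The default
        is strongly suprathreshold so that transmission latency is short
        and tightly distributed; unreliability comes from the synaptic
        release probability of the simulator, not from weak coupling.
    """
    if n_neurons < 3:
        raise ValueError("need at least 3 neurons")
    n_edges = math.ceil(mean_out_degree * n_neurons)
    n_pairs = n_neurons * (n_neurons - 1)
    if n_edges > n_pairs:
        raise ValueError(
            f"requested {n_edges} edges but only {n_pairs} ordered pairs exist"
        )
    rng = np.random.default_rng(seed)
    # ordered off-diagonal pairs indexed 0 .. n(n-1)-1
    flat = rng.choice(n_pairs, size=n_edges, replace=False)
    edges = []
    for idx in sorted(flat.tolist()):
        src, rem = divmod(idx, n_neurons - 1)
        dst = rem if rem < src else rem + 1
        delay = rng.uniform(*delay_range)
        weight = rng.uniform(*weight_range)
        edges.append((src, dst, float(weight), float(delay)))
    n_burst = int(round(bursting_fraction * n_neurons))
    phenotypes = np.array([REGULAR_SPIKING] * n_neurons, dtype=object)
    burst_idx = rng.choice(n_neurons, size=n_burst, replace=False)
    for i in burst_idx:
        phenotypes[i] = INTRINSICALLY_BURSTING
    return NetworkModel(n_neurons, edges, list(phenotypes))


@njit(cache=False)
def _euler_kernel(
    a, b, c, d_reset, v0, u0,
    n_steps, dt,
    noise_amp, drive,
    out_offsets, out_dst, out_weight, out_delay_steps,
    delay_jitter_steps, release_prob, ring_len, seed,
):  # pragma: no cover - exercised through simulate_izhikevich
    n = a.shape[0]
    np.random.seed(seed)
    v = v0.copy()
    u = u0.copy()
    ring = np.zeros((ring_len, n))
    cap = 4096
    spike_neuron = np.empty(cap, dtype=np.int64)
    spike_time = np.empty(cap, dtype=np.float64)
    n_spikes = 0
    for step in range(n_steps):
        row = step % ring_len
        for i in range(n):
            current = drive[i] + ring[row, i]
            if noise_amp > 0.0:
                current += noise_amp * np.random.standard_normal()
            dv = 0.04 * v[i] * v[i] + 5.0 * v[i] + 140.0 - u[i] + current
            du = a[i] * (b[i] * v[i] - u[i])
            v_prev = v[i]
            v[i] += dt * dv
            u[i] += dt * du
            ring[row, i] = 0.0
            if not np.isfinite(v[i]):
                return spike_neuron[:0], spike_time[:0], -1
            if v[i] >= 30.0:
                if n_spikes == cap:
                    cap *= 2
                    new_n = np.empty(cap, dtype=np.int64)
                    new_t = np.empty(cap, dtype=np.float64)
                    new_n[:n_spikes] = spike_neuron[:n_spikes]
                    new_t[:n_spikes] = spike_time[:n_spikes]
                    spike_neuron = new_n
                    spike_time = new_t
                # sub-step threshold-crossing time by linear interpolation,
                # so spike times are not quantized to the integration grid
                frac = (30.0 - v_prev) / (v[i] - v_prev)
                if frac < 0.0:
                    frac = 0.0
                spike_neuron[n_spikes] = i
                spike_time[n_spikes] = (step + frac) * dt
                n_spikes += 1
                v[i] = c[i]
                u[i] += d_reset[i]
                # schedule synaptic impulses on every outgoing edge;
                # stochastic release and per-delivery timing jitter model
                # quantal synaptic variability
                for e in range(out_offsets[i], out_offsets[i + 1]):
                    if release_prob < 1.0 and np.random.random() >= release_prob:
                        continue
                    k = out_dst[e]
                    arrive = step + out_delay_steps[e]
                    if delay_jitter_steps > 0.0:
                        shift = int(round(delay_jitter_steps
                                          * np.random.standard_normal()))
                        clip = int(4.0 * delay_jitter_steps) + 1
                        if shift > clip:
                            shift = clip
                        elif shift < -clip:
                            shift = -clip
                        arrive += shift
                        if arrive <= step:
                            arrive = step + 1
                    ring[arrive % ring_len, k] += out_weight[e] / dt
    return spike_neuron[:n_spikes], spike_time[:n_spikes], 0


def simulate_izhikevich(
    model: NetworkModel,
    duration: float,
    dt: float = 0.25,
    noise_amplitude: float = 6.0,
    seed: int = 0,
    external_current: float | np.ndarray = 0.0,
    delay_jitter_sd: float = 0.35,
    release_prob: float = 0.5,
) -> SpikeTrainSet:
    """Integrate the network with forward Euler and record spike times.

    Dynamics per neuron: ``v' = 0.04 v^2 + 5 v + 140 - u + I`` and
    ``u' = a (b v - u)``; on ``v >= 30`` mV a spike is recorded, ``v`` is
    reset to ``c`` and ``u`` incremented by ``d_reset``.  Each presynaptic
    spike on an edge of weight ``w`` (mV) and delay ``delta`` (ms) injects a
    current impulse of area ``w`` into the target ``delta`` ms after the
    spike (depolarizing it by ~``w`` mV independent of the step size),
    with an independent Gaussian perturbation of sd ``delay_jitter_sd``
    ms per delivery that models synaptic release-timing variability —
    the phase noise that makes indirect correlation peaks lower and
    wider than direct ones.  Each delivery succeeds with probability
    ``release_prob`` (quantal release failure); sub-unity release keeps
    the network out of the fully synchronized avalanche regime, in which
    shared-input correlations would rival direct ones.  ``I`` additionally contains
    independent zero-mean Gaussian noise of standard deviation
    ``noise_amplitude`` per neuron per step, plus the optional constant
    ``external_current`` drive.

    Parameters
    ----------
    duration : seconds (>= 1 s)
    dt : integration step in ms (<= 1 ms)
    seed : RNG seed; identical inputs and seed give bitwise-identical output.

    Raises
    ------
    FloatingPointError
        If the state diverges (unstable dt / weight combination).
    """
    if dt > 1.0 or dt <= 0:
        raise ValueError(f"dt must be in (0, 1] ms, got {dt}")
    if duration < 1.0:
        raise ValueError(f"duration must be >= 1 s, got {duration}")
    n = model.n_neurons
    a = np.array([p.a for p in model.neuron_params])
    b = np.array([p.b for p in model.neuron_params])
    c = np.array([p.c for p in model.neuron_params])
    d_reset = np.array([p.d_reset for p in model.neuron_params])
    rest = [p.resting_state() for p in model.neuron_params]
    v0 = np.array([r[0] for r in rest])
    u0 = np.array([r[1] for r in rest])
    drive = np.broadcast_to(np.asarray(external_current, dtype=float), (n,)).copy()

    # outgoing edges in CSR layout, delays rounded to integration steps
    order = sorted(range(len(model.edges)), key=lambda e: model.edges[e][0])
    out_dst = np.array(
        [model.edges[e][1] for e in order] or [0], dtype=np.int64
    )
    out_weight = np.array([model.edges[e][2] for e in order] or [0.0])
    out_delay_steps = np.array(
        [max(1, int(round(model.edges[e][3] / dt))) for e in order] or [1],
        dtype=np.int64,
    )
    out_offsets = np.zeros(n + 1, dtype=np.int64)
    for e in order:
        out_offsets[model.edges[e][0] + 1] += 1
    out_offsets = np.cumsum(out_offsets)

    if delay_jitter_sd < 0:
        raise ValueError("delay_jitter_sd must be >= 0")
    if not 0 < release_prob <= 1:
        raise ValueError("release_prob must be in (0, 1]")
    delay_jitter_steps = delay_jitter_sd / dt
    max_delay = int(out_delay_steps.max()) if len(model.edges) else 1
    ring_len = max_delay + int(4.0 * delay_jitter_steps) + 3
    n_steps = int(round(duration * 1000.0 / dt))

    spike_neuron, spike_ms, status = _euler_kernel(
        a, b, c, d_reset, v0, u0, n_steps, dt,
        float(noise_amplitude), drive,
        out_offsets, out_dst, out_weight, out_delay_steps,
        delay_jitter_steps, float(release_prob), ring_len,
        int(seed) & 0x7FFFFFFF,
    )
    if status != 0:
        raise FloatingPointError(
            "membrane potential diverged; reduce dt or synaptic weights"
        )
    trains: list[np.ndarray] = []
    times_s = spike_ms / 1000.0
    for i in range(n):
        trains.append(np.sort(times_s[spike_neuron == i]))
    return SpikeTrainSet(n, trains, duration)


def generate_delta_motif(
    motif: str,
    delays: list[float],
    event_rate: float = 5.0,
    jitter_sd: float = 0.0,
    duration: float = 60.0,
    seed: int = 0,
) -> tuple[SpikeTrainSet, NetworkModel]:
    """Deterministic spike-motif fixture with known correlation structure.

    A Poisson stream of "events" drives the motif root; every downstream
    neuron copies each event shifted by the cumulative delay along its
    path, plus independent Gaussian jitter of sd ``jitter_sd`` per
    traversed edge.  Longer paths therefore accumulate phase noise, which
    is exactly the property the super-selection rule exploits (indirect
    peaks are lower and wider).

    Motifs
    ------
    ``chain``          0 -> 1 -> ... with one delay per edge.
    ``common_input``   0 -> i for i = 1..len(delays) (marrying parents).
    ``common_output``  i -> sink for i = 0..len(delays)-1; the sink fires
                       once per event, each source ``delays[i]`` ms earlier.
    ``pair``           a single edge 0 -> 1.

    Returns the spike trains together with the true motif as a
    :class:`NetworkModel` (unit weights).
    """
    delays_arr = np.asarray(delays, dtype=float)
    if np.any(delays_arr <= 0):
        raise ValueError("delays must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    # leave head/tail margins so shifted copies stay inside the recording
    margin = (delays_arr.sum() + 6 * jitter_sd * max(1, len(delays_arr))) / 1000.0 + 0.01
    n_events = rng.poisson(event_rate * duration)
    events = np.sort(rng.uniform(margin, duration - margin, size=n_events))

    def jitter(size: int) -> np.ndarray:
        if jitter_sd == 0:
            return np.zeros(size)
        return rng.normal(0.0, jitter_sd, size=size) / 1000.0

    if motif == "chain":
        n = len(delays_arr) + 1
        trains = [events.copy()]
        t = events.copy()
        for d in delays_arr:
            t = t + d / 1000.0 + jitter(t.size)
            trains.append(t.copy())
        edges = [(i, i + 1, 1.0, float(delays_arr[i])) for i in range(len(delays_arr))]
    elif motif == "common_input":
        n = len(delays_arr) + 1
        trains = [events.copy()]
        for d in delays_arr:
            trains.append(events + d / 1000.0 + jitter(events.size))
        edges = [(0, i + 1, 1.0, float(delays_arr[i])) for i in range(len(delays_arr))]
    elif motif == "common_output":
        n = len(delays_arr) + 1
        sink = len(delays_arr)
        trains = [events - d / 1000.0 + jitter(events.size) for d in delays_arr]
        trains.append(events.copy())
        edges = [(i, sink, 1.0, float(delays_arr[i])) for i in range(len(delays_arr))]
    elif motif == "pair":
        if len(delays_arr) != 1:
            raise ValueError("pair motif takes exactly one delay")
        n = 2
        trains = [events.copy(), events + delays_arr[0] / 1000.0 + jitter(events.size)]
        edges = [(0, 1, 1.0, float(delays_arr[0]))]
    else:
        raise ValueError(f"unknown motif {motif!r}")

    clipped = [np.unique(t[(t >= 0) & (t < duration)]) for t in trains]
    model = NetworkModel(n, edges)
    return SpikeTrainSet(n, clipped, duration), model
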