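# Methods

## The reconstruction problem

Given only the spike times of `n` simultaneously recorded neurons, we
want the *effective* connectivity: the set of directed synaptic links
that actually carried causal influence during the recording.  Pairwise
statistics alone cannot provide this — a cross-correlogram peak between
two neurons may reflect a direct synapse, a multi-neuron pathway
(indirect link), or a shared input or output (apparent link).

`spikeconn` implements a correlation-triangle approach:

1. **Correlation peaks.**  Spike trains are binned (default 0.1 ms) and
   the linear (zero-padded) cross-correlation
   `R_jk(τ) = Σ_t s_j(t) s_k(t+τ)` is computed for every unordered pair
   `j < k` (by `R_jk(τ) = R_kj(−τ)` nothing is lost).  The full-signal
   computation uses the FFT correlation theorem; the production path
   evaluates the identical quantity sparsely from the occupied bins,
   restricted to the lags actually searched.  After Gaussian smoothing
   (sd σ, truncated at 4σ, edge-renormalized) local maxima inside the
   search window `(−T, +T)` give a list of peaks, each with a signed
   delay τ (sub-bin position by parabolic interpolation), an amplitude,
   and a full width at half prominence.  A peak with τ > 0 means `j`
   leads `k`.
2. **Super-selection.**  For every neuron triplet and every combination
   of one peak per pair, the cyclic delay sum `τ_jk + τ_km + τ_mj` is
   formed.  If its magnitude falls below the closure threshold ε, one of
   the three correlations is the combination of the other two; since
   phase noise accumulates along longer paths, the dependent peak is the
   one with the smallest amplitude, and it is discarded.  Exact
   amplitude ties (noise-free fixtures) fall back to largest width, then
   largest |τ|, then lexicographically last pair.
3. **Parameter-grid voting.**  Steps 1–2 run at every point of a small
   `(T, σ)` grid (shared ε).  True edges produce a stable peak at every
   point; spurious survivors move around.  The per-edge detection
   frequency `f_jk` across the `K` grid points is thresholded at a
   discrimination level `d`; the shipped default `d = 1` keeps only
   unanimous edges.

## Key algorithmic choices

* **Independent triangle removals.**  Each flagged triangle discards its
  minimum-amplitude peak regardless of whether another triangle already
  removed one of its members.  The closure of a triangle is evidence on
  its own: under a skip-on-overlap rule, removing a 2-hop peak dissolves
  the triangles that explain 3-hop peaks, which then survive as false
  positives.  A useful corollary is that the victim choice depends only
  on a static total order over peaks, so pruning is order-independent
  and provably reaches its fixed point in a single pass; the
  implementation exploits this with a vectorized pass (the loop that
  re-checks for a fixed point remains, and terminates immediately).
* **Reference amplitudes.**  Peak *detection* uses each grid point's own
  smoothing σ, but the amplitude entering the triangle comparison is
  re-measured on a fixed, lightly smoothed reference correlogram
  (σ_ref = 0.25 ms).  A Gaussian filter of sd σ attenuates a narrow
  direct peak by far more than a broad indirect one, so amplitudes read
  off a heavily smoothed curve can invert the discrimination ordering;
  the σ-independent amplitude also makes the victim choice identical
  across grid points, which is what allows true edges to reach `f = 1`.
* **Permissive peak detection.**  The prominence threshold is 5 % of the
  window's dynamic range.  Spurious maxima admitted here are cleaned up
  by the super-selection and the frequency vote; a direct peak rejected
  at detection time is unrecoverable.  There is no absolute amplitude
  criterion.
* **Pearson mode.**  `ρ(τ)` of the overlapping lag-shifted segments
  (computed exactly via prefix sums over occupied bins) replaces the raw
  product sum when firing rates are heterogeneous or bursty: raw
  amplitudes scale with the joint rate of the pair, which corrupts
  between-pair amplitude comparisons inside a triangle.  The Izhikevich
  benchmark uses this mode; `raw` is the API default.
* **Strictness conventions.**  Closure test `< ε` strict; threshold
  `f ≥ d` with the additional requirement `f > 0` so `d = 0` means
  "seen by at least one point"; τ = 0 peaks are kept for triangle
  arithmetic but never yield a directed edge.

## Parameters

| name | default | units | role |
|------|---------|-------|------|
| `dt` (binning) | 0.1 (0.25 in the benchmark) | ms | correlogram lag resolution |
| `T` | grid {2.25, 3.5, 4.5} (sim) / {16, 17.5, 20} (MEA) | ms | peak search half-window |
| `σ` | grid {0.013, 0.1, 0.63} (sim) / {0.4, 0.55, 0.7} (MEA) | ms | smoothing sd |
| `ε` | 0.7 (sim) / 3.0 (MEA) | ms | triangle closure threshold; ≈ mean peak width (`suggest_epsilon`) |
| `d` | 1.0 | — | fraction of grid points that must assert an edge |
| `min_prominence_frac` | 0.05 | — | detection threshold |

`T` should span 2–3× the expected effective delay (conduction plus
spike-initiation latency); σ spans "no smoothing" to roughly the peak
width; ε tracks the variance of the delays and is well approximated by
the mean detected peak width.

## The synthetic benchmark

`spikeconn.synthetic` provides ground truth at two levels.

**Delta motifs** (chains, common-input/-output forks, pairs) emit Poisson
events whose downstream copies are shifted by exact delays plus optional
per-edge Gaussian jitter.  They make every stage's expected output
computable by hand and are used as oracles throughout the test suite.
A zero-jitter fork is spike-for-spike identical to a zero-jitter chain,
so only jittered forks are distinguishable — indeed the phase-noise
accumulation along paths is precisely the physical signal the
super-selection exploits.

**Izhikevich networks** emulate spontaneously active in vitro cultures:
sparse random digraphs (mean in/out degree 2 at every size, i.e., the
sparse regime `n_c ≪ n(n−1)`), all-excitatory quadratic
integrate-and-fire neurons (`v' = 0.04v² + 5v + 140 − u + I`,
`u' = a(bv − u)`, reset at 30 mV), forward-Euler at 0.25 ms with
threshold-crossing interpolation so spike times are not quantized to the
grid, and an independent Gaussian noise current per neuron per step.
Synapses are strong (50–70 mV depolarization, giving a short and tightly
distributed spike-initiation latency of ~0.6–0.8 ms), unreliable
(release probability 0.5), and jittered (0.35 ms sd per delivery), with
conduction delays of 0.8–1.0 ms.  This combination is what places the
simulator in the operating regime the method expects:

* effective peak delays ≈ 1.5 ms, inside the shortest search window of
  the simulation grid (T = 2.25 ms);
* release failures make shared-input coincidences scale as `p²` against
  `p` for direct ones, keeping apparent peaks weaker than direct peaks
  (with reliable synapses they rival or exceed them and no amplitude
  rule can order the triangle);
* release failures also hold the cascade branching ratio near 1, so the
  network produces burst-like episodes without locking into fully
  synchronized avalanches;
* delivery jitter gives direct peaks a finite width that grows along
  multi-hop paths — the lower-and-wider signature of indirect links.

Neuron phenotype defaults to regular spiking for all cells
(`bursting_fraction` adds intrinsically bursting cells; their doublet
inter-spike interval imprints connectivity-unrelated echo peaks on every
correlogram they touch, which measurably degrades reconstruction).
Firing rates under the default drive are ~3 Hz with network bursts.

What the generator does *not* emulate: inhibitory synapses, conductance
dynamics, plasticity, electrode noise, spike-sorting errors leaking into
the trains, and spatial structure.  Passing benchmarks therefore show
that the method recovers connectivity *when its assumptions hold*; they
do not certify performance on real MEA recordings, where the MEA grid
profile and the Pearson mode are the recommended starting point.

## Benchmark protocol and problem sizes

The validation protocol (in `spikeconn.benchmark`) simulates 300 s
recordings of 20 random networks per size (10, 20, 50 neurons),
reconstructs each on the 9-point simulation grid in Pearson mode with
0.25 ms bins, and scores against the generating graph: TP/n_c, FP/n_c,
the confidence indicator Δ = (TP − FP)/n_c (independent of sparsity) and
the accuracy ACC = (TP + TN)/n(n−1) (which inflates on sparse truth —
TN dominates — and is reported only for comparability).  Typical
behaviour at the defaults: per-point TP/n_c ≈ 85–95 % with FP/n_c
≈ 4–12 %; at `d = 1` the false positives vanish (they never repeat
across all nine points) while unanimous true edges remain, giving mean
Δ ≈ 85–90 %.  The single-network `(T, σ)` sweep shows a flat
high-sensitivity plateau for T ≥ 2.25 ms and a collapse for T < 2 ms,
where the window no longer contains the effective delays.

## Spike sorting

PCA (mean-centred, components retained to 90 % explained variance)
followed by k-means with 20 restarts per candidate k in
{1, …, components + 1}; k chosen at the elbow (largest second
difference) of the within-cluster-sum curve, with k = 1 declared when a
two-way split reduces the objective by less than 40 % (an isotropic
single cluster in d ≥ 4 dimensions loses well under that; two real units
lose far more).  Events beyond 3× their cluster's rms centroid distance
are flagged as outliers but never dropped.  A `k_override` mirrors
manual curation of difficult electrodes.

## Degenerate inputs and numerical conventions

Silent neurons stay in the matrices as isolated nodes.  Pearson mode
refuses constant signals.  Smoothing kernels narrower than one lag bin
degenerate to the identity (this realizes the σ = 0.013 ms grid points).
Peak widths are floored at one bin; width ties in the victim order are
compared after quantization to the lag grid, since sub-sample width
differences are round-off.  The simulator validates finiteness of the
state and rejects diverging parameter combinations.  All randomness
flows through explicit integer seeds; identical seeds give
bitwise-identical recordings and reconstructions.

## Known limitations

* Inhibitory connections are out of scope (correlation troughs are not
  searched).
* Heavily synchronized regimes (release probability → 1, dense graphs)
  violate the amplitude-ordering assumption and degrade precision; the
  paper trail for this lives in the benchmark defaults above.
* The `O(n³)` triangle enumeration is brute-force (vectorized); beyond a
  few hundred active neurons it would dominate runtime.
* ACC should not be compared across network sizes (sparsity changes the
  TN mass).
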