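# spikeconn

Effective-connectivity reconstruction for spiking neuronal networks.

Multi-electrode-array recordings of cultured neurons (e.g. hiPSC-derived
networks) yield spike trains, not wiring diagrams.  Pairwise correlation
finds *functional* couplings, but it cannot tell a synapse from a
two-hop pathway or from two neurons sharing an input.  `spikeconn`
implements a super-selective correlation method that recovers the
*effective* — direct and causal — connectivity:

1. For every neuron pair `j < k`, compute the cross-correlation
   `R_jk(τ) = Σ_t s_j(t) s_k(t+τ)` of the binned trains (FFT-based, or an
   exact sparse equivalent), smooth with a Gaussian of sd σ, and detect
   peaks inside `(−T, +T)`; each peak carries a signed delay `τ_jk`
   (τ > 0 ⇒ `j` leads `k`), an amplitude `A_jk` and a width.
2. For every neuron triplet, every cyclic combination of peaks forms a
   *correlation triangle*.  If `|τ_jk + τ_km + τ_mj| < ε`, one delay is
   the combination of the other two — an indirect or apparent link — and
   the triangle's minimum-amplitude peak is discarded (indirect peaks
   are lower and wider, because phase noise accumulates along paths).
3. Repeat over a small grid of `(T, σ)` points.  An edge enters the
   binary matrix `M_p` of point `p` if a surviving peak implies
   `τ_jk > 0`; the per-edge frequency `f_jk = (1/K) Σ_p M_p` is
   thresholded at a discrimination level `d` (default: unanimity,
   `d = 1`).  True edges are found by every point; false survivors
   fluctuate between points and are voted out.

A built-in Izhikevich network simulator generates ground-truth
recordings that mimic spontaneously active cultures, and the evaluation
module scores reconstructions (TP/n_c, FP/n_c, Δ = (TP−FP)/n_c, ACC),
computes graph descriptors (degrees, hubs, path length, clustering) and
a timing-based receiver probability `s⁻/(s⁺+s⁻)` per neuron.  A
PCA + k-means spike sorter turns per-electrode waveform snippets into
single-unit trains.  See `docs/methods.md` for the model details and
design rationale.

## Worked example

```python
import spikeconn as sc

# ground truth: 10 neurons, sparse random wiring (mean out-degree 2)
model = sc.generate_random_network(10, mean_out_degree=2.0, seed=1)

# 300 s of noise-driven spontaneous activity
trains = sc.simulate_izhikevich(model, duration=300.0, seed=2)

# reconstruct on the 9-point simulation grid, Pearson correlations
freq, per_point = sc.reconstruct(
    trains, sc.SIMULATION_PROFILE, dt=0.25, mode="pearson"
)
adj = sc.threshold(freq, d=1.0)

res = sc.score(adj, model)
print(f"n_c={res.n_c} TP={res.TP} FP={res.FP} "
      f"Delta={100*res.delta:.0f}% ACC={100*res.acc:.1f}%")
```

Output:

```
n_c=20 TP=20 FP=0 Delta=100% ACC=100.0%
```

All 20 true synapses are recovered with no false positives at
unanimity for this network; the confidence indicator Δ = (TP − FP)/n_c
is 100 % and the accuracy over all 90 ordered pairs is likewise perfect.
Across many random networks the typical mean Δ at `d = 1` is 85–90 % —
occasional edges lose their correlation peak to a closing triangle at
some grid point and drop out of the unanimous vote.

The same pipeline is available from the shell:

```bash
spikeconn simulate --n 10 --degree 2 --duration 300 --seed 1 \
    --out-spikes spikes.csv --out-truth truth.csv
spikeconn reconstruct --spikes spikes.csv --profile sim --dt 0.25 \
    --mode pearson --d 1.0 --out freq.csv --out-adj adj.csv
spikeconn evaluate --adj adj.csv --truth truth.csv
spikeconn graph --adj adj.csv
spikeconn receiver --spikes spikes.csv --window 15
spikeconn sort --waveforms wf.csv --replicates 20 --out sorted.csv
```

For real MEA data use `--profile mea` (T ∈ {16, 17.5, 20} ms,
σ ∈ {0.4, 0.55, 0.7} ms, ε = 3 ms, matching cortical conduction delays)
and millisecond-scale `--dt`.

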