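# replikit

Kinetic modelling of genome-wide DNA replication timing.

Eukaryotic genomes replicate from many origins whose firing is stochastic:
an origin at 1-kb site *j* fires after an exponential waiting time with
rate *f<sub>j</sub>* (min⁻¹), and each firing launches two replication
forks that move outward at a constant speed *v* (kb/min, default 1.4).
The time at which site *j* replicates is then

```
T_j = min_i ( A_i + |i − j| / v ),      A_i ~ Exp(f_i)
```

— either the site fires itself or the nearest-in-time fork reaches it.
`replikit` is built around the closed form of the expectation of this
minimum. Writing S<sub>k</sub> = Σ<sub>|i|≤k</sub> (k−|i|) f<sub>j+i</sub>
and W<sub>k</sub> = Σ<sub>|i|≤k</sub> f<sub>j+i</sub>,

```
E[T_j] = Σ_{k=0..R} [ exp(−S_k/v) − exp(−(S_k+W_k)/v) ] / W_k
```

with *R* the radius of influence (default 2000 kb) beyond which
neighbouring origins are ignored. This lets the package:

- **infer origin firing rates** from Repli-seq-style timing profiles by a
  multiplicative fixed-point iteration
  f<sub>j</sub> ← f<sub>j</sub> (T̃<sub>j</sub>/T<sub>j</sub>)<sup>α</sup>
  initialised from the uniform-rate inversion f = π/(4v) T⁻²;
- **simulate replication stochastically** (origins firing, forks stepping
  with Erlang-distributed traversal times, fork merging), yielding mean
  timing, replication fork directionality (RFD ∈ [−1, 1]), inter-origin
  distances and replicon lengths;
- **detect misfit regions** where observed timing deviates from the
  constant-fork-speed prediction — the model's timing slope can never
  exceed 1/v min per kb, so steeper observed transitions (fork stalling,
  replication stress) accumulate squared error above a calling threshold
  (default 10²·⁸ min², merged within 300 kb);
- **read and write** the standard text formats involved: bedGraph tracks,
  BED annotations (fragile sites, genes) and cumulative Repli-seq
  fraction matrices, including sigmoidal extraction of the median
  replication time t_rep.

It is intended for researchers analysing replication-timing data who want
mechanistic per-site firing rates rather than descriptive early/late
calls, and for anyone studying replication stress through timing misfits.

## Worked example

Everything below runs from synthetic data — no downloads needed.

```python
import numpy as np
from replikit import (
    ModelConfig, SyntheticSpec, correlate_tracks, fit,
    gen_firing_landscape, gen_observed_timing, simulate_ensemble,
)

spec = SyntheticSpec(n_sites=2000, origin_count=10, seed=5)   # 2-Mb toy genome
rates = gen_firing_landscape(spec)
config = ModelConfig()                                        # v=1.4, R=2000, alpha=2
observed, _ = gen_observed_timing(spec, rates, config)

result = fit(observed, config)
print(f"initial MSE : {result.mse_trace[0]:8.2f} min^2")
print(f"final MSE   : {result.mse_trace[-1]:8.2f} min^2 after {result.iterations_run} iterations")

summary = simulate_ensemble(result.rates, config.with_overrides(n_simulations=100))
print(f"median IOD  : {np.median(summary.iod_samples):8.1f} kb over {summary.iod_samples.size} samples")
print(f"RFD range   : [{summary.rfd.min():+.2f}, {summary.rfd.max():+.2f}]")
print(f"rate vs timing (Spearman): {correlate_tracks(result.rates.rates, observed.times, 'spearman')[0]:+.3f}")
```

prints

```
initial MSE :   684.48 min^2
final MSE   :     7.64 min^2 after 20 iterations
median IOD  :    285.0 kb over 691 samples
RFD range   : [-1.00, +1.00]
rate vs timing (Spearman): -0.663
```

The fit collapses the timing mismatch by two orders of magnitude; the
simulated ensemble of the fitted rates produces inter-origin distances on
the few-hundred-kb scale typical of mammalian genomes, fork directionality
spanning both orientations, and the expected negative association between
firing rate and replication time (early sites fire fast).

The same workflow is available from the shell:

```sh
replikit synth spec.yaml --output-dir data/
replikit fit data/observed_timing.bedgraph --output-dir fitted/
replikit simulate fitted/rates.bedgraph --seed 1 --output-dir sim/
replikit analyze data/observed_timing.bedgraph fitted/predicted.bedgraph --output-dir misfits/
```

Each command writes a `manifest.yaml` recording config, seeds and input
checksums, so runs are reproducible.

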