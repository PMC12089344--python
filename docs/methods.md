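# Methods

## The model

The genome is discretised into 1-kb sites. Every site is a potential
replication origin with a firing rate f_j > 0 (min⁻¹): its firing time is
A_j ~ Exp(f_j), independent across sites. A fired origin launches two
forks moving outward at constant speed v (kb/min), and a site is
replicated either by firing or by the first incoming fork:

    T_j = min_i ( A_i + |i − j| / v ).

The firing rate is a coarse-grained quantity: it absorbs licensing,
activation and all upstream regulation into a single per-site propensity.
An origin that is passively replicated before its firing time never
fires; because the minimum above is taken over *all* sites, passive
replication needs no special treatment in the expectation — the classic
nucleation-and-growth argument.

### Closed-form expectation

The survival function P(T_j > t) = Π_i min{1, exp(−f_i (t − |i−j|/v))} is
piecewise a single exponential between the fork-arrival breakpoints k/v.
Integrating segment by segment, with
S_k = Σ_{|i|≤k} (k−|i|) f_{j+i} and W_k = Σ_{|i|≤k} f_{j+i}:

    E[T_j] = Σ_{k≥0} [exp(−S_k/v) − exp(−(S_k+W_k)/v)] / W_k

truncated at the radius of influence k ≤ R. The recurrences
W via prefix sums and S_{k+1} = S_k + W_k give O(R) work per site, and
the whole genome is evaluated as vectorised k-sweeps.

Three uniform-rate reductions are used for initialisation and validation:
the one-dimensional series E[T] = (1/f) Σ_k [e^{−fk²/v} − e^{−f(k+1)²/v}]/(2k+1);
the finite-genome expectation, computed exactly by partitioning the
survival-product integral at its breakpoints (its value depends on the
parity of the origin count through the distance multiset and is
non-increasing in the number of origins); and the asymptotic
approximation E[T] ≈ ½√(π/(fv)) whose inverse f = π/(4v) T⁻² seeds the
fit. Over f/v ∈ [10⁻⁵, 10⁻¹] the approximation stays within 5% of the
series (measured maximum ≈ 1.7%).

### Numerical choices

- **Degenerate windows.** Each series term is evaluated as
  exp(−S_k/v)·g(W_k/v)/v with g(x) = (1−e^{−x})/x computed via `expm1`,
  so the W_k → 0 limit (term → 1/v) is reached smoothly without
  cancellation; the rate floor (default 10⁻¹⁰ min⁻¹) keeps W_k > 0.
- **Truncation and tail.** The k-sum stops early once the survival factor
  exp(−S_k/v) < 10⁻¹² everywhere (terms decay double-exponentially), when
  the clamped window freezes at the chromosome span, or at k = R. The
  geometric remainder of the frozen window, exp(−S/v)/W, is then added in
  closed form, so the evaluation is exact for the R-window model rather
  than dropping tail mass — this matters on low-rate landscapes where the
  neglected tail would otherwise be comparable to Monte-Carlo error.
- **Chromosome ends.** Windows are clamped at chromosome boundaries (the
  missing flank contributes rate 0). There is no wraparound: end sites
  genuinely replicate later under the same rates, which is the physically
  correct behaviour for linear chromosomes. A consequence used in the
  tests: translation invariance holds in chromosome interiors but not
  within R of an end.
- **Units.** Positions in 1-kb sites, time in minutes, v in kb/min, rates
  in min⁻¹, everywhere.

## Fitting

Rates are initialised per site by f_j(0) = π/(4v) T_j⁻², then refined by
f_j(k+1) = f_j(k) (T̃_j(k)/T_j)^α with α = 2 (a fixed-point/inexact
gradient scheme exploiting the monotone dependence of E[T_j] on each
rate), clipping into [rate_floor, rate_cap] after every update. The
default run is 20 iterations; an optional early stop triggers when the
relative MSE improvement drops below `early_stop_tol`. Convergence is
tracked as the genome (and per-chromosome) mean squared timing error in
min². Masked sites are excluded from the MSE and the update but carry
rates derived from linearly interpolated timing so neighbouring
predictions remain computable. Fitting is deterministic and
chromosome-independent.

Convergence behaviour worth knowing: on forward-model data with a
near-dead background (rates at the floor), the multiplicative update
contracts background rates only geometrically (the prediction is weakly
sensitive to rates that are already small), so deep inter-origin valleys
approach their targets at roughly ×0.9 residual per iteration. On a
10-Mb, 50-origin landscape the MSE reaches ~1.2% of its initial value
after 20 iterations and crosses 1% around iteration 22. Fits of observed
timing with moderate rate landscapes converge much faster.

## Simulation

The ensemble simulator mirrors a process-algebra formulation of the same
model: ORI processes fire at their rates and spawn left- and right-moving
fork processes. Two fork-motion modes:

- `deterministic`: per-site traversal exactly 1/v min; a replicate is
  computed directly by the min-formula via a two-pass min-plus scan
  (running minima of A_i ∓ i/v), which is also the analytic oracle.
- `erlang` (default): each 1-kb step takes an independent Exp(v) time, so
  a k-site traversal is Erlang(k, v) with mean k/v. Event-driven with a
  priority queue; a fork reaching an already-replicated site retires
  (fork merging), and a passively replicated origin never fires.

Tie-breaking (measure-zero in continuous time, possible in floats): a
fork arriving exactly at a site's firing time wins; between two forks
arriving together, the rightward-moving fork wins in deterministic mode
and heap insertion order decides in erlang mode.

Per-site RFD is (#rightward − #leftward)/n_simulations; replicates in
which the site fired as an origin contribute to neither direction, so an
efficient origin has RFD ≈ 0 with ±1 flanks. Inter-origin distances are
gaps between consecutive *fired* origins per replicate and chromosome;
replicon lengths count the sites replicated by each fired origin and its
forks (they partition the chromosome, so they sum to its length); active
fork counts tally forks alive in each 1-min bin of their birth–death
span. Replicate i uses seed base_seed + i; fork-step noise uses a
sub-stream separate from firing times.

## Timing extraction from Repli-seq-style inputs

Two input routes produce per-site timing:

- **Smoothed signal tracks** (0–100, ENCODE wavelet style) are
  coverage-weighted onto the grid and mapped as T = (100 − s) × 6 min,
  spanning a nominal 0–600 min S phase. The orientation "high signal =
  early" is the package default and is exposed as a flag
  (`high_signal_early=False` flips it), since signal conventions vary
  between processing pipelines. Sites without coverage are masked; no
  further renormalisation is applied.
- **Cumulative fraction matrices** (site × S-phase bin, percent
  replicated, e.g. 16 bins) are reduced per site to t_rep, the 50%
  crossing of a least-squares logistic fit F(t) = 100/(1+e^{−k(t−t₀)});
  when the fit fails to converge the 50% crossing is linearly
  interpolated instead and the site is flagged. All-zero or all-complete
  sites are masked.

## Misfit analysis

The fit error (T_j − T̃_j)² in min² is the discrepancy measure. Misfit
regions are maximal runs of error above a threshold (default 10²·⁸ min²;
a stricter 10⁴ min² preset exists for contrasts that should only count
extreme misfits), with runs merged when separated by ≤ 300 kb. Because
predicted slopes are bounded by 1/v, observed transitions steeper than
the fork speed — injected stalls in synthetic data, fork stalling in real
data — necessarily leave localised error that the fit cannot remove.
Overlap fractions against interval annotations are computed at site
resolution (misfit sites inside the class's intervals over all sites
inside them, with the complement reported alongside); correlations
between per-site tracks use Spearman, Pearson or Kendall with
pairwise-complete masking and raw two-sided p-values. Normalised error
maps use log10(e+1) scaled min–max per chromosome. The early/late split
used for grouped error summaries is a median split of the timing profile.

## Synthetic data

The generators emulate what the model assumes: `gen_firing_landscape`
places a chosen number of origins uniformly at random with log-uniform
rates (default 10⁻³–10⁻¹ min⁻¹, spanning the decades seen in fitted-rate
distributions without committing to a parametric form) over a passive
background at the rate floor; `gen_observed_timing` forward-computes the
closed form, then optionally injects stall delays (default scale: 60 min
over 150-kb regions, ramped linearly over 10 sites at each edge so no
unmeasurable discontinuity appears) and Gaussian noise;
`gen_fraction_heatmap` renders timing into noisy cumulative logistic
curves; `gen_interval_track` scatters non-overlapping labelled intervals.

What the generators do *not* emulate — and hence what passing tests do
not establish about real data: mappability structure and systematic
(non-Gaussian, spatially correlated) Repli-seq noise, cell-line-specific
rate distributions, copy-number and cell-cycle-fraction artefacts, and
any biological origin clustering beyond uniform placement.

## Problem sizes and defaults

Defaults: v = 1.4 kb/min, R = 2000 kb, α = 2, 20 iterations, 500
simulation replicates, rate bounds [10⁻¹⁰, 10] min⁻¹, series tolerance
10⁻¹². The test suite and the acceptance script exercise the model at
5,000–10,000-site genomes (5–10 Mb), 10⁴-replicate Monte-Carlo checks on
500-site landscapes, and 500-replicate stochastic ensembles — sizes at
which every closed-form/simulation comparison is resolved well inside
Monte-Carlo error while the whole suite runs in well under a minute for
the numerical core. Fitting a full 10-Mb genome for 20 iterations takes a
few seconds on one CPU; cost scales linearly in sites × R.

## Known limitations

- Constant fork speed is a modelling contract, not an option: variable
  speeds, strand asymmetries and Okazaki-level detail are out of scope.
- The fit is a heuristic fixed-point scheme; it has no likelihood, no
  standard errors, and its background-rate convergence is geometric (see
  Fitting above).
- RFD at origin-fired sites is defined as contributing 0 to either
  direction; other conventions (excluding such replicates) would shift
  RFD magnitudes near efficient origins.
- bigWig I/O is not built in; convert to bedGraph first.
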