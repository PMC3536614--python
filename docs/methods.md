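# Model and methods

## The network

The model is a self-organizing recurrent network (SORN) of binary
threshold units, 200 excitatory and 40 inhibitory by default, with no
external input.  Three weight matrices connect the populations, all
stored incoming-major (row *i* holds the inputs of unit *i*):

* `W_EE` — excitatory→excitatory, sparse (initial connection probability
  0.1), fully plastic;
* `W_EI` — inhibitory→excitatory, sparse (probability 0.2), plastic
  under inhibitory STDP;
* `W_IE` — excitatory→inhibitory, dense, fixed after initialization,
  each row normalized to sum to one.

Inhibitory–inhibitory and self connections are forbidden.  The state at
discrete time *t* is a pair of binary vectors `x(t)`, `y(t)`.  A unit
fires at *t+1* iff its summed excitatory drive, minus inhibitory drive,
minus its threshold, plus white Gaussian membrane noise, is strictly
positive; a unit exactly at threshold stays silent.  With zero noise the
update is deterministic, and two runs with the same seed are
bit-identical.

One time step corresponds to roughly 10–20 ms of biological time (a
membrane time constant / STDP window); the homeostatic mechanisms are
deliberately run much faster than their biological counterparts, which
is admissible because of the separation of time scales and keeps
simulations short.

## The five plasticity mechanisms

1. **Additive STDP** (EE only, existing synapses only):
   `dW_ij = eta_stdp * (x_i(t+1) x_j(t) − x_i(t) x_j(t+1))` — causal
   pre-before-post potentiates, the reverse order depresses by the same
   amount; simultaneous activity at both steps cancels.  A weight driven
   to or below zero is set to exactly zero and the synapse is
   structurally eliminated.
2. **Synaptic normalization**: each unit's incoming EE weights are
   divided by their sum every step, so each row with inputs sums to one
   (exactly, to 1e-9).  This is the competitive, multiplicative-scaling
   constraint; rows without inputs are left alone.
3. **Intrinsic plasticity**: excitatory thresholds move by
   `eta_ip * (x_i − target_rate)` each step, holding every unit near the
   target firing probability (0.1).  Thresholds are not clipped —
   under weak drive homeostasis may legitimately push them negative.
4. **Structural plasticity**: with probability 0.1 per step, one ordered
   unconnected non-self EE pair, drawn uniformly, is created at weight
   exactly 0.001.
5. **Inhibitory STDP**: when inhibitory unit *k* fired at *t*, its weight
   onto excitatory *i* is reduced by `eta_istdp_dep` if *i* stays silent
   at *t+1* (floored at 0.001, so inhibitory synapses are never
   eliminated) and increased by the larger `eta_istdp_pot` if *i* fires.
   This balances excitatory and inhibitory drive at low rates.

### Step ordering and RNG discipline

Within one step: threshold dynamics → STDP → iSTDP → normalization →
intrinsic plasticity → structural plasticity.  Normalization follows
STDP so the sum-to-one invariant holds at every step boundary; the
structural birth comes last so a newborn survives at 0.001 into the next
step.  A single seeded generator is consumed in a fixed order (noise E,
noise I, structural draws), so checkpointed and resumed runs are
bit-identical to uninterrupted ones.  Whether normalization precedes or
follows iSTDP within a step is not constrained by the model description;
this package fixes the order above.

## Parameter defaults

| name | default | meaning |
|---|---|---|
| `n_exc`, `n_inh` | 200, 40 | population sizes (20% inhibitory) |
| `p_ee_init`, `p_ei_init` | 0.1, 0.2 | initial connection probabilities |
| `eta_stdp` | 0.004 | additive STDP step |
| `eta_istdp_pot`, `eta_istdp_dep` | 0.004, 0.001 | iSTDP steps (potentiation larger) |
| `eta_ip` | 0.01 | threshold step |
| `target_rate` | 0.1 | homeostatic firing probability (scalar or per unit) |
| `sigma_noise_exc/inh` | sqrt(0.05) | membrane-noise sd (variance 0.05) |
| `p_struct` | 0.1 | structural creation probability per step |
| `w_new`, `w_ei_floor` | 0.001 | birth weight; inhibitory floor |
| `t_exc_max`, `t_inh_max` | 0.5, 1.0 | threshold init intervals [0, max] |
| `hist_exclusion` | 1e-4 | small-synapse exclusion for histograms |

The membrane noise is specified by its **variance** (0.05) in this model
family; the parameter fields hold the standard deviation.  Initial EE
weights are uniform on (0, 1] then row-normalized; EI weights uniform on
(0, 1] (iSTDP, not normalization, regulates them afterwards); initial
activity is Bernoulli(target_rate) per unit — any start is admissible
because the first 3,000 steps are discarded as washout in all analyses.

## What the simulations show, and at what scale

All headline statistics are computed from simulator output at desk
scale; the package's own long-run reference points are:

* **10,000 steps** (seconds): firing is Poisson-like (mean ISI CV ≈ 0.93,
  pairwise correlations ≈ 0.01), the weight distribution is
  lognormal-like (KS ≈ 0.06 against the fitted lognormal, far below the
  best-fit exponential), and ≈ 24% of synapses carry half the total
  weight.
* **50,000 steps** (≈ 15 s): lifetimes of structurally created synapses
  that died follow a power law; the discrete MLE with KS-selected lower
  cutoff gives an exponent magnitude ≈ 1.5 (the random-walk
  first-passage value).  The fixed default cutoff `xmin = 2` gives a
  visibly flatter ≈ 1.24 because lifetimes shorter than the typical
  interval between STDP coincidence events (tens of steps at rate 0.1)
  are governed by the waiting-time distribution, not by the scale-free
  diffusion of the weight; the KS-minimizing cutoff (the standard
  Clauset-style selection, used by `fit_power_law(..., xmin=None)`)
  excludes that regime automatically.
* **hundreds of thousands of steps** (minutes): the connection fraction
  traces the decay → growth → stable sequence.  The full sequence within
  one run is demonstrated on a reduced 60E/12I network over 200,000
  steps; the default-size network needs millions of steps to stabilize,
  which is outside desk scale.

### The decay→growth transition and the strongest synapses

During the connectivity minimum (for the default network, roughly steps
30,000–150,000) some units are left with one or two incoming synapses.
Normalization then pins those weights near one, producing a transient
population of outsized weights and visible deviations from the lognormal
shape — a property of the model at the transition.  A pinned
single-input row cannot lose its synapse (normalization restores it to
one each step) and only recovers when a structurally created synapse
survives in that row, so the transient clears slowly: the mean of the
ten largest weights is ≈ 1 at 50,000 steps and declines over the
following hundreds of thousands of steps (strongly seed-dependent) as
rows are repopulated, heading toward the small (≲ 0.1) strongest-weight
scale of the equilibrated network.  Strongest-weight measurements at
fixed desk-scale horizons therefore probe this transition rather than
the stable regime.

## Analysis conventions

* Histograms use bin edges uniform in log10 with density = count /
  linear bin width; weights at or below `hist_exclusion` are dropped,
  mimicking the detection limit of spine imaging.
* Lognormal fits are maximum likelihood on log-weights; goodness of fit
  is a one-sample KS statistic.
* Lifetime fits exclude synapses present at t = 0 (unknown birth) and
  synapses still alive at the horizon (right censoring; the stable
  backbone would otherwise dominate).  Both a discrete MLE (Hurwitz-zeta
  likelihood) and a log-binned least-squares slope are reported; the MLE
  is primary.
* CV summaries require ≥ 3 inter-spike intervals per unit; silent and
  sparse units are excluded and flagged.  Correlations are Pearson on
  the raw binary trains; constant trains give flagged NaN entries.
* Phase classification fits a linear slope per non-overlapping window
  (default 1000 steps) and labels decay/growth/stable against a slope
  tolerance estimated, by default, as twice the sd of window slopes in
  the final quarter of the series.
* The STDP conditional curves (potentiation/depression probability per
  weight bin) take per-change logs from the engine and estimate
  synapse-step totals from the periodic snapshots, each snapshot
  standing for the steps until the next.
* The Gibrat null model multiplies each weight by exp(eps),
  eps ~ N(0, sd), per step; with normalization the ensemble keeps a
  fixed total and a lognormal-like shape, without it the log-variance
  grows as sd^2 per step without bound.

## Synthetic data and what passing tests mean

The generator (`sorn.fixtures`) produces lognormal and discrete
power-law samples with known parameters (estimator-recovery checks),
symmetric random-walk first-passage lifetimes (the −3/2 oracle), and a
tiny 10E/2I network record.  These validate the estimators and the
engine's bookkeeping, and the simulator itself emulates the
self-organization claims — but none of this is experimental data: spike
rasters here are binary and synchronous, weights are unitless fractions
of a fixed row budget, and biological spine-size data enters only
through user-supplied tables run through the same analysis functions.
Passing tests show internal consistency of model + estimators at the
stated scales, not biological validity.

## Known limitations

* Discrete time and binary activity; no refractoriness, conductances or
  external input streams.
* The default-size network's stable regime lies beyond desk-scale
  budgets; long-horizon statements are demonstrated on reduced networks
  or bounded horizons, as noted above.
* The strongest-synapse scale near the decay→growth transition is
  dominated by pinned single-input rows and is strongly seed-dependent.
* Lifetime fits below the STDP-coincidence timescale are not power-law;
  exponent estimates are meaningful only above the selected cutoff.
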