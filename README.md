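# sorn-plasticity

A simulator and analysis suite for **SORN** — a self-organizing
recurrent network of binary threshold neurons in which five interacting
plasticity mechanisms (additive STDP, synaptic normalization, intrinsic
plasticity, structural plasticity, and inhibitory STDP) shape the
synaptic connectivity with no external input.

The package is for computational neuroscientists studying how the
statistics and dynamics of cortical synapses — lognormal-like weight
distributions, Poisson-like irregular firing, constant synapse turnover
with a stable strong backbone, and weight-proportional fluctuations —
can emerge from network self-organization rather than being built in.

## The model in brief

Binary units update synchronously; excitatory unit *i* fires at *t+1*
iff

    sum_j W_EE[i,j] x_j(t) − sum_k W_EI[i,k] y_k(t) − T_E[i] + xi > 0

with white Gaussian noise `xi` (variance 0.05), and analogously for
inhibitory units driven through the fixed, row-normalized `W_IE`.  Each
step then applies, in order:

* **STDP**:  `dW_EE[i,j] = eta (x_i(t+1) x_j(t) − x_i(t) x_j(t+1))`,
  with elimination when a weight reaches zero;
* **iSTDP** on `W_EI`, depressing "successful" inhibition slightly and
  potentiating "failed" inhibition by a larger amount (floored at 0.001);
* **synaptic normalization**: every unit's incoming EE weights are
  rescaled to sum to one — the competition that keeps growth bounded;
* **intrinsic plasticity**: thresholds track a target rate of 0.1;
* **structural plasticity**: with probability 0.1 a new EE synapse is
  created at weight 0.001 between a random unconnected pair.

STDP is purely additive, yet the network develops *multiplicative*
statistics: potentiation probability grows with weight (rich-get-richer)
and fluctuation size is proportional to weight.  Lifetimes of newly
created synapses follow a power law with exponent near −3/2, the
first-passage signature of weights diffusing toward elimination.

## Worked example

```python
import sorn
from sorn import analysis as an

record = sorn.run(sorn.NetworkParams(seed=1), 10_000)
w = record.final_syn.w_ee

fit = an.fit_lognormal(w, record.params.hist_exclusion)
cv = an.isi_cv_stats(record.raster_exc, washout=3000)
share = an.top_share(w[w > record.params.hist_exclusion], 0.5)
print(fit.params, cv.mean_cv, share)
```

prints (seed 1):

```
{'mu': -2.66, 'sigma': 0.88}  0.929  0.241
```

i.e. after 10,000 self-organization steps the surviving
excitatory-to-excitatory weights are lognormal-like (log-mean −2.66,
log-sd 0.88), units fire irregularly (mean inter-spike-interval CV 0.93,
close to the Poisson value 1), and the strongest 24% of synapses carry
half of the total synaptic weight — close to the ~20% observed in
cortex.  The scripts in `examples/` walk through one capability each
(weight distributions, firing statistics, synapse lifetimes,
rich-get-richer curves, the Gibrat null model) and print what the
numbers mean.

A thin CLI wraps the same library:

```
sorn simulate -c config.toml -o outdir [--disable stdp,sn,ip,istdp,sp] [--seed N]
sorn analyze outdir/record.h5 --which isi,weights,lifetimes,phases,returnmap
sorn ablate -c config.toml -o outdir --mode single
sorn fixtures powerlaw-sample -o sample.csv -p alpha=1.5 -p n=10000
```

Records are HDF5 (raster, connection-fraction series, weight snapshots,
synapse birth/death events, optional per-change STDP log) plus a CSV
event log and a JSON manifest stamped with the configuration hash.

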