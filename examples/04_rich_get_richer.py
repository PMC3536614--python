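"""Rich-get-richer STDP dynamics and weight-dependent fluctuations.

With per-change STDP logging enabled, the run records every isolated
STDP weight change together with the synapse's weight at that moment.
Binning by weight shows that the probability of potentiation rises with
synaptic strength while depression is much flatter — so strong synapses
keep winning.  The companion statistic, mean |weight change| across
200-step windows, grows roughly linearly with weight: multiplicative-
looking dynamics from a purely additive STDP rule.
"""

import numpy as np

import sorn
from sorn import analysis as an

record = sorn.run(sorn.NetworkParams(seed=1), 10_000,
                  record=sorn.RecordSpec(raster=False, snapshot_every=200,
                                         stdp_deltas=True))

bins = np.linspace(0, 0.2, 11)
curves = an.stdp_conditional_curves(record.stdp_log, record.snapshots, bins)
fluct = an.fluctuation_vs_weight(record.snapshots, bins)

print("weight bin | P(potentiation) | P(depression) | mean |dW| per 200 steps")
for c, p, d, f in zip(curves["bin_centers"], curves["pot_fraction"],
                      curves["dep_fraction"], fluct["mean_abs_change"]):
    if not np.isnan(p):
        print(f"  {c:7.3f}  |     {p:7.4f}     |    {d:7.4f}    |  {f:.4f}")
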