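"""Self-organized synaptic weight distribution.

Runs the default 200E/40I network for 10,000 steps and fits a lognormal
to the surviving excitatory-to-excitatory weights.  The printed mu/sigma
are the mean and sd of log-weights; the KS statistic measures the
distance to the fitted lognormal (smaller is closer).  The top-share
line says what fraction of the strongest synapses carries half of the
total weight — experimentally this is around 20%.
"""

import numpy as np

import sorn
from sorn import analysis as an

record = sorn.run(sorn.NetworkParams(seed=1), 10_000,
                  record=sorn.RecordSpec(raster=False))
params = record.params
w = record.final_syn.w_ee
retained = w[w > params.hist_exclusion]

fit = an.fit_lognormal(w, params.hist_exclusion)
share = an.top_share(retained, 0.5)

print(f"surviving synapses: {retained.size} "
      f"(connection fraction {record.final_syn.connection_fraction():.3f})")
print(f"lognormal fit: mu={fit.params['mu']:.2f}, "
      f"sigma={fit.params['sigma']:.2f}, KS={fit.gof:.3f}")
print(f"top {share * 100:.1f}% of synapses hold 50% of total weight")
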