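"""Poisson-like irregular firing.

After a 3,000-step washout, the inter-spike-interval coefficient of
variation (CV) of each excitatory unit is computed; CV = 1 is the
Poisson benchmark, CV = 0 a metronome.  Pairwise Pearson correlations
between spike trains stay near zero: the network fires irregularly and
nearly independently despite being fully self-organized.
"""

import numpy as np

import sorn
from sorn import analysis as an

record = sorn.run(sorn.NetworkParams(seed=1), 10_000)

stats = an.isi_cv_stats(record.raster_exc, washout=3000)
corr = an.pairwise_correlations(record.raster_all(), washout=3000)
off_diag = corr[~np.eye(corr.shape[0], dtype=bool)]

print(f"mean firing rate: {record.raster_exc[3000:].mean():.3f} "
      f"(homeostatic target {record.params.target_rate})")
print(f"mean ISI CV over {stats.n_units_included} units: "
      f"{stats.mean_cv:.3f}  (Poisson process: 1.0)")
print(f"mean |pairwise correlation|: {np.nanmean(np.abs(off_diag)):.4f}")
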