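"""Build the group functional-connectivity template.

Per-subject parcel time series are scrubbed for motion (frames above the
framewise-displacement threshold are censored; subjects needing >= 30%
censoring are dropped), correlated, Fisher-z transformed, averaged,
thresholded at 30% edge density and converted to a distance in [0, 1].
"""
import numpy as np

import tauspread as ts

cfg = ts.CohortConfig(seed=1)
series = ts.generate_template_timeseries(20, cfg)

fcs = [ts.scrub_and_fc(s.signals, s.fd, fd_threshold=0.5)
       for s in series.subjects]
retained = [fc for fc in fcs if fc.retained]
print(f"subjects retained after scrubbing: {len(retained)}/{len(fcs)} "
      f"(mean censored fraction {np.mean([fc.censored_fraction for fc in fcs]):.2f})")

tpl = ts.build_template(fcs, density=0.30)
n_pairs = 200 * 199 // 2
print(f"edges retained at 30% density: "
      f"{tpl.mask[np.triu_indices(200, 1)].sum()} of {n_pairs}")
print(f"distance matrix: 0 = strongest retained connection, 1 = weakest or "
      f"not retained; mean off-diagonal distance {tpl.distance[np.triu_indices(200, 1)].mean():.2f}")
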