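"""Detect each participant's tau epicentres from baseline scans.

A two-component Gaussian mixture per region separates non-specific from
abnormal binding; the posterior probability of the abnormal component times
the SUVR gives a cleaned score, and the top 10 regions define the individual
epicentres.
"""
import numpy as np

import tauspread as ts

cfg = ts.CohortConfig(seed=1)
tables, truth = ts.generate_cohort(cfg)

base = ts.baseline_suvr_table(tables.tau_scans)
mask = ts.default_exclusion_mask(base, truth.networks)
gmms = ts.fit_region_gmms(base, exclusion_mask=mask, seed=0)
scores = ts.epicentre_scores(base, gmms, exclusion_mask=mask)
sets = ts.select_epicentres(scores, k=10)

bimodal = [p for p, g in gmms.items() if not g.unimodal]
ex = gmms[bimodal[0]]
print(f"excluded low-uptake somatomotor parcels: {len(mask)}")
print(f"regions with a detectable abnormal component: {len(bimodal)}/200")
print(f"example region {bimodal[0]}: non-specific N({ex.mu1:.2f}, {ex.sigma1:.2f}), "
      f"abnormal N({ex.mu2:.2f}, {ex.sigma2:.2f}), weight {ex.pi_abn:.2f}")

pos = tables.participants.loc[tables.participants.ab_status == "pos", "id"]
hits = np.mean([len(set(sets[p]) & set(truth.epicentres[p])) / 10 for p in pos])
print(f"each participant gets exactly {len(sets[pos.iloc[0]])} epicentres; "
      f"{100 * hits:.0f}% of the planted ones are recovered in the "
      "amyloid-positive group at this noise level")
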