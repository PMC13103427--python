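"""Fine-scale spatial structure: isolation by distance and admixture decay.

Within one simulated zone we (1) Mantel-test geographic against genetic
and ancestry distances, and (2) regress each selfer's admixture on its
mean distance to the three nearest outcrossers.
"""

import numpy as np
import pandas as pd

import contactzone as cz

cfg = cz.SimConfig(n_sites=400, n_outcrosser=40, n_selfer=40,
                   generations_since_pulse=10, depth_mean=30.0, seed=6)
panels = cz.simulate_panels(cfg)
records, truth = cz.simulate_zone(cfg, panels)
reads = cz.simulate_reads(truth, panels, cfg)
meta = pd.DataFrame([r.__dict__ for r in records])

selfers = np.flatnonzero(truth.taxon == 1)
geo = cz.geographic_distance(meta.lon[selfers].to_numpy(),
                             meta.lat[selfers].to_numpy(), planar=True)
dosage = (reads.alt / np.maximum(reads.depth, 1))[selfers]
gen = cz.nei_distance(dosage)
anc = cz.ancestry_distance(truth.true_ancestry[selfers].astype(float))

for name, mat in [("genetic", gen), ("ancestry", anc)]:
    try:
        res = cz.mantel(geo, mat, n_perm=999, seed=0)
    except ValueError as exc:  # e.g. no admixture variation at all
        print(f"Mantel geographic ~ {name} distance: {exc}")
        continue
    print(f"Mantel geographic ~ {name} distance: r = {res.r:+.3f}, p = {res.p:.3f}")

d3 = cz.dist_to_heterospecifics(meta, planar=True)
rep = cz.admixture_vs_distance(truth.true_alpha[selfers], d3[selfers],
                               quadratic=True)
print(f"selfer admixture ~ distance-to-outcrossers: slope = {rep.slope:+.2e},"
      f" F = {rep.linear_F:.2f} (p = {rep.linear_p:.3f});"
      f" quadratic improvement F = {rep.quadratic_F:.2f} (p = {rep.quadratic_p:.3f})")
# positive Mantel r means spatial neighbours are genetically similar; the
# distance model asks whether admixture concentrates near the contact front.
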