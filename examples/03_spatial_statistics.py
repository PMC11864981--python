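"""Moran's I and the spatial cross-correlation index on spot data.

A zone marker gene is spatially clustered (positive I); a random gene is
not. SCI couples two features through the spatial weights.
"""

import numpy as np

import spotgin as sg

cohort = sg.generate_cohort(n_samples=1, grid=(16, 16), n_genes=300,
                            n_classes=2, seed=7, subclass_mode="marginal",
                            events=None)
ds = cohort.datasets[0]
nm = sg.normalize_dataset(ds)
weights = sg.build_weights(ds.spot_xy(), rule="knn", k=6)

zone_marker = cohort.truth.program_genes["histology"][0]  # main-tumor marker
idx = nm.gene_index([zone_marker])[0]
x = nm.values[idx]

res = sg.morans_i_permutation(x, weights, n_perm=499, seed=1)
print(f"zone marker {zone_marker}: I = {res['i']:.3f} "
      f"(perm p = {res['p']:.3f}, null mean = {res['null_mean']:.4f})")

rng = np.random.default_rng(0)
noise = rng.normal(size=ds.n_spots)
print(f"random field:          I = {sg.morans_i(noise, weights):.3f}")

y = nm.values[nm.gene_index([cohort.truth.program_genes['histology'][1]])[0]]
print(f"SCI(marker, second marker of same zone) = {sg.sci(x, y, weights):.3f}")
print(f"SCI(x, x) = I/2 check: {sg.sci(x, x, weights):.4f} vs "
      f"{sg.morans_i(x, weights) / 2:.4f}")

# The zone marker is significantly clustered (I ~ 0.13, perm p < 0.01)
# because its zone is a contiguous band, while per-spot count noise keeps
# I well below 1; the random field sits near the permutation-null mean
# -1/(N-1) ~ -0.004; two markers of the same zone share a positive SCI.
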