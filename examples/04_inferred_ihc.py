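"""Quantify agreement between a stain image and marker-gene expression.

Renders a synthetic stain whose blue channel tracks a marker gene, then
recovers the relationship with the Gaussian-smoother / linear-model
pipeline — once for a faithful stain and once for a pure-noise null.
"""

import spotgin as sg

cohort = sg.generate_cohort(n_samples=1, grid=(20, 20), n_genes=300,
                            n_classes=2, seed=9, subclass_mode="marginal",
                            events=None)
ds = cohort.datasets[0]
nm = sg.normalize_dataset(ds)
sg.select_hvg_joint([nm], 50)
marker = str(nm.hvg_ids[0])

truth = sg.render_marker_image(ds, nm, marker, a=0.8, sigma_noise=0.1, seed=2)
res = sg.quantify_marker(ds, nm, marker, sigma=truth["sigma_px"])
print(f"stain tracking {marker}: R = {res['r']:.3f} "
      f"(p = {res['p']:.2e}, n = {res['n']} spots)")

sg.render_marker_image(ds, nm, marker, a=0.0, sigma_noise=0.15, seed=2)
null = sg.quantify_marker(ds, nm, marker, sigma=truth["sigma_px"])
print(f"null stain (a = 0):   R = {null['r']:.3f} (p = {null['p']:.2f})")

# A faithful stain yields R above 0.9 at modest noise; the null stain's
# correlation is indistinguishable from zero - the same contrast used to
# validate inferred immunostains against true marker genes vs decoys.
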