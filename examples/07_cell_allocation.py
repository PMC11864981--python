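"""Allocate deconvolution scores to integer per-nucleus cell types.

Generates Dirichlet deconvolution scores and nucleus positions for one
section, allocates counts per spot with the rounding formula, maps types
onto nuclei, and compares the composition of tumor-zone vs healthy-zone
neighborhoods with a permutation test.
"""

import pandas as pd

import spotgin as sg
from spotgin.cellcomp import composition_frequencies
from spotgin.synthetic import REFERENCE_ZONES

cohort = sg.generate_cohort(n_samples=1, grid=(14, 14), n_genes=250,
                            n_classes=2, seed=3, subclass_mode="marginal",
                            events=None)
ds = cohort.datasets[0]
dec = sg.generate_deconvolution(ds, n_types=4, seed=5)

scores = sg.DeconvolutionScores(dec["scores"])
n_cells = dec["true_counts"].sum(axis=1)
alloc = sg.allocate_all(scores, n_cells)
print("allocation for 5 spots:")
print(alloc.head(5))
print(f"\nmax |sum C - N| over spots: "
      f"{alloc['rounding_deviation'].abs().max()} "
      f"(bound ceil(T/2) = 2)")

# assemble a nucleus-level map and compare tumor vs healthy composition
frames = {"tumor": [], "healthy": []}
nuclei = dec["nuclei"]
for barcode, row in alloc.iterrows():
    pos = nuclei.loc[nuclei["barcode"] == barcode, ["x", "y"]].to_numpy()
    typed = sg.map_to_nuclei(row[dec["types"]], pos, seed=8)
    zone = ds.histology.loc[barcode]
    key = "healthy" if zone in REFERENCE_ZONES else "tumor"
    frames[key].append(typed)

tumor = pd.concat(frames["tumor"])
healthy = pd.concat(frames["healthy"])
print(f"\ntumor-zone nuclei: {len(tumor)}, healthy-zone: {len(healthy)}")
print("tumor composition:", composition_frequencies(tumor).round(2).to_dict())
result = sg.compare_neighborhood_composition(tumor, healthy, n_perm=300,
                                             seed=1)
print(result.round(3))

# Counts conserve within the ceil(T/2) rounding bound; with symmetric
# Dirichlet proportions the two zones differ mainly in nucleus density,
# so per-type frequency differences are small — though with only ~150
# healthy-zone nuclei an occasional type reaches nominal significance.
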