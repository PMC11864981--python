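"""Why neighborhoods matter: k-hop ablation on the texture task.

The texture cohort's subclasses share identical per-spot expression
profiles and differ only in how the two spot programs are arranged in
space. A k=0 model (linear, no neighborhood) can therefore only guess,
while a 3-hop graph network sees the arrangement. Takes a few minutes.
"""

from spotgin import experiments as ex

table = ex.texture_ablation(seed=1, ks=(0, 1, 3))
print(table[["accuracy", "precision", "recall", "f1"]].round(3))

# Typical output: k=0 accuracy ~0.25-0.45 (chance for four classes is
# 0.25), k=3 accuracy >0.95 - the information is entirely in the
# neighborhood, mirroring the gap between a linear per-spot model and a
# 3-hop graph network on real cohorts.
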