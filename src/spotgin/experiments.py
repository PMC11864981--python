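"""Reference experiment protocols on the synthetic cohorts.

These functions fix the study conditions — cohort sizes, splits,
network hyper-parameters — for the recovery experiments the package is
validated with, so tests, the acceptance script and users run the exact
same protocol:

* ``cnv_recovery``       — planted arm events on the default cohort
  (12 samples, 30x30 hex grid, 2,000 genes, gain x1.5 / loss x0.5),
  arm-call accuracy, multiclass AUC and a permuted gene-to-bin control;
* ``texture_ablation``   — the neighborhood-texture subclass task
  (16 samples, 24x24, 300 genes; classes share marginal signatures and
  differ only in spatial arrangement), k-hop network vs k=0 linear model;
* ``control_ablation``   — the spot-local (marginal) subclass task where
  neighborhood information should not matter;
* ``multitask``          — subclass + MGMT + CDKN2A/B heads on the
  marginal cohort, with participant-level majority voting;
* ``shuffled_null``      — label-shuffle null for any head, evaluated on
  a class-balanced validation subsample;
* ``ihc_recovery``       — marker-image correlation, noiseless and null.

Splits are at section level: the last four samples (one per subclass)
form the validation side; participants never straddle the split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnv import build_bins, assign_genes, roc_gain_loss, sample_arm_calls, score_bins
from .gnn import (GinConfig, HeadSpec, evaluate, init_model, khop_ablation,
                  predict, predict_participant, predicted_classes, train)
from .graphs import make_training_set
from .ihc import quantify_marker
from .preprocess import normalize_dataset, select_hvg_joint
from .synthetic import (REFERENCE_ZONES, SUBCLASSES, generate_cohort,
                        render_marker_image)

N_HVG = 100

GNN_COHORT = dict(n_samples=16, grid=(24, 24), n_genes=300, n_classes=4,
                  events=None)
VALIDATION_SAMPLES = {"SYN12", "SYN13", "SYN14", "SYN15"}  # one per subclass

SUBCLASS_HEAD = HeadSpec("methylation_subclass", classes=list(SUBCLASSES))
MGMT_HEAD = HeadSpec("mgmt_status", classes=["methylated", "unmethylated"])
CDKN_HEAD = HeadSpec("cdkn2ab_status",
                     classes=["none", "heterozygous", "homozygous"])


def prepare_bundles(cohort, n_hvg: int = N_HVG) -> list:
    """Normalize every section and select one joint variable-gene list."""
    nms = [normalize_dataset(ds) for ds in cohort.datasets]
    select_hvg_joint(nms, n_hvg)
    return [{"dataset": ds, "nm": nm, "participant": ds.sample_id}
            for ds, nm in zip(cohort.datasets, nms)]


def gnn_bundles(seed: int, subclass_mode: str) -> list:
    cohort = generate_cohort(seed=seed, subclass_mode=subclass_mode,
                             **GNN_COHORT)
    return prepare_bundles(cohort)


# ---------------------------------------------------------------------- #
# ablations
# ---------------------------------------------------------------------- #
def texture_ablation(seed: int, ks=(0, 3), epochs: int = 35,
                     hidden: int = 48, bundles: list | None = None) -> pd.DataFrame:
    """k-hop ablation on the texture task: only neighborhoods carry class."""
    if bundles is None:
        bundles = gnn_bundles(seed, "texture")
    cfg = GinConfig(hidden_dim=hidden, dropout_p=0.3, epochs=epochs,
                    lr=1e-3, batch_size=64, seed=seed, heads=[SUBCLASS_HEAD])
    return khop_ablation(bundles, cfg, ks=ks,
                         val_sections=set(VALIDATION_SAMPLES))


def control_ablation(seed: int, ks=(0, 3), epochs: int = 25,
                     hidden: int = 48, bundles: list | None = None) -> pd.DataFrame:
    """Same ablation on the spot-local task: k should barely matter."""
    if bundles is None:
        bundles = gnn_bundles(seed, "marginal")
    cfg = GinConfig(hidden_dim=hidden, dropout_p=0.3, epochs=epochs,
                    lr=1e-3, batch_size=64, seed=seed, heads=[SUBCLASS_HEAD])
    return khop_ablation(bundles, cfg, ks=ks,
                         val_sections=set(VALIDATION_SAMPLES))


# ---------------------------------------------------------------------- #
# multi-task heads
# ---------------------------------------------------------------------- #
def multitask(seed: int, k: int = 2, epochs: int = 30, hidden: int = 64,
              bundles: list | None = None) -> dict:
    """Train subclass + MGMT + CDKN2A/B heads; report held-out accuracies.

    Returns per-head validation accuracy, the participant-level majority
    vote accuracy for the subclass head, and the vote table.
    """
    if bundles is None:
        bundles = gnn_bundles(seed, "marginal")
    heads = [SUBCLASS_HEAD, MGMT_HEAD, CDKN_HEAD]
    ts = make_training_set(bundles, k=k,
                           val_sections=set(VALIDATION_SAMPLES), seed=seed)
    cfg = GinConfig(hidden_dim=hidden, dropout_p=0.3, epochs=epochs,
                    lr=1e-3, batch_size=64, seed=seed, k=k, heads=heads)
    model = init_model(cfg, ts.train[0].features.shape[1])
    history = train(model, ts.train, cfg)
    logits = predict(model, ts.validation)
    out = {"loss_history": history, "n_validation": len(ts.validation)}
    for head in heads:
        pred = predicted_classes(logits[head.task], head.classes)
        true = [s.labels[head.task] for s in ts.validation]
        out[head.task] = evaluate(pred, true, head.classes)
    votes = predict_participant(logits["methylation_subclass"],
                                SUBCLASS_HEAD.classes,
                                [s.participant for s in ts.validation])
    truth = {b["participant"]: b["dataset"].labels.methylation_subclass
             for b in bundles}
    out["participant_votes"] = votes
    out["participant_accuracy"] = float(np.mean(
        [votes.loc[p, "predicted"] == truth[p] for p in votes.index]))
    return out


def shuffled_null(seed: int, task: str, k: int = 2, epochs: int = 10,
                  hidden: int = 32, bundles: list | None = None) -> float:
    """Label-shuffle null: validation accuracy should sit at chance.

    Training labels for ``task`` are permuted across subgraphs; accuracy
    is computed against the true labels on a class-balanced subsample of
    the validation side (so chance is exactly 1/n_classes regardless of
    class shares).
    """
    if bundles is None:
        bundles = gnn_bundles(seed, "marginal")
    head = {h.task: h for h in (SUBCLASS_HEAD, MGMT_HEAD, CDKN_HEAD)}[task]
    ts = make_training_set(bundles, k=k,
                           val_sections=set(VALIDATION_SAMPLES), seed=seed)
    rng = np.random.default_rng(seed)
    originals = [s.labels[task] for s in ts.train]
    for s, lab in zip(ts.train, rng.permutation(originals)):
        s.labels = dict(s.labels)
        s.labels[task] = lab
    cfg = GinConfig(hidden_dim=hidden, dropout_p=0.3, epochs=epochs,
                    lr=1e-3, batch_size=64, seed=seed, k=k, heads=[head])
    model = init_model(cfg, ts.train[0].features.shape[1])
    train(model, ts.train, cfg)
    # class-balanced validation subsample
    true = np.array([s.labels[task] for s in ts.validation], dtype=object)
    keep: list = []
    counts = pd.Series(true).value_counts()
    n_min = int(counts.min())
    for cls in counts.index:
        keep.extend(list(np.flatnonzero(true == cls)[:n_min]))
    subs = [ts.validation[i] for i in sorted(keep)]
    logits = predict(model, subs)[task]
    pred = predicted_classes(logits, head.classes)
    return float(np.mean(pred == np.array([s.labels[task] for s in subs],
                                          dtype=object)))


# ---------------------------------------------------------------------- #
# CNV recovery
# ---------------------------------------------------------------------- #
def cnv_recovery(seed: int, n_samples: int = 12, grid=(30, 30),
                 n_genes: int = 2000, permute_samples: int = 3) -> dict:
    """Recover planted arm events on the default cohort.

    Scores every sample against its non-tumor (white matter / cortex)
    reference spots, calls arms at the default thresholds and compares to
    the planted truth. The permutation control re-scores the first
    ``permute_samples`` samples with a shuffled gene-to-bin assignment;
    the planted-event effect size (direction times mean arm score,
    averaged over events) should collapse.
    """
    cohort = generate_cohort(n_samples=n_samples, grid=grid,
                             n_genes=n_genes, seed=seed)
    bins = build_bins(cohort.chrom_sizes, arms=cohort.arms)
    gene_bins = assign_genes(cohort.genes, bins)
    rng = np.random.default_rng(seed)
    permuted_bins = pd.Series(rng.permutation(gene_bins.to_numpy()),
                              index=gene_bins.index)

    correct = total = 0
    scores_all, labels_all = [], []
    effects, effects_perm = [], []
    for i, ds in enumerate(cohort.datasets):
        nm = normalize_dataset(ds)
        ref = list(ds.histology.index[ds.histology.isin(REFERENCE_ZONES)])
        profile = score_bins(nm, gene_bins, ref, bins=bins)
        calls = sample_arm_calls(profile)
        truth = pd.Series(cohort.truth.reference_calls[ds.sample_id])
        shared = [a for a in calls.index if a in truth.index]
        correct += int((calls[shared] == truth[shared]).sum())
        total += len(shared)
        arm = profile.arm_scores()
        tumor = [b for b in arm.index if b not in set(ref)]
        mean_arm = arm.loc[tumor].mean(axis=0)
        scores_all.extend(mean_arm[shared].to_list())
        labels_all.extend(truth[shared].to_list())
        for chrom, armside, direction in cohort.truth.events[ds.sample_id]:
            sign = 1.0 if direction == "gain" else -1.0
            effects.append(sign * mean_arm[f"{chrom}{armside}"])
        if i < permute_samples:
            perm_profile = score_bins(nm, permuted_bins, ref, bins=bins)
            perm_arm = perm_profile.arm_scores().loc[tumor].mean(axis=0)
            for chrom, armside, direction in cohort.truth.events[ds.sample_id]:
                sign = 1.0 if direction == "gain" else -1.0
                effects_perm.append(sign * perm_arm[f"{chrom}{armside}"])

    n_perm_events = len(effects_perm)
    return {
        "arm_accuracy": correct / total,
        "auc": roc_gain_loss(np.array(scores_all), np.array(labels_all)),
        "effect_planted": float(np.mean(effects[:n_perm_events])),
        "effect_permuted": float(np.mean(effects_perm)),
        "n_arm_calls": total,
    }


# ---------------------------------------------------------------------- #
# marker image recovery
# ---------------------------------------------------------------------- #
def ihc_recovery(seed: int, grid=(24, 24), n_genes: int = 300) -> dict:
    """Noiseless marker image recovery plus the a=0 null."""
    cohort = generate_cohort(n_samples=2, grid=grid, n_genes=n_genes,
                             n_classes=2, seed=seed, subclass_mode="marginal",
                             events=None)
    ds = cohort.datasets[0]
    nm = normalize_dataset(ds)
    select_hvg_joint([nm], 50)
    gene = str(nm.hvg_ids[0])
    truth = render_marker_image(ds, nm, gene, a=0.8, sigma_noise=0.0,
                                seed=seed)
    noiseless = quantify_marker(ds, nm, gene, sigma=truth["sigma_px"])
    truth0 = render_marker_image(ds, nm, gene, a=0.0, sigma_noise=0.15,
                                 seed=seed)
    null = quantify_marker(ds, nm, gene, sigma=truth0["sigma_px"])
    return {"noiseless_r": noiseless["r"], "null_r": null["r"],
            "n_spots": noiseless["n"], "gene": gene}
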