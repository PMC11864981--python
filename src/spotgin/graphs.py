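"""Spot adjacency graphs, k-hop subgraphs and feature assembly.

Spots sit on the (approximately) hexagonal Visium lattice. Adjacency is
defined by pairwise Euclidean distance: self-distances are replaced by the
sentinel constant 1,000 (coordinates are first rescaled so every true
pairwise distance stays below it), the threshold sits slightly above the
smallest nonzero distance, and pairs within the threshold are adjacent —
at most six neighbors on an ideal lattice. A k-hop subgraph around a
center spot carries concatenated node features (variable-gene expression,
CNV scores, one-hot histology, optional image vectors), a self-loop per
node, and the sample-level diagnostic labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .datasets import HISTOLOGY_CLASSES, TUMOR_CLASSES

logger = logging.getLogger(__name__)

SELF_DISTANCE_SENTINEL = 1_000.0
DEFAULT_THRESHOLD_FACTOR = 1.05


@dataclass
class SpotGraph:
    """Binary symmetric spot adjacency without self-edges."""

    barcodes: np.ndarray
    adjacency: sp.csr_matrix
    threshold_used: float
    n_components: int

    def neighbors(self, idx: int) -> np.ndarray:
        return self.adjacency[idx].indices

    def degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)


@dataclass
class Subgraph:
    """k-hop neighborhood with assembled features and task labels."""

    center: str
    k: int
    nodes: list                      # barcodes, center first
    edge_index: np.ndarray           # 2 x E, incl. one self-loop per node
    features: np.ndarray | None = None
    labels: dict = field(default_factory=dict)
    sample_id: str = ""
    section_id: str = ""
    participant: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_adjacency(coords: np.ndarray, barcodes=None,
                    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR) -> SpotGraph:
    """Distance-threshold adjacency with the 1,000 self-distance sentinel.

    Coordinates are uniformly rescaled (when needed) so the maximum true
    pairwise distance stays below the sentinel, keeping the constant
    meaningful for arbitrary pixel units. Disconnected graphs (multi-biopsy
    slides) are allowed; the component count is logged.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two spots")
    if barcodes is None:
        barcodes = np.array([f"spot{i}" for i in range(n)], dtype=object)
    barcodes = np.asarray(barcodes, dtype=object)

    dist = squareform(pdist(coords))
    off = dist[np.triu_indices(n, k=1)]
    if (off == 0).any():
        raise ValueError("distinct coordinates required")
    max_d = off.max()
    if max_d >= SELF_DISTANCE_SENTINEL:
        dist = dist * ((SELF_DISTANCE_SENTINEL * 0.999) / max_d)
    np.fill_diagonal(dist, SELF_DISTANCE_SENTINEL)
    threshold = threshold_factor * dist[dist > 0].min()
    adj = sp.csr_matrix((dist <= threshold).astype(np.int8))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        logger.info("adjacency has %d connected components", n_comp)
    return SpotGraph(barcodes=barcodes, adjacency=adj,
                     threshold_used=float(threshold), n_components=int(n_comp))


def extract_khop(graph: SpotGraph, center: str, k: int) -> Subgraph:
    """Breadth-first closure within k edges, with induced edges.

    k=0 yields the single center node. Node order: center first, then by
    hop distance (ties in barcode index order).
    """
    if k not in (0, 1, 2, 3):
        raise ValueError("k must be in {0,1,2,3}")
    index = pd.Index(graph.barcodes)
    c = index.get_loc(center)
    frontier = {c}
    seen = {c: 0}
    for hop in range(1, k + 1):
        nxt = set()
        for node in frontier:
            for nb in graph.neighbors(node):
                if nb not in seen:
                    seen[nb] = hop
                    nxt.add(int(nb))
        frontier = nxt
        if not frontier:
            break
    order = sorted(seen, key=lambda i: (seen[i], i))
    rows, cols = [], []
    sub = graph.adjacency[order][:, order].tocoo()
    rows.extend(sub.row)
    cols.extend(sub.col)
    # one self-loop per node so message passing retains own features
    rows.extend(range(len(order)))
    cols.extend(range(len(order)))
    edge_index = np.array([rows, cols], dtype=np.int64)
    return Subgraph(center=center, k=k,
                    nodes=[graph.barcodes[i] for i in order],
                    edge_index=edge_index)


def one_hot_histology(labels: pd.Series | None, barcodes,
                      vocab=HISTOLOGY_CLASSES) -> np.ndarray:
    """One-hot block per spot; unannotated spots are all-zero rows."""
    out = np.zeros((len(barcodes), len(vocab)))
    if labels is None:
        return out
    lut = {c: j for j, c in enumerate(vocab)}
    for i, b in enumerate(barcodes):
        if b in labels.index:
            out[i, lut[labels.loc[b]]] = 1.0
    return out


def assemble_features(sub: Subgraph, nm, cnv_scores: pd.DataFrame | None = None,
                      histology: pd.Series | None = None,
                      image_vectors: pd.DataFrame | None = None,
                      labels=None, sample_id: str = "",
                      section_id: str = "", participant: str = "",
                      histology_vocab=HISTOLOGY_CLASSES) -> Subgraph:
    """Concatenate per-node features in fixed order and attach labels.

    Order: variable-gene expression, CNV scores, one-hot histology,
    optional image vector. Every feature source must cover every node;
    missing histology yields an all-zero one-hot block.
    """
    barcode_pos = pd.Index(nm.barcodes).get_indexer(sub.nodes)
    if (barcode_pos < 0).any():
        raise ValueError("expression matrix does not cover every node")
    blocks = [nm.hvg_values()[:, barcode_pos].T]
    if cnv_scores is not None:
        missing = [b for b in sub.nodes if b not in cnv_scores.index]
        if missing:
            raise ValueError(f"CNV scores missing nodes {missing[:3]}")
        blocks.append(np.nan_to_num(
            cnv_scores.loc[list(sub.nodes)].to_numpy(float)))
    blocks.append(one_hot_histology(histology, sub.nodes, histology_vocab))
    if image_vectors is not None:
        missing = [b for b in sub.nodes if b not in image_vectors.index]
        if missing:
            raise ValueError(f"image vectors missing nodes {missing[:3]}")
        blocks.append(image_vectors.loc[list(sub.nodes)].to_numpy(float))
    widths = {b.shape[0] for b in blocks}
    if widths != {sub.n_nodes}:
        raise ValueError("feature blocks disagree on node count")
    sub.features = np.concatenate(blocks, axis=1)
    if labels is not None:
        hist_center = None
        if histology is not None and sub.center in histology.index:
            hist_center = histology.loc[sub.center]
        sub.labels = {
            "histology": hist_center,
            "methylation_subclass": labels.methylation_subclass,
            "mgmt_status": labels.mgmt_status,
            "cdkn2ab_status": labels.cdkn2ab_status,
        }
    sub.sample_id = sample_id
    sub.section_id = section_id
    sub.participant = participant
    return sub


@dataclass
class TrainingSet:
    train: list
    validation: list
    manifest: dict


def make_training_set(bundles: list, k: int, tumor_filter: bool = True,
                      val_sections: set | None = None,
                      val_fraction: float = 0.25, seed: int = 0,
                      center_stride: int = 1,
                      require_all_classes: bool = True) -> TrainingSet:
    """Build one subgraph per eligible center spot and split by section.

    ``bundles`` is a list of dicts with keys ``dataset`` (SpotDataset with
    coords/histology/labels), ``nm`` (NormalizedMatrix with hvg_ids) and
    optionally ``cnv`` (spots x features score frame) and ``participant``.
    The split never divides a section and never places a participant on
    both sides; each dataset is normalized on its own (per-section
    normalization is independent by construction). ``tumor_filter`` keeps
    subgraphs containing at least one tumor-annotated spot;
    ``center_stride`` subsamples center spots (every stride-th barcode)
    when a cheaper, spatially uniform subgraph set is wanted.
    """
    rng = np.random.default_rng(seed)
    if val_sections is None:
        participants = sorted({b.get("participant", b["dataset"].sample_id)
                               for b in bundles})
        n_val = max(1, int(round(val_fraction * len(participants))))
        val_participants = set(
            rng.choice(participants, size=n_val, replace=False))
        val_sections = {b["dataset"].section_id for b in bundles
                        if b.get("participant", b["dataset"].sample_id)
                        in val_participants}

    hvg_sets = {tuple(map(str, b["nm"].hvg_ids)) for b in bundles}
    if len(hvg_sets) > 1:
        raise ValueError(
            "bundles disagree on the variable-gene list; use "
            "preprocess.select_hvg_joint so node features align")

    train, validation = [], []
    manifest = {"k": k, "tumor_filter": tumor_filter, "sections": []}
    for bundle in bundles:
        ds = bundle["dataset"]
        nm = bundle["nm"]
        cnv_scores = bundle.get("cnv")
        participant = bundle.get("participant", ds.sample_id)
        role = "validation" if ds.section_id in val_sections else "train"
        manifest["sections"].append({"participant": participant,
                                     "section": ds.section_id, "role": role})
        graph = build_adjacency(ds.spot_xy(), barcodes=ds.barcodes)
        tumor_spots = set()
        if ds.histology is not None:
            tumor_spots = set(
                ds.histology.index[ds.histology.isin(TUMOR_CLASSES)])
        subs = []
        for center in ds.barcodes[::center_stride]:
            sub = extract_khop(graph, center, k)
            if tumor_filter and not (set(sub.nodes) & tumor_spots):
                continue
            assemble_features(sub, nm, cnv_scores=cnv_scores,
                              histology=ds.histology, labels=ds.labels,
                              sample_id=ds.sample_id,
                              section_id=ds.section_id,
                              participant=participant)
            subs.append(sub)
        (validation if role == "validation" else train).extend(subs)

    t_parts = {s.participant for s in train}
    v_parts = {s.participant for s in validation}
    if t_parts & v_parts:
        raise ValueError(f"participants on both sides: {t_parts & v_parts}")
    if require_all_classes and train:
        for task in ("methylation_subclass", "mgmt_status", "cdkn2ab_status"):
            train_classes = {s.labels.get(task) for s in train} - {None, "unknown"}
            val_classes = {s.labels.get(task) for s in validation} - {None, "unknown"}
            missing = val_classes - train_classes
            if missing:
                raise ValueError(
                    f"classes absent from training side for {task}: {missing}")
    manifest["n_train"] = len(train)
    manifest["n_validation"] = len(validation)
    return TrainingSet(train=train, validation=validation, manifest=manifest)
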