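"""Data model and on-disk formats for spot-level spatial transcriptomics.

The central container is :class:`SpotDataset`: a genes x spots count matrix
(10X MatrixMarket convention with ``features.tsv`` / ``barcodes.tsv``
sidecars), per-spot array and pixel coordinates (``tissue_positions`` CSV
dialect), optional per-spot histology annotations and an optional stain
image. Genomic gene coordinates are carried as a :class:`GeneAnnotation`
table read from BED4 and converted to 1-based inclusive coordinates, the
convention used by the genomic-bin arithmetic in :mod:`spotgin.cnv`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: closed vocabulary of per-spot histology labels
HISTOLOGY_CLASSES = (
    "main tumor",
    "necrosis",
    "infiltrative tumor",
    "white matter",
    "cortex",
    "arachnoidea",
    "healthy",
)

#: labels regarded as tumor tissue by the subgraph tumor filter
TUMOR_CLASSES = ("main tumor", "infiltrative tumor")

MGMT_STATUSES = ("methylated", "unmethylated", "unknown")
CDKN2AB_STATUSES = ("none", "heterozygous", "homozygous", "unknown")

POSITION_COLUMNS = ("barcode", "in_tissue", "array_row", "array_col", "px_x", "px_y")


class FormatError(ValueError):
    """Malformed on-disk input (dimension mismatch, missing column, ...)."""


class ValidationError(ValueError):
    """In-memory data violating a container invariant."""


@dataclass
class SampleLabels:
    """Per-sample diagnostic labels attached to every subgraph of the sample."""

    sample_id: str
    methylation_subclass: str = "unknown"
    mgmt_status: str = "unknown"
    cdkn2ab_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.mgmt_status not in MGMT_STATUSES:
            raise ValidationError(
                f"mgmt_status {self.mgmt_status!r} not in {MGMT_STATUSES}"
            )
        if self.cdkn2ab_status not in CDKN2AB_STATUSES:
            raise ValidationError(
                f"cdkn2ab_status {self.cdkn2ab_status!r} not in {CDKN2AB_STATUSES}"
            )

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "methylation_subclass": self.methylation_subclass,
            "mgmt_status": self.mgmt_status,
            "cdkn2ab_status": self.cdkn2ab_status,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleLabels":
        return cls(
            sample_id=d["sample_id"],
            methylation_subclass=d.get("methylation_subclass", "unknown"),
            mgmt_status=d.get("mgmt_status", "unknown"),
            cdkn2ab_status=d.get("cdkn2ab_status", "unknown"),
        )


@dataclass
class SpotDataset:
    """Counts, coordinates and annotations for one tissue section / biopsy.

    ``counts`` is a sparse genes x spots matrix of non-negative integers.
    ``coords`` is indexed by barcode with columns ``array_row``,
    ``array_col``, ``px_x``, ``px_y``, ``in_tissue``. ``histology`` maps a
    subset of barcodes to labels from :data:`HISTOLOGY_CLASSES`.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    coords: pd.DataFrame | None = None
    sample_id: str = "sample"
    section_id: str = "section"
    histology: pd.Series | None = None
    labels: SampleLabels | None = None
    image: np.ndarray | None = None  # HxWx3 uint8
    image_scale: float = 1.0  # pixels of `image` per unit of px_x / px_y
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer counts")
        if self.histology is not None:
            unknown = set(self.histology.index) - set(self.barcodes)
            if unknown:
                raise ValidationError(
                    f"histology barcodes absent from counts: {sorted(unknown)[:5]}"
                )
            bad = set(self.histology.values) - set(HISTOLOGY_CLASSES)
            if bad:
                raise ValidationError(f"unknown histology labels: {sorted(bad)}")
        if self.coords is not None:
            missing = [c for c in POSITION_COLUMNS[1:] if c not in self.coords.columns]
            if missing:
                raise ValidationError(f"coords missing columns {missing}")

    # ------------------------------------------------------------------ #
    def subset_spots(self, barcodes: np.ndarray) -> "SpotDataset":
        """Restrict the dataset to the given barcodes (order preserved)."""
        index = pd.Index(self.barcodes)
        pos = index.get_indexer(barcodes)
        if (pos < 0).any():
            raise ValidationError("subset barcode absent from dataset")
        hist = None
        if self.histology is not None:
            keep = self.histology.index.isin(barcodes)
            hist = self.histology[keep]
        return SpotDataset(
            counts=self.counts[:, pos].tocsr(),
            gene_ids=self.gene_ids,
            barcodes=np.asarray(barcodes, dtype=object),
            coords=None if self.coords is None else self.coords.loc[barcodes],
            sample_id=self.sample_id,
            section_id=self.section_id,
            histology=hist,
            labels=self.labels,
            image=self.image,
            image_scale=self.image_scale,
            meta=dict(self.meta),
        )

    def drop_zero_spots(self) -> "SpotDataset":
        """Drop spots with zero total UMIs (normalization divides by totals)."""
        totals = np.asarray(self.counts.sum(axis=0)).ravel()
        keep = totals > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d zero-UMI spots", n_drop)
            return self.subset_spots(self.barcodes[keep])
        return self

    def spot_xy(self) -> np.ndarray:
        """Pixel coordinates as an (n_spots, 2) float array."""
        if self.coords is None:
            raise ValidationError("dataset has no coordinates")
        return self.coords.loc[self.barcodes, ["px_x", "px_y"]].to_numpy(float)


# ---------------------------------------------------------------------- #
# readers
# ---------------------------------------------------------------------- #
def _read_single_column_tsv(path, what: str) -> np.ndarray:
    table = pd.read_csv(path, sep="\t", header=None)
    values = table.iloc[:, 0].astype(str).to_numpy(dtype=object)
    if len(set(values)) != len(values):
        raise FormatError(f"duplicate entries in {what} file {path}")
    return values


def read_counts(mtx_path, features_path, barcodes_path, sample_id="sample",
                section_id="section") -> SpotDataset:
    """Read a 10X-convention triplet (matrix.mtx + features.tsv + barcodes.tsv)."""
    matrix = scipy.io.mmread(str(mtx_path))
    gene_ids = _read_single_column_tsv(features_path, "features")
    barcodes = _read_single_column_tsv(barcodes_path, "barcodes")
    if matrix.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"{mtx_path}: declared shape {matrix.shape} does not match sidecars "
            f"({len(gene_ids)} features, {len(barcodes)} barcodes)"
        )
    data = matrix.data if sp.issparse(matrix) else np.asarray(matrix).ravel()
    if data.size and not np.allclose(data, np.round(data)):
        raise ValidationError(f"{mtx_path}: non-integer matrix values")
    counts = sp.csr_matrix(matrix, dtype=np.int64)
    return SpotDataset(counts=counts, gene_ids=gene_ids, barcodes=barcodes,
                       sample_id=sample_id, section_id=section_id)


def read_positions(csv_path) -> pd.DataFrame:
    """Read a tissue-positions CSV (10X dialect) indexed by barcode."""
    table = pd.read_csv(csv_path)
    missing = [c for c in POSITION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing columns {missing}")
    table = table.set_index("barcode")
    return table


def attach_positions(dataset: SpotDataset, csv_path, keep_all: bool = False) -> SpotDataset:
    """Attach coordinates to a dataset; by default restrict to in-tissue spots.

    Position-table barcodes absent from the counts are dropped with a
    warning; counts barcodes without a position are dropped as well.
    """
    pos = read_positions(csv_path)
    extra = set(pos.index) - set(dataset.barcodes)
    if extra:
        warnings.warn(f"{len(extra)} position barcodes absent from counts; dropped")
        pos = pos.loc[[b for b in pos.index if b not in extra]]
    if not keep_all:
        pos = pos[pos["in_tissue"] == 1]
        if pos.empty:
            raise FormatError(f"{csv_path}: no tissue spots (in_tissue==1)")
    barcodes = np.asarray([b for b in dataset.barcodes if b in set(pos.index)],
                          dtype=object)
    out = dataset.subset_spots(barcodes)
    out.coords = pos.loc[barcodes]
    out.validate()
    return out


def read_gene_bed(bed_path) -> pd.DataFrame:
    """Read a BED4 gene table, converting to 1-based inclusive coordinates.

    On disk BED is 0-based half-open; internally ``start = bed_start + 1``
    and ``end = bed_end``. The table is sorted by (chrom, start) and indexed
    by gene id. An optional 5th column is interpreted as a probe count.
    """
    table = pd.read_csv(bed_path, sep=r"\s+", header=None, comment="#")
    if table.shape[1] < 4:
        raise FormatError(f"{bed_path}: BED4 requires chrom/start/end/name")
    table = table.iloc[:, :5] if table.shape[1] >= 5 else table.iloc[:, :4]
    cols = ["chrom", "start", "end", "gene_id"] + (
        ["n_probes"] if table.shape[1] == 5 else [])
    table.columns = cols
    if (table["start"] < 0).any() or (table["end"] < table["start"]).any():
        raise FormatError(f"{bed_path}: negative coordinates or end < start")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{bed_path}: gene listed twice: {dup}")
    table["start"] = table["start"].astype(np.int64) + 1
    table["end"] = table["end"].astype(np.int64)
    table["chrom"] = table["chrom"].astype(str)
    table = table.sort_values(["chrom", "start"], kind="stable")
    return table.set_index("gene_id")


def read_histology(tsv_path) -> pd.Series:
    """Read a per-spot histology annotation TSV (barcode, label)."""
    table = pd.read_csv(tsv_path, sep="\t")
    if not {"barcode", "label"} <= set(table.columns):
        raise FormatError(f"{tsv_path}: needs 'barcode' and 'label' columns")
    return pd.Series(table["label"].values, index=table["barcode"].values,
                     name="histology")


def read_labels(json_path) -> SampleLabels:
    with open(json_path) as fh:
        return SampleLabels.from_dict(json.load(fh))


# ---------------------------------------------------------------------- #
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------- #
def write_counts(dataset: SpotDataset, mtx_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(dataset.counts), field="integer")
    pd.Series(dataset.gene_ids).to_csv(features_path, sep="\t", header=False,
                                       index=False)
    pd.Series(dataset.barcodes).to_csv(barcodes_path, sep="\t", header=False,
                                       index=False)


def write_positions(dataset: SpotDataset, csv_path) -> None:
    if dataset.coords is None:
        raise ValidationError("dataset has no coordinates")
    out = dataset.coords.reset_index().rename(columns={"index": "barcode"})
    out.to_csv(csv_path, index=False)


def write_histology(dataset: SpotDataset, tsv_path) -> None:
    if dataset.histology is None:
        raise ValidationError("dataset has no histology")
    pd.DataFrame({"barcode": dataset.histology.index,
                  "label": dataset.histology.values}).to_csv(
        tsv_path, sep="\t", index=False)


def write_gene_bed(genes: pd.DataFrame, bed_path) -> None:
    """Write a GeneAnnotation table back to BED4(+probes)."""
    cols = ["chrom", "start", "end", "gene_id"]
    if "n_probes" in genes.columns:
        cols.append("n_probes")
    out = genes.reset_index()[cols]
    out["start"] = out["start"].astype(np.int64) - 1  # back to BED 0-based
    out.to_csv(bed_path, sep="\t", header=False, index=False)


def write_labels(labels: SampleLabels, json_path) -> None:
    with open(json_path, "w") as fh:
        json.dump(labels.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------- #
def qc_summary(dataset: SpotDataset) -> dict:
    """Per-spot UMI totals / genes detected and dataset-level medians.

    Returns a JSON-serializable dict: ``umi_per_spot`` and
    ``genes_per_spot`` keyed by barcode plus ``median_umi`` /
    ``median_genes`` / ``n_spots`` / ``n_genes``.
    """
    totals = np.asarray(dataset.counts.sum(axis=0)).ravel()
    detected = np.asarray((dataset.counts > 0).sum(axis=0)).ravel()
    return {
        "sample_id": dataset.sample_id,
        "n_spots": int(dataset.n_spots),
        "n_genes": int(dataset.n_genes),
        "umi_per_spot": {b: int(t) for b, t in zip(dataset.barcodes, totals)},
        "genes_per_spot": {b: int(d) for b, d in zip(dataset.barcodes, detected)},
        "median_umi": float(np.median(totals)) if totals.size else 0.0,
        "median_genes": float(np.median(detected)) if detected.size else 0.0,
    }
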