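"""Ground-truthed synthetic cohorts emulating every pipeline input.

The generator lays spots on a hexagonal lattice, draws negative-binomial
counts from class-, zone- and label-specific expression programs, plants
arm-level copy-number events (expected counts scaled before noise), and
can render a marker-tracking stain image and spot-level deconvolution
scores with nucleus positions. Every random artifact records its seed and
the planted truth, so recovery can be checked end to end.

Two subclass constructions are offered:

* ``texture`` — all classes share identical per-spot marginal signatures
  (a 50/50 mixture of two spot programs) and differ only in the spatial
  arrangement (alternating row stripes of class-specific width), so the
  class is invisible to any single spot and only neighborhoods carry it;
* ``marginal`` — each class up-regulates its own gene block in every
  tumor spot, a purely spot-local signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import SampleLabels, SpotDataset
from .ihc import IntensityField, gaussian_smooth

HEX_ROW_SPACING = np.sqrt(3.0) / 2.0
PIXELS_PER_UNIT = 100.0        # pixel coordinates = 100 x lattice units

SUBCLASSES = ("GB-RTKI", "GB-RTKII", "GB-MES", "ASTRO-IDH")
CELL_TYPES = ("tumor", "astrocyte", "monocyte", "tcell", "endothelial",
              "oligodendrocyte")

#: fraction of grid columns per histology zone, left to right
ZONE_LAYOUT = (
    ("main tumor", 0.45),
    ("infiltrative tumor", 0.15),
    ("necrosis", 0.10),
    ("white matter", 0.15),
    ("cortex", 0.15),
)
TUMOR_ZONES = ("main tumor", "infiltrative tumor", "necrosis")
REFERENCE_ZONES = ("white matter", "cortex")

#: default planted arm events, cycled across samples (program genes live on
#: chr1/chr2, so default events avoid them)
DEFAULT_EVENT_POOL = (
    ("chr3", "p", "gain"), ("chr4", "q", "loss"), ("chr5", "p", "loss"),
    ("chr6", "q", "gain"), ("chr7", "p", "gain"), ("chr8", "q", "loss"),
)

def _program_indices(n_genes: int) -> dict:
    """Indices of program genes, spread uniformly across the genome.

    Marker programs in real tissue are scattered over chromosomes; keeping
    them spread (and interleaving the two texture programs) prevents
    class/label programs from masquerading as copy-number events in any
    single genomic bin.
    """
    reserved = np.unique(np.round(np.linspace(0, n_genes - 1, 200)).astype(int))
    sig = reserved[:50]
    hist = reserved[50:150]
    return {
        "texture0": sig[::2], "texture1": sig[1::2],
        "marginal": sig[:48],
        "histology": [hist[z::5][:20] for z in range(5)],
        "mgmt": reserved[150:170],
        "cdkn2ab": reserved[170:185],        # locus program, lost with deletion
        "cdkn2ab_up": reserved[185:200],     # de-repressed cell-cycle targets
    }


# ---------------------------------------------------------------------- #
# genome and lattice
# ---------------------------------------------------------------------- #
def default_genome(n_genes: int = 2000, n_chroms: int = 8,
                   chrom_size: int = 60_000_000, seed: int = 0):
    """Uniformly spaced genes on equal-size chromosomes; arms are halves.

    Returns (chrom_sizes, arms, genes) where genes is indexed by gene id
    with chrom/start/end/n_probes columns (1-based inclusive).
    """
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chroms)}
    arms = {c: s // 2 for c, s in chrom_sizes.items()}
    per = int(np.ceil(n_genes / n_chroms))
    spacing = chrom_size // (per + 1)
    rng = np.random.default_rng(seed)
    rows = []
    g = 0
    for ci in range(n_chroms):
        for j in range(per):
            if g >= n_genes:
                break
            start = (j + 1) * spacing
            rows.append((f"G{g:05d}", f"chr{ci + 1}", start, start + 999,
                         int(rng.integers(5, 41))))
            g += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "n_probes"]).set_index("gene_id")
    return chrom_sizes, arms, genes


def hex_grid(rows: int, cols: int) -> pd.DataFrame:
    """Hex lattice coordinates: odd rows shifted half a pitch."""
    recs = []
    for r in range(rows):
        for c in range(cols):
            recs.append((f"S{r:03d}C{c:03d}-1", 1, r, c,
                         PIXELS_PER_UNIT * (c + 0.5 * (r % 2)),
                         PIXELS_PER_UNIT * HEX_ROW_SPACING * r))
    coords = pd.DataFrame(recs, columns=["barcode", "in_tissue", "array_row",
                                         "array_col", "px_x", "px_y"])
    return coords.set_index("barcode")


def zone_map(coords: pd.DataFrame) -> pd.Series:
    """Histology label per spot: contiguous vertical zones of the grid."""
    cols = coords["array_col"]
    n_cols = cols.max() + 1
    edges = np.cumsum([f for _, f in ZONE_LAYOUT]) * n_cols
    labels = []
    for c in cols:
        for (name, _), edge in zip(ZONE_LAYOUT, edges):
            if c < edge - 1e-9:
                labels.append(name)
                break
        else:
            labels.append(ZONE_LAYOUT[-1][0])
    return pd.Series(labels, index=coords.index, name="histology")


def stripe_widths(rows: int, n_classes: int) -> list:
    """Class-specific stripe widths keeping an exact 50/50 type mixture.

    Widths 1, 2, 3, 6, ... are preferred (subject to the balance
    constraint): these give each class a distinct per-node neighbor
    composition on the hex lattice, while stripes wider than a 3-hop
    patch (7 rows) would be indistinguishable from each other for
    interior centers.
    """
    widths = [w for w in range(1, rows // 2 + 1) if rows % (2 * w) == 0]
    if len(widths) < n_classes:
        raise ValueError(
            f"{rows} rows support only {len(widths)} balanced stripe "
            f"widths; need {n_classes}")
    preferred = [1, 2, 3, 6, 12, 24]
    chosen = [w for w in preferred if w in widths][:n_classes]
    chosen += [w for w in widths if w not in chosen][: n_classes - len(chosen)]
    return sorted(chosen)


# ---------------------------------------------------------------------- #
# truth containers
# ---------------------------------------------------------------------- #
@dataclass
class SyntheticTruth:
    seed: int
    subclass: dict = field(default_factory=dict)
    mgmt: dict = field(default_factory=dict)
    cdkn2ab: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    reference_calls: dict = field(default_factory=dict)
    spot_type: dict = field(default_factory=dict)
    stripe_width: dict = field(default_factory=dict)
    program_genes: dict = field(default_factory=dict)
    marker: dict = field(default_factory=dict)
    cell_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed, "subclass": self.subclass, "mgmt": self.mgmt,
            "cdkn2ab": self.cdkn2ab,
            "events": {k: [list(e) for e in v] for k, v in self.events.items()},
            "reference_calls": self.reference_calls,
            "stripe_width": self.stripe_width,
            "program_genes": self.program_genes,
            "marker": self.marker,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    datasets: list
    genes: pd.DataFrame
    chrom_sizes: dict
    arms: dict
    truth: SyntheticTruth

    def dataset(self, sample_id: str) -> SpotDataset:
        for ds in self.datasets:
            if ds.sample_id == sample_id:
                return ds
        raise KeyError(sample_id)


# ---------------------------------------------------------------------- #
# CNV planting
# ---------------------------------------------------------------------- #
def plant_cnv(means: np.ndarray, genes: pd.DataFrame, arms: dict,
              events, tumor_mask: np.ndarray,
              multiplier_gain: float = 1.5,
              multiplier_loss: float = 0.5) -> tuple[np.ndarray, dict]:
    """Scale expected counts on event arms (tumor spots) before noise.

    ``events`` is a list of (chrom, arm, direction); returns the modified
    mean matrix and the reference arm-call table (every autosome arm
    present, neutral unless altered).
    """
    means = means.copy()
    reference = {f"{c}{a}": 0 for c in arms for a in ("p", "q")}
    mids = ((genes["start"] + genes["end"]) // 2).to_numpy()
    for chrom, arm, direction in events:
        if chrom not in arms:
            raise ValueError(f"unknown chromosome {chrom}")
        boundary = arms[chrom]
        on_arm = (genes["chrom"] == chrom).to_numpy() & (
            (mids <= boundary) if arm == "p" else (mids > boundary))
        mult = multiplier_gain if direction == "gain" else multiplier_loss
        means[np.ix_(on_arm, tumor_mask)] *= mult
        reference[f"{chrom}{arm}"] = 1 if direction == "gain" else -1
    return means, reference


# ---------------------------------------------------------------------- #
# cohort generation
# ---------------------------------------------------------------------- #
def generate_cohort(n_samples: int = 12, grid: tuple = (30, 30),
                    n_genes: int = 2000, n_classes: int = 4,
                    seed: int = 0, subclass_mode: str = "texture",
                    events: str | dict | None = "default",
                    dispersion: float = 0.5,
                    signature_multiplier: float = 6.0,
                    histology_multiplier: float = 4.0,
                    mgmt_multiplier: float = 3.0,
                    cdkn2ab_factors: tuple = (1.0, 0.55, 0.2),
                    cdkn2ab_up_factors: tuple = (1.0, 1.7, 2.8),
                    multiplier_gain: float = 1.5,
                    multiplier_loss: float = 0.5) -> SyntheticCohort:
    """Generate a labeled cohort of hex-lattice sections with planted truth.

    Each sample carries: a methylation-subclass program (``subclass_mode``),
    contiguous histology zones with zone marker programs, an MGMT-like and
    a CDKN2A/B-like expression program in tumor spots, and (optionally)
    two arm-level CNV events. Counts are negative binomial with the given
    dispersion (variance = m + dispersion * m^2).

    The CDKN2A/B genotype acts on two gene sets, mirroring the biology of
    the deletion: the locus program itself is lost with increasing dosage
    (``cdkn2ab_factors``) while downstream cell-cycle targets are
    de-repressed (``cdkn2ab_up_factors``).
    """
    rows, cols = grid
    if rows < 8 or cols < 8:
        raise ValueError("grid must be at least 8x8")
    if n_genes < 200:
        raise ValueError("need at least 200 genes")
    if n_classes > len(SUBCLASSES):
        raise ValueError(f"at most {len(SUBCLASSES)} subclasses supported")

    chrom_sizes, arms, genes = default_genome(n_genes, seed=seed)
    gene_ids = genes.index.to_numpy(dtype=object)
    coords = hex_grid(rows, cols)
    zones = zone_map(coords)
    n_spots = len(coords)
    zone_names = [z for z, _ in ZONE_LAYOUT]
    if subclass_mode == "texture":
        widths = stripe_widths(rows, n_classes)

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_samples + 1)
    base_rng = np.random.default_rng(children[0])
    # gene base means shared across the cohort (a common probe panel)
    mu = base_rng.lognormal(mean=-0.7, sigma=1.0, size=n_genes)

    prog = _program_indices(n_genes)
    truth = SyntheticTruth(seed=seed)
    truth.program_genes = {
        name: [str(gene_ids[i]) for i in np.ravel(idx)]
        for name, idx in prog.items()}
    datasets = []
    tumor_mask_arr = zones.isin(TUMOR_ZONES).to_numpy()

    for si in range(n_samples):
        rng = np.random.default_rng(children[si + 1])
        sample_id = f"SYN{si:02d}"
        subclass_idx = si % n_classes
        subclass = SUBCLASSES[subclass_idx]
        mgmt = "methylated" if si % 2 == 0 else "unmethylated"
        cdkn_idx = si % 3
        cdkn2ab = ("none", "heterozygous", "homozygous")[cdkn_idx]

        lib = rng.lognormal(mean=0.0, sigma=0.15, size=n_spots)
        means = mu[:, None] * lib[None, :]

        # subclass program
        if subclass_mode == "texture":
            w = widths[subclass_idx]
            spot_type = ((coords["array_row"] // w) % 2).to_numpy()
            means[np.ix_(prog["texture0"], spot_type == 0)] *= signature_multiplier
            means[np.ix_(prog["texture1"], spot_type == 1)] *= signature_multiplier
            truth.stripe_width[sample_id] = int(w)
            truth.spot_type[sample_id] = pd.Series(spot_type,
                                                   index=coords.index)
        elif subclass_mode == "marginal":
            block = len(prog["marginal"]) // n_classes
            idx = prog["marginal"][subclass_idx * block:(subclass_idx + 1) * block]
            means[np.ix_(idx, tumor_mask_arr)] *= signature_multiplier
        else:
            raise ValueError("subclass_mode must be 'texture' or 'marginal'")

        # histology zone markers
        for zi, zname in enumerate(zone_names):
            zmask = (zones == zname).to_numpy()
            means[np.ix_(prog["histology"][zi], zmask)] *= histology_multiplier

        # MGMT-like and CDKN2A/B-like programs in tumor spots
        if mgmt == "methylated":
            means[np.ix_(prog["mgmt"], tumor_mask_arr)] *= mgmt_multiplier
        means[np.ix_(prog["cdkn2ab"], tumor_mask_arr)] *= cdkn2ab_factors[cdkn_idx]
        means[np.ix_(prog["cdkn2ab_up"], tumor_mask_arr)] *= cdkn2ab_up_factors[cdkn_idx]

        # CNV events
        if events == "default":
            sample_events = [DEFAULT_EVENT_POOL[(2 * si) % len(DEFAULT_EVENT_POOL)],
                             DEFAULT_EVENT_POOL[(2 * si + 1) % len(DEFAULT_EVENT_POOL)]]
        elif events is None:
            sample_events = []
        else:
            sample_events = list(events.get(sample_id, []))
        means, reference = plant_cnv(means, genes, arms, sample_events,
                                     tumor_mask_arr, multiplier_gain,
                                     multiplier_loss)

        counts = _negative_binomial(rng, means, dispersion)
        ds = SpotDataset(
            counts=sp.csr_matrix(counts), gene_ids=gene_ids,
            barcodes=coords.index.to_numpy(dtype=object),
            coords=coords.copy(), sample_id=sample_id, section_id=sample_id,
            histology=zones.copy(),
            labels=SampleLabels(sample_id=sample_id,
                                methylation_subclass=subclass,
                                mgmt_status=mgmt, cdkn2ab_status=cdkn2ab),
        ).drop_zero_spots()
        datasets.append(ds)
        truth.subclass[sample_id] = subclass
        truth.mgmt[sample_id] = mgmt
        truth.cdkn2ab[sample_id] = cdkn2ab
        truth.events[sample_id] = sample_events
        truth.reference_calls[sample_id] = reference

    return SyntheticCohort(datasets=datasets, genes=genes,
                           chrom_sizes=chrom_sizes, arms=arms, truth=truth)


def _negative_binomial(rng: np.random.Generator, means: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: variance = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(means)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------- #
# marker stain image
# ---------------------------------------------------------------------- #
def render_marker_image(dataset: SpotDataset, nm, gene: str, a: float = 0.8,
                        sigma_noise: float = 0.15, seed: int = 0,
                        image_scale: float = 0.08,
                        sigma_fraction: float = 0.2) -> dict:
    """Render a stain image whose blue channel tracks a marker gene.

    Pixel intensity = minmax(a * kernel-smoothed marker expression) plus
    Gaussian noise, clipped to [0,1]. The rendering bandwidth is
    ``sigma_fraction`` of the spot pitch, i.e. sub-pitch (a Visium capture
    spot is ~55 um wide on a 100 um pitch): each spot's footprint carries
    its own expression level rather than a neighborhood average. The image and scale are attached to the dataset; the
    coefficients are returned and recorded as truth.
    """
    xy = dataset.spot_xy() * image_scale
    expr = nm.values[nm.gene_index([gene])[0]]
    lo, hi = expr.min(), expr.max()
    z = (expr - lo) / (hi - lo) if hi > lo else np.zeros_like(expr)
    pitch = _lattice_pitch(xy)
    field = IntensityField(x=xy[:, 0], y=xy[:, 1], z=z,
                           sigma=sigma_fraction * pitch)

    margin = 4
    W = int(np.ceil(xy[:, 0].max())) + margin
    H = int(np.ceil(xy[:, 1].max())) + margin
    yy, xx = np.mgrid[0:H, 0:W]
    queries = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    smoothed = gaussian_smooth(field, queries).reshape(H, W)

    signal = a * smoothed
    lo, hi = signal.min(), signal.max()
    signal = (signal - lo) / (hi - lo) if hi > lo else np.zeros_like(signal)
    rng = np.random.default_rng(seed)
    if sigma_noise > 0:
        signal = signal + rng.normal(0.0, sigma_noise, size=signal.shape)
    signal = np.clip(signal, 0.0, 1.0)

    image = np.empty((H, W, 3), dtype=np.uint8)
    image[..., 0] = 128
    image[..., 1] = 128
    image[..., 2] = np.round(255.0 * signal).astype(np.uint8)
    dataset.image = image
    dataset.image_scale = image_scale
    truth = {"gene": gene, "a": a, "sigma_noise": sigma_noise, "seed": seed,
             "image_scale": image_scale,
             "sigma_px": float(sigma_fraction * pitch)}
    return truth


def _lattice_pitch(xy: np.ndarray) -> float:
    from scipy.spatial.distance import pdist
    sub = xy[: min(len(xy), 300)]
    return float(pdist(sub).min())


# ---------------------------------------------------------------------- #
# deconvolution scores and nuclei
# ---------------------------------------------------------------------- #
def generate_deconvolution(dataset: SpotDataset, n_types: int = 5,
                           concentration: float = 1.0,
                           noise_sd: float = 0.05,
                           seed: int = 0) -> dict:
    """Dirichlet cell-type proportions, true counts, scores and nuclei.

    True per-spot cell counts N_j mirror tissue density: 7-15 in tumor
    zones, 0-5 in healthy zones, 3-9 in between. True counts are
    multinomial draws from the Dirichlet proportions; scores are the true
    counts plus half-normal noise; nuclei are placed uniformly inside the
    spot footprint.
    """
    types = list(CELL_TYPES[:n_types])
    rng = np.random.default_rng(seed)
    zones = dataset.histology
    xy = dataset.spot_xy()
    pitch = _lattice_pitch(xy)
    counts_rows, score_rows, nuc_rows = {}, {}, []
    for i, barcode in enumerate(dataset.barcodes):
        zone = zones.loc[barcode] if zones is not None else "main tumor"
        if zone in ("main tumor",):
            n = int(rng.integers(7, 16))
        elif zone in REFERENCE_ZONES + ("healthy", "arachnoidea"):
            n = int(rng.integers(0, 6))
        else:
            n = int(rng.integers(3, 10))
        props = rng.dirichlet([concentration] * n_types)
        true = rng.multinomial(n, props)
        noise = np.abs(rng.normal(0.0, noise_sd, size=n_types)) \
            if noise_sd > 0 else np.zeros(n_types)
        counts_rows[barcode] = true
        score_rows[barcode] = true + noise
        for _ in range(n):
            ang = rng.uniform(0, 2 * np.pi)
            rad = 0.4 * pitch * np.sqrt(rng.uniform())
            nuc_rows.append((xy[i, 0] + rad * np.cos(ang),
                             xy[i, 1] + rad * np.sin(ang), barcode))
    true_counts = pd.DataFrame.from_dict(counts_rows, orient="index",
                                         columns=types)
    scores = pd.DataFrame.from_dict(score_rows, orient="index", columns=types)
    nuclei = pd.DataFrame(nuc_rows, columns=["x", "y", "barcode"])
    return {"scores": scores, "true_counts": true_counts, "nuclei": nuclei,
            "types": types, "seed": seed}


# ---------------------------------------------------------------------- #
# on-disk layout
# ---------------------------------------------------------------------- #
def save_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the cohort in the directory layout the pipeline consumes.

    Per sample: matrix.mtx / features.tsv / barcodes.tsv /
    tissue_positions.csv / histology.tsv / labels.json (+ image.png when
    present). Cohort level: genes.bed, chrom_sizes.tsv, arms.tsv,
    truth.json. Regeneration under the same seed is byte-identical.
    """
    from pathlib import Path

    from . import datasets as dio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in cohort.datasets:
        d = out / ds.sample_id
        d.mkdir(exist_ok=True)
        dio.write_counts(ds, d / "matrix.mtx", d / "features.tsv",
                         d / "barcodes.tsv")
        dio.write_positions(ds, d / "tissue_positions.csv")
        dio.write_histology(ds, d / "histology.tsv")
        dio.write_labels(ds.labels, d / "labels.json")
        if ds.image is not None:
            from PIL import Image
            Image.fromarray(ds.image).save(d / "image.png")
    dio.write_gene_bed(cohort.genes, out / "genes.bed")
    pd.Series(cohort.chrom_sizes).to_csv(out / "chrom_sizes.tsv", sep="\t",
                                         header=False)
    pd.Series(cohort.arms).to_csv(out / "arms.tsv", sep="\t", header=False)
    (out / "truth.json").write_text(cohort.truth.to_json() + "\n")
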