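"""Expression-inferred copy-number profiles per spot.

Genes are pooled into fixed-width genomic bins (1 Mbp by default), per-gene
log expression is centered against a reference set of non-tumor spots,
clamped, averaged per bin, smoothed along each chromosome, detrended with a
loess fit over the genome-wide bin index, and median-centered per spot.
Scores above/below symmetric thresholds become gain/loss calls, at bin or
chromosome-arm level, and calls are validated against an external
(methylation-array-like) reference profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1_000_000
DEFAULT_CLAMP = 3.0
DEFAULT_SMOOTH_WINDOW = 2     # running-mean half-width, in bins
DEFAULT_LOESS_SPAN = 0.5
DEFAULT_TAU_LOSS = 0.15
DEFAULT_TAU_GAIN = 0.15

CALL_LOSS, CALL_NEUTRAL, CALL_GAIN = -1, 0, 1
CALL_NAMES = {CALL_LOSS: "loss", CALL_NEUTRAL: "neutral", CALL_GAIN: "gain"}
CALL_CODES = {v: k for k, v in CALL_NAMES.items()}


# ---------------------------------------------------------------------- #
# bins
# ---------------------------------------------------------------------- #
def build_bins(chrom_sizes: dict, width: int = DEFAULT_BIN_WIDTH,
               arms: dict | None = None) -> pd.DataFrame:
    """Tile each chromosome with ``width``-bp bins (last bin may be shorter).

    ``arms`` optionally maps chromosome -> last base of the p arm; bins are
    labelled 'p' or 'q' by their midpoint, 'unknown' when no arm table is
    given. Returns a DataFrame with chrom/start/end/width/arm and a strictly
    increasing genome-wide ``index``.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        start = 1
        while start <= size:
            end = min(start + width - 1, size)
            if arms and chrom in arms:
                mid = (start + end) // 2
                arm = "p" if mid <= arms[chrom] else "q"
            else:
                arm = "unknown"
            rows.append((chrom, start, end, end - start + 1, arm))
            start = end + 1
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "width", "arm"])
    bins.index.name = "index"
    return bins


def assign_genes(genes: pd.DataFrame, bins: pd.DataFrame) -> pd.Series:
    """Map each gene to the bin containing its midpoint floor((start+end)/2).

    Genes on chromosomes absent from the bin table are skipped with a
    warning. Returns a Series gene_id -> bin index.
    """
    mapping = {}
    skipped = 0
    by_chrom = {c: g for c, g in bins.groupby("chrom")}
    for gene_id, row in genes.iterrows():
        chrom_bins = by_chrom.get(row["chrom"])
        if chrom_bins is None:
            skipped += 1
            continue
        mid = (int(row["start"]) + int(row["end"])) // 2
        starts = chrom_bins["start"].to_numpy()
        j = int(np.searchsorted(starts, mid, side="right")) - 1
        if j < 0 or mid > int(chrom_bins["end"].iloc[j]):
            skipped += 1
            continue
        mapping[gene_id] = int(chrom_bins.index[j])
    if skipped:
        logger.warning("assign_genes: skipped %d genes outside the bin table",
                       skipped)
    return pd.Series(mapping, name="bin", dtype=int)


# ---------------------------------------------------------------------- #
# scoring
# ---------------------------------------------------------------------- #
@dataclass
class CnvProfile:
    """Per-spot x per-bin alteration scores plus discrete calls."""

    scores: pd.DataFrame                 # spots x bins (columns = bin index)
    bins: pd.DataFrame
    reference_spots: list
    tau_loss: float = DEFAULT_TAU_LOSS
    tau_gain: float = DEFAULT_TAU_GAIN
    calls: pd.DataFrame | None = None    # filled by call_alterations

    def arm_scores(self) -> pd.DataFrame:
        """Mean score per (chrom, arm) across each arm's non-missing bins."""
        key = self.bins.loc[self.scores.columns].apply(
            lambda r: f"{r['chrom']}{r['arm']}", axis=1)
        return self.scores.T.groupby(key.values).mean().T


def score_bins(nm, gene_bins: pd.Series, reference_spots,
               smooth_window_bins: int = DEFAULT_SMOOTH_WINDOW,
               loess_span: float = DEFAULT_LOESS_SPAN,
               bins: pd.DataFrame | None = None,
               clamp: float = DEFAULT_CLAMP) -> CnvProfile:
    """Score copy number per spot and genomic bin from normalized expression.

    Pipeline per spot: (1) center each gene on its mean over the reference
    spots; (2) clamp centered values to +-``clamp``; (3) average genes per
    bin; (4) running-mean smooth over +-``smooth_window_bins`` bins within
    each chromosome; (5) subtract a loess fit of score against genome-wide
    bin index (span ``loess_span``); (6) subtract the spot's median score.
    Bins without assigned genes are missing (NaN) and excluded from calls.
    """
    reference_spots = list(reference_spots)
    if not reference_spots:
        raise ValueError("need at least one reference spot")
    if bins is None:
        raise ValueError("pass the bin table used for gene assignment")

    barcode_index = pd.Index(nm.barcodes)
    ref_pos = barcode_index.get_indexer(reference_spots)
    if (ref_pos < 0).any():
        raise KeyError("reference spot absent from matrix")

    shared = [g for g in gene_bins.index if g in set(nm.gene_ids)]
    gene_pos = pd.Index(nm.gene_ids).get_indexer(shared)
    V = nm.values[gene_pos]                       # genes x spots
    centered = V - V[:, ref_pos].mean(axis=1, keepdims=True)
    np.clip(centered, -clamp, clamp, out=centered)

    bin_of_gene = gene_bins.loc[shared].to_numpy()
    n_bins = len(bins)
    sums = np.zeros((n_bins, centered.shape[1]))
    counts = np.zeros(n_bins)
    np.add.at(sums, bin_of_gene, centered)
    np.add.at(counts, bin_of_gene, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        binned = sums / counts[:, None]           # bins x spots, NaN when empty

    # (4) running mean within chromosome, ignoring missing bins
    smoothed = np.full_like(binned, np.nan)
    w = int(smooth_window_bins)
    for chrom, cb in bins.groupby("chrom", sort=False):
        idx = cb.index.to_numpy()
        seg = binned[idx]
        if w > 0:
            filled = np.where(np.isnan(seg), 0.0, seg)
            valid = (~np.isnan(seg)).astype(float)
            kernel = np.ones(2 * w + 1)
            num = np.apply_along_axis(
                lambda col: np.convolve(col, kernel, mode="same"), 0, filled)
            den = np.apply_along_axis(
                lambda col: np.convolve(col, kernel, mode="same"), 0, valid)
            with np.errstate(invalid="ignore", divide="ignore"):
                seg = num / den
        smoothed[idx] = seg

    # (5) loess detrend against genome-wide bin index, per spot
    x = np.arange(n_bins, dtype=float)
    detrended = np.full_like(smoothed, np.nan)
    delta = max(1.0, 0.01 * n_bins)
    for s in range(smoothed.shape[1]):
        col = smoothed[:, s]
        ok = ~np.isnan(col)
        if ok.sum() < 3:
            detrended[:, s] = col
            continue
        fit = lowess(col[ok], x[ok], frac=loess_span, delta=delta,
                     return_sorted=False)
        detrended[ok, s] = col[ok] - fit

    # (6) per-spot median centering
    med = np.nanmedian(detrended, axis=0)
    final = detrended - med

    scores = pd.DataFrame(final.T, index=list(nm.barcodes),
                          columns=bins.index)
    empty = int(np.isnan(final).all(axis=1).sum())
    if empty:
        logger.info("score_bins: %d bins without genes marked missing", empty)
    return CnvProfile(scores=scores, bins=bins, reference_spots=reference_spots)


# ---------------------------------------------------------------------- #
# calls and validation
# ---------------------------------------------------------------------- #
def _call(values: np.ndarray, tau_loss: float, tau_gain: float) -> np.ndarray:
    """Strict-inequality thresholding; NaN stays NaN (missing)."""
    out = np.zeros(values.shape, dtype=float)
    out[values > tau_gain] = CALL_GAIN
    out[values < -tau_loss] = CALL_LOSS
    out[np.isnan(values)] = np.nan
    return out


def call_alterations(profile: CnvProfile, tau_loss: float | None = None,
                     tau_gain: float | None = None,
                     level: str = "bin") -> pd.DataFrame:
    """Gain/neutral/loss calls per spot at bin or chromosome-arm level.

    At ``level='arm'`` the call is that of the arm's mean score. Thresholds
    must be positive; scores exactly at a threshold are neutral.
    """
    tl = profile.tau_loss if tau_loss is None else tau_loss
    tg = profile.tau_gain if tau_gain is None else tau_gain
    if tl <= 0 or tg <= 0:
        raise ValueError("thresholds must be positive")
    if level == "bin":
        values = profile.scores
    elif level == "arm":
        values = profile.arm_scores()
    else:
        raise ValueError("level must be 'bin' or 'arm'")
    calls = pd.DataFrame(_call(values.to_numpy(float), tl, tg),
                         index=values.index, columns=values.columns)
    if level == "bin":
        profile.calls = calls
        profile.tau_loss, profile.tau_gain = tl, tg
    return calls


def sample_arm_calls(profile: CnvProfile, spots=None,
                     tau_loss: float | None = None,
                     tau_gain: float | None = None) -> pd.Series:
    """One call per arm for a whole sample: call of the mean arm score
    over the given spots (default: all non-reference spots)."""
    tl = profile.tau_loss if tau_loss is None else tau_loss
    tg = profile.tau_gain if tau_gain is None else tau_gain
    arm = profile.arm_scores()
    if spots is None:
        spots = [b for b in arm.index if b not in set(profile.reference_spots)]
    mean = arm.loc[spots].mean(axis=0)
    return pd.Series(_call(mean.to_numpy(float), tl, tg), index=mean.index)


def compare_to_reference(calls: pd.DataFrame | pd.Series,
                         reference: pd.Series) -> dict:
    """Consensus / divergence fractions of inferred vs reference arm calls.

    ``calls`` holds inferred calls per arm (a Series for one sample or a
    samples x arms DataFrame); ``reference`` maps arm -> call code. Arms
    missing from the reference are excluded and logged. Fractions returned:
    consensus neutral / gain / loss, divergent gain (inferred gain vs
    reference loss), divergent loss, other mismatch; plus per-arm mismatch
    counts.
    """
    frame = calls.to_frame().T if isinstance(calls, pd.Series) else calls
    shared = [a for a in frame.columns if a in reference.index]
    dropped = set(frame.columns) - set(shared)
    if dropped:
        logger.warning("arms missing from reference excluded: %s",
                       sorted(dropped))
    inferred = frame[shared].to_numpy(float)
    ref = reference.loc[shared].to_numpy(float)[None, :]
    ok = ~np.isnan(inferred)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable arm calls")
    agree = (inferred == ref) & ok
    out = {
        "n_comparisons": n,
        "consensus": float(agree.sum() / n),
        "consensus_neutral": float(((inferred == 0) & (ref == 0) & ok).sum() / n),
        "consensus_gain": float(((inferred == 1) & (ref == 1) & ok).sum() / n),
        "consensus_loss": float(((inferred == -1) & (ref == -1) & ok).sum() / n),
        "divergent_gain": float(((inferred == 1) & (ref == -1) & ok).sum() / n),
        "divergent_loss": float(((inferred == -1) & (ref == 1) & ok).sum() / n),
    }
    mismatch = pd.Series(((inferred != ref) & ok).sum(axis=0), index=shared)
    out["mismatch_per_arm"] = {k: int(v) for k, v in mismatch.items()}
    return out


def probe_density_diagnostic(genes: pd.DataFrame, gene_bins: pd.Series,
                             bins: pd.DataFrame,
                             mismatch_per_bin: pd.Series) -> dict:
    """Correlate per-bin probe density with mismatch frequency.

    Per bin: probes = sum of ``n_probes`` of its genes; mean inter-probe
    distance = bin width / probes; density = probes / bin width. Returns
    Pearson R (density vs mismatch frequency) with a two-sided t-test p.
    R is reported as NaN when either vector is constant.
    """
    if "n_probes" not in genes.columns:
        raise ValueError("gene table has no n_probes column")
    probes = np.zeros(len(bins))
    shared = [g for g in gene_bins.index if g in genes.index]
    np.add.at(probes, gene_bins.loc[shared].to_numpy(),
              genes.loc[shared, "n_probes"].to_numpy(float))
    has = probes > 0
    usable = has & bins.index.isin(mismatch_per_bin.index)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 bins with probe and mismatch data")
    width = bins["width"].to_numpy(float)
    density = probes[usable] / width[usable]
    distance = width[usable] / probes[usable]
    mism = mismatch_per_bin.loc[bins.index[usable]].to_numpy(float)
    if np.ptp(density) == 0 or np.ptp(mism) == 0:
        return {"r": float("nan"), "p": float("nan"),
                "n_bins": int(usable.sum()),
                "mean_interprobe_distance": float(distance.mean())}
    r, p = scipy.stats.pearsonr(density, mism)
    return {"r": float(r), "p": float(p), "n_bins": int(usable.sum()),
            "mean_interprobe_distance": float(distance.mean())}


def roc_gain_loss(arm_scores: np.ndarray, truth: np.ndarray) -> float:
    """Multiclass AUC for {loss, neutral, gain} from a scalar arm score.

    Pairwise AUCs are computed by rank sums of the continuous score between
    each unordered class pair, oriented by the natural order
    loss < neutral < gain, then averaged (Hand-Till construction for an
    ordinal discriminant). Requires >= 2 classes present.
    """
    from .gnn import _pairwise_rank_auc  # shared rank-sum core

    scores = np.asarray(arm_scores, float)
    labels = np.asarray(truth)
    classes = [c for c in (CALL_LOSS, CALL_NEUTRAL, CALL_GAIN)
               if (labels == c).any()]
    if len(classes) < 2:
        raise ValueError("need at least two classes for ROC analysis")
    aucs = []
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            lo, hi = classes[a], classes[b]
            aucs.append(_pairwise_rank_auc(scores[labels == hi],
                                           scores[labels == lo]))
    return float(np.mean(aucs))
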