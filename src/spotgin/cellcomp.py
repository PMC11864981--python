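"""Spot-level cell-type allocation from deconvolution scores.

External deconvolution produces a non-negative score per spot and cell
type. Scores are min-max normalized per type to [0,1]; the cell count per
type at grid point j with N_j nuclei is

    C_jk = round(d'_jk * N_j / sum_k d'_jk)

with round-half-away-from-zero. The rounded counts may miss N_j by at
most ceil(T/2) cells for T types; the deviation is reported, never
silently corrected. Counts are then mapped onto individual nucleus
positions to give a spatial cell-type map, and neighborhood compositions
of two subgraph groups can be compared with a permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


@dataclass
class DeconvolutionScores:
    """Raw and per-type min-max normalized scores (spots x types)."""

    d: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.d.to_numpy(float) < 0).any():
            raise ValueError("deconvolution scores must be non-negative")

    @property
    def type_names(self) -> list:
        return list(self.d.columns)

    @property
    def d_norm(self) -> pd.DataFrame:
        values = self.d.to_numpy(float)
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        span = hi - lo
        out = np.zeros_like(values)
        nz = span > 0
        out[:, nz] = (values[:, nz] - lo[nz]) / span[nz]
        return pd.DataFrame(out, index=self.d.index, columns=self.d.columns)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def allocate_cells(scores_row: np.ndarray, n_cells: int) -> np.ndarray:
    """Integer cells per type from one normalized score row and N_j nuclei.

    All-zero scores with cells present cannot be typed: the caller should
    label those nuclei unassigned (a NaN vector is returned to signal it).
    The allocation is invariant to scaling the row by any c > 0.
    """
    d = np.asarray(scores_row, float)
    if n_cells < 0:
        raise ValueError("cell count must be non-negative")
    total = d.sum()
    if total <= 0:
        if n_cells > 0:
            return np.full(d.shape, np.nan)
        return np.zeros(d.shape)
    return _round_half_away(d * n_cells / total)


def allocate_all(scores: DeconvolutionScores, n_cells: pd.Series) -> pd.DataFrame:
    """Allocate every spot; adds an ``unassigned`` column for score-less
    spots and a ``rounding_deviation`` column (sum_k C_jk - N_j)."""
    d_norm = scores.d_norm
    rows = []
    for barcode in d_norm.index:
        n = int(n_cells.get(barcode, 0))
        alloc = allocate_cells(d_norm.loc[barcode].to_numpy(), n)
        if np.isnan(alloc).any():
            rows.append([0] * d_norm.shape[1] + [n, 0])
        else:
            rows.append(list(alloc.astype(int)) + [0, int(alloc.sum() - n)])
    out = pd.DataFrame(rows, index=d_norm.index,
                       columns=list(d_norm.columns) + [UNASSIGNED,
                                                       "rounding_deviation"])
    return out


def map_to_nuclei(counts: pd.Series | dict, nucleus_xy: np.ndarray,
                  seed: int = 0) -> pd.DataFrame:
    """Assign cell types to nuclei by seeded sampling without replacement.

    ``counts`` maps type -> integer count for one spot; nuclei beyond the
    summed count remain unassigned. Returns (x, y, type) per nucleus.
    """
    counts = pd.Series(counts).astype(int)
    nucleus_xy = np.atleast_2d(np.asarray(nucleus_xy, float))
    n_nuclei = len(nucleus_xy)
    pool: list = []
    for t, c in counts.items():
        pool.extend([t] * max(0, int(c)))
    if len(pool) > n_nuclei:
        pool = pool[:n_nuclei]  # truncate surplus allocation
    types = np.array(pool + [UNASSIGNED] * (n_nuclei - len(pool)), dtype=object)
    rng = np.random.default_rng(seed)
    types = types[rng.permutation(n_nuclei)]
    return pd.DataFrame({"x": nucleus_xy[:, 0], "y": nucleus_xy[:, 1],
                         "type": types})


def composition_frequencies(assignments: pd.DataFrame) -> pd.Series:
    """Relative frequency per assigned type (unassigned excluded)."""
    typed = assignments.loc[assignments["type"] != UNASSIGNED, "type"]
    if typed.empty:
        raise ValueError("no assigned cells")
    return typed.value_counts(normalize=True).sort_index()


def compare_neighborhood_composition(group_a: pd.DataFrame,
                                     group_b: pd.DataFrame,
                                     n_perm: int = 1000,
                                     seed: int = 0) -> pd.DataFrame:
    """Per-type frequency difference between two cell groups.

    Two-sided permutation test: cells are pooled and group membership
    reshuffled ``n_perm`` times; p is the fraction of permutations with an
    absolute frequency difference at least as large as observed.
    """
    a = group_a.loc[group_a["type"] != UNASSIGNED, "type"].to_numpy()
    b = group_b.loc[group_b["type"] != UNASSIGNED, "type"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must contain assigned cells")
    types = sorted(set(a) | set(b))

    def freq(v):
        s = pd.Series(v).value_counts(normalize=True)
        return np.array([s.get(t, 0.0) for t in types])

    observed = freq(a) - freq(b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(types))
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = freq(perm[:len(a)]) - freq(perm[len(a):])
        exceed += np.abs(diff) >= np.abs(observed) - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    return pd.DataFrame({"freq_a": freq(a), "freq_b": freq(b),
                         "difference": observed, "p": p}, index=types)
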