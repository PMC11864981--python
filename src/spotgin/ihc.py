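"""Stain-image / expression agreement.

A chromogenic or fluorescent stain image is reduced to a per-pixel
intensity field (one channel, min-max rescaled to [0,1]), smoothed with a
Gaussian kernel smoother

    z_hat(x,y) = sum_i z_i K_i / sum_i K_i,
    K_i = exp(-((x-x_i)^2 + (y-y_i)^2) / (2 sigma^2)),

sampled at spot centers, optionally aggregated over polygonal segments by
even-odd ray casting, and correlated with the spot expression of the
marker gene through an ordinary least-squares fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass
class IntensityField:
    """Point-sampled stain intensity in [0,1] with a smoothing bandwidth."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.z.size and (self.z.min() < 0 or self.z.max() > 1):
            raise ValueError("intensities must lie in [0,1]")


def extract_intensity(image: np.ndarray, channel: str = "blue",
                      invert: bool = False, stride: int = 1,
                      sigma: float = 1.0) -> IntensityField:
    """Extract one channel of an RGB image as a [0,1] intensity field.

    ``stride`` subsamples the pixel grid (recorded implicitly in the
    returned coordinates). A constant image degenerates under min-max
    rescaling and is returned as all-zero with a warning.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an RGB image (HxWx3)")
    plane = arr[::stride, ::stride, CHANNELS[channel]].astype(float)
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        warnings.warn("constant image channel; returning all-zero intensities")
        z = np.zeros_like(plane)
    else:
        z = (plane - lo) / (hi - lo)
    if invert:
        z = 1.0 - z
    yy, xx = np.mgrid[0:arr.shape[0]:stride, 0:arr.shape[1]:stride]
    return IntensityField(x=xx.ravel().astype(float),
                          y=yy.ravel().astype(float),
                          z=z.ravel(), sigma=sigma)


def gaussian_smooth(field: IntensityField, query_xy: np.ndarray,
                    sigma: float | None = None,
                    chunk: int = 256) -> np.ndarray:
    """Evaluate the Gaussian kernel smoother at query points.

    Queries farther than 10 sigma from every sample would underflow the
    kernel weights; those fall back to the nearest sample's value with a
    warning. Output is a convex combination of sample intensities.
    """
    if field.x.size == 0:
        raise ValueError("empty intensity field")
    s = field.sigma if sigma is None else sigma
    if s <= 0:
        raise ValueError("sigma must be positive")
    queries = np.atleast_2d(np.asarray(query_xy, float))
    samples = np.column_stack([field.x, field.y])
    out = np.empty(len(queries))
    far_warned = False
    for start in range(0, len(queries), chunk):
        q = queries[start:start + chunk]
        d2 = ((q[:, None, :] - samples[None, :, :]) ** 2).sum(axis=2)
        d2min = d2.min(axis=1)
        logw = -d2 / (2.0 * s * s)
        logw -= logw.max(axis=1, keepdims=True)  # stabilize the ratio
        w = np.exp(logw)
        vals = (w @ field.z) / w.sum(axis=1)
        far = np.sqrt(d2min) > 10.0 * s
        if far.any():
            if not far_warned:
                warnings.warn("query beyond 10 sigma of all samples; "
                              "using nearest-sample value")
                far_warned = True
            vals[far] = field.z[d2.argmin(axis=1)][far]
        out[start:start + chunk] = vals
    return out


# ---------------------------------------------------------------------- #
# polygons
# ---------------------------------------------------------------------- #
def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd ray casting with half-open edges (y_i <= y < y_{i+1}).

    For every edge straddling the query's y, the x coordinate of the
    intersection of the rightward ray is

        x_int = x_i + (y - y_i)(x_{i+1} - x_i)/(y_{i+1} - y_i);

    an odd number of crossings to the right means inside.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    verts = np.asarray(vertices, float)
    if len(verts) < 3:
        raise ValueError("polygon needs at least three vertices")
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        straddle = ((y1 <= y) & (y < y2)) | ((y2 <= y) & (y < y1))
        if not straddle.any():
            continue
        x_int = x1 + (y[straddle] - y1) * (x2 - x1) / (y2 - y1)
        crossing = np.zeros(len(pts), dtype=bool)
        crossing[straddle] = x_int > x[straddle]
        inside ^= crossing
    return inside


def point_in_polygon(point, vertices) -> bool:
    return bool(points_in_polygon(np.asarray(point, float)[None, :],
                                  vertices)[0])


def aggregate_per_segment(points: np.ndarray, values: np.ndarray,
                          polygons: dict) -> dict:
    """Mean value per polygonal segment; empty segments report NaN."""
    pts = np.atleast_2d(np.asarray(points, float))
    vals = np.asarray(values, float)
    out = {}
    for seg_id, verts in polygons.items():
        mask = points_in_polygon(pts, np.asarray(verts, float))
        out[seg_id] = float(vals[mask].mean()) if mask.any() else float("nan")
    return out


# ---------------------------------------------------------------------- #
def correlate_intensity_expression(intensity: np.ndarray,
                                   expression: np.ndarray) -> dict:
    """OLS fit of expression on smoothed intensity: Pearson R, p, slope.

    Pairs with a missing value on either side are dropped; at least three
    pairs are required. A zero-variance side yields missing R with a
    warning.
    """
    z = np.asarray(intensity, float)
    e = np.asarray(expression, float)
    ok = ~(np.isnan(z) | np.isnan(e))
    z, e = z[ok], e[ok]
    if len(z) < 3:
        raise ValueError("need at least three paired spots")
    if np.ptp(z) == 0 or np.ptp(e) == 0:
        warnings.warn("zero-variance side; correlation undefined")
        return {"r": float("nan"), "p": float("nan"),
                "slope": float("nan"), "n": int(len(z))}
    fit = scipy.stats.linregress(z, e)
    return {"r": float(fit.rvalue), "p": float(fit.pvalue),
            "slope": float(fit.slope), "n": int(len(z))}


def quantify_marker(dataset, nm, gene: str, channel: str = "blue",
                    invert: bool = False, sigma: float | None = None,
                    stride: int = 2) -> dict:
    """End-to-end stain/expression agreement for one marker gene.

    Extracts the stain channel from ``dataset.image``, smooths it at the
    spot centers (default bandwidth = spot pitch, estimated as the minimum
    inter-spot distance) and correlates with the gene's normalized
    expression.
    """
    if dataset.image is None:
        raise ValueError("dataset has no image")
    xy = dataset.spot_xy() * dataset.image_scale
    if sigma is None:
        from scipy.spatial.distance import pdist
        sub = xy[: min(len(xy), 400)]
        sigma = float(pdist(sub).min())
    field = extract_intensity(dataset.image, channel=channel, invert=invert,
                              stride=stride, sigma=sigma)
    smoothed = gaussian_smooth(field, xy)
    expr = nm.values[nm.gene_index([gene])[0]]
    out = correlate_intensity_expression(smoothed, expr)
    out["gene"] = gene
    out["sigma"] = sigma
    return out
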