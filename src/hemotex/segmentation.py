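"""Otsu histogram thresholding for hemorrhage ROI extraction.

The intensity histogram over [0, 1] is split at a candidate threshold bin t
into a background class T0 = {0..t} and a foreground class T1 = {t+1..l-1}.
For each split the class weights, means and variances are

    w_b(t) = sum_{i<=t} p(i)            w_f(t) = sum_{i>t} p(i)
    mu_b(t) = sum_{i<=t} v_i p(i)/w_b   mu_f(t) = sum_{i>t} v_i p(i)/w_f
    var_b(t), var_f(t) analogously, with v_i the bin-center value,

and the optimal threshold minimizes the weighted within-class variance

    sigma_w^2(t) = w_b(t) var_b(t) + w_f(t) var_f(t),

equivalently maximizes the between-class variance
w_b w_f (mu_b - mu_f)^2. Ties break toward the smallest t.

Two thresholding modes are exposed: ``otsu`` (the minimizer above, default)
and ``fixed`` (a constant threshold, default 0.5 on the normalized scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateHistogramError, ParameterError, ValidationError
from .imaging_io import IntensityImage, Mask

log = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Histogram:
    """Binned intensity distribution over [0, 1]."""

    counts: np.ndarray  # int counts per bin
    probabilities: np.ndarray  # counts / total
    bin_edges: np.ndarray  # length l+1 over [0, 1]

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class OtsuStats:
    """The optimal split and its class statistics."""

    t_index: int
    t_value: float  # upper edge of bin t_index, in [0, 1]
    w_b: float
    w_f: float
    mu_b: float
    mu_f: float
    var_b: float
    var_f: float
    sigma_w2: float
    sigma_b2: float  # between-class variance at the optimum


def intensity_histogram(
    image: IntensityImage, n_bins: int = 256, roi: Optional[Mask] = None
) -> Histogram:
    """Histogram of image intensities over equal-width bins on [0, 1].

    Pixels outside ``roi`` (if given) are excluded; the value 1.0 falls in
    the last bin.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    values = image.pixels
    if roi is not None:
        if roi.shape != image.shape:
            raise ValidationError("roi shape does not match image")
        if roi.n_set == 0:
            raise ValidationError("roi is empty")
        values = values[roi.pixels]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values.ravel(), bins=edges)
    total = counts.sum()
    probs = counts / total if total > 0 else np.zeros(n_bins)
    return Histogram(counts=counts, probabilities=probs.astype(np.float64),
                     bin_edges=edges)


def _class_stats(p: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-split weights/means/variances by direct summation.

    Direct (non-cumulative) sums keep splits that share the same occupied
    bins exactly equal, so ties break identically to a naive per-split
    evaluation; central-moment form avoids catastrophic cancellation.
    """
    l = len(p)
    w_b = np.empty(l)
    w_f = np.empty(l)
    mu_b = np.empty(l)
    mu_f = np.empty(l)
    var_b = np.empty(l)
    var_f = np.empty(l)
    for t in range(l):
        pb, pf = p[: t + 1], p[t + 1:]
        vb, vf = v[: t + 1], v[t + 1:]
        wb = pb.sum()
        wf = pf.sum()
        w_b[t], w_f[t] = wb, wf
        mu_b[t] = (vb * pb).sum() / wb if wb > 0 else 0.0
        mu_f[t] = (vf * pf).sum() / wf if wf > 0 else 0.0
        var_b[t] = ((vb - mu_b[t]) ** 2 * pb).sum() / wb if wb > 0 else 0.0
        var_f[t] = ((vf - mu_f[t]) ** 2 * pf).sum() / wf if wf > 0 else 0.0
    return w_b, w_f, mu_b, mu_f, var_b, var_f


def otsu_threshold(hist: Histogram) -> OtsuStats:
    """Split minimizing the weighted within-class variance.

    Candidate splits are t in {0..l-2}; ties break toward the smallest
    index. Requires at least two occupied bins.
    """
    p = hist.probabilities
    if np.count_nonzero(hist.counts) < 2:
        raise DegenerateHistogramError(
            "otsu needs >= 2 occupied histogram bins"
        )
    v = hist.bin_centers
    w_b, w_f, mu_b, mu_f, var_b, var_f = _class_stats(p, v)
    sigma_w2 = w_b * var_b + w_f * var_f
    t = int(np.argmin(sigma_w2[:-1]))  # exclude the all-in-one split
    return OtsuStats(
        t_index=t,
        t_value=float(hist.bin_edges[t + 1]),
        w_b=float(w_b[t]),
        w_f=float(w_f[t]),
        mu_b=float(mu_b[t]),
        mu_f=float(mu_f[t]),
        var_b=float(var_b[t]),
        var_f=float(var_f[t]),
        sigma_w2=float(sigma_w2[t]),
        sigma_b2=float(w_b[t] * w_f[t] * (mu_b[t] - mu_f[t]) ** 2),
    )


def remove_small_objects(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_px`` pixels."""
    if min_px <= 0 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def segment_roi(
    image: IntensityImage,
    mode: str = "otsu",
    fixed_t: float = 0.5,
    roi: Optional[Mask] = None,
    min_object_px: int = 0,
    n_bins: int = 256,
) -> Mask:
    """Threshold the image into a hemorrhage ROI mask.

    ``otsu`` mode derives the threshold from the (roi-restricted)
    histogram; ``fixed`` uses ``fixed_t`` directly. The mask keeps pixels
    strictly above the threshold, restricted to ``roi``; components below
    ``min_object_px`` are removed (8-connectivity). A degenerate histogram
    in otsu mode falls back to the fixed threshold (logged). The result may
    legitimately be empty.
    """
    if mode not in ("otsu", "fixed"):
        raise ParameterError(f"unknown mode {mode!r}")
    if not (0.0 <= fixed_t <= 1.0):
        raise ParameterError(f"fixed_t must be in [0,1], got {fixed_t}")
    if mode == "otsu":
        try:
            stats = otsu_threshold(intensity_histogram(image, n_bins, roi))
            threshold = stats.t_value
        except DegenerateHistogramError:
            log.warning("degenerate histogram; falling back to fixed t=%g", fixed_t)
            threshold = fixed_t
    else:
        threshold = fixed_t
    fg = image.pixels > threshold
    if roi is not None:
        fg &= roi.pixels
    fg = remove_small_objects(fg, min_object_px)
    return Mask(fg.astype(np.uint8))


def brain_interior_mask(image: IntensityImage, skull_gate: float = 0.9) -> Mask:
    """Skull-strip by an intensity gate: pixels >= ``skull_gate`` are skull;
    the filled region they enclose, minus the skull itself, is brain."""
    skull = image.pixels >= skull_gate
    filled = ndimage.binary_fill_holes(skull)
    interior = filled & ~skull
    return Mask(interior.astype(np.uint8))
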