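"""Tamura and Gradient Local Ternary Pattern (GLTP) texture descriptors.

The fused per-image signature concatenates

* **Tamura features** — coarseness (dominant texture scale, in pixels),
  contrast (intensity spread penalized by kurtosis) and directionality
  (edge-angle histogram concentration), computed per block of a B x B
  partition of the ROI crop (3*B^2 values), and
* **the GLTP histogram** — each pixel's 8-neighborhood of Sobel gradient
  magnitudes is ternary-coded against a +-t band around the center
  magnitude Gc (-1 below Gc - t, 0 inside the band, +1 above Gc + t); the
  negative and positive halves become two 8-bit codes whose 256-bin
  histograms are concatenated into a 512-vector.

Ternary coding of gradient magnitude (rather than raw intensity) keeps the
descriptor stable under illumination shifts and tolerant of noise: additive
intensity offsets leave gradients untouched, and the 0 band absorbs small
magnitude fluctuations around the center.

Neighbor bit order is frozen for reproducibility: bit b=0 at the top-left
neighbor, proceeding clockwise (top, top-right, right, bottom-right,
bottom, bottom-left, left = b=7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ValidationError
from .imaging_io import IntensityImage, Mask

log = logging.getLogger(__name__)

# clockwise from top-left: (dr, dc) for bits 0..7
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

_SOBEL_H = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_V = _SOBEL_H.T


@dataclass(frozen=True)
class GradientField:
    """Sobel responses and their magnitude, same shape as the source."""

    Gi: np.ndarray  # horizontal response
    Gj: np.ndarray  # vertical response
    Gmag: np.ndarray  # sqrt(Gi^2 + Gj^2)


@dataclass(frozen=True)
class TernaryCodeImage:
    """Per-pixel 8-vector of ternary codes for interior pixels.

    codes has shape (M-2, N-2, 8) with entries in {-1, 0, +1}; border
    pixels are not encoded.
    """

    codes: np.ndarray
    t_gltp: float


@dataclass(frozen=True)
class GLTPCodePair:
    """Negative and positive 8-bit decimal codes per encoded pixel."""

    n_codes: np.ndarray  # ints 0..255
    p_codes: np.ndarray


@dataclass(frozen=True)
class GLTPHistogram:
    """256 + 256 bin histogram of the negative/positive codes."""

    h_n: np.ndarray
    h_p: np.ndarray
    normalized: bool

    @property
    def fused(self) -> np.ndarray:
        return np.concatenate([self.h_n, self.h_p])


@dataclass(frozen=True)
class TamuraVector:
    """Blockwise (coarseness, contrast, directionality), row-major blocks."""

    values: np.ndarray  # length 3 * B^2
    block_grid: int


@dataclass(frozen=True)
class FusedFeatureVector:
    """Tamura block features followed by the 512-bin GLTP histogram."""

    values: np.ndarray
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.values)


def sobel_gradients(image: IntensityImage) -> GradientField:
    """3x3 Sobel-Feldman responses with edge-replicated borders."""
    px = image.pixels
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValidationError("Sobel needs at least a 3x3 image")
    gi = ndimage.correlate(px, _SOBEL_H, mode="nearest")
    gj = ndimage.correlate(px, _SOBEL_V, mode="nearest")
    return GradientField(Gi=gi, Gj=gj, Gmag=np.hypot(gi, gj))


def gltp_encode(field: GradientField, t_gltp: float) -> TernaryCodeImage:
    """Ternary-code each interior pixel's 8 neighbors against Gc +- t.

    A neighbor's gradient magnitude below ``Gc - t`` codes to -1, above
    ``Gc + t`` to +1, inside the band to 0.
    """
    if t_gltp < 0:
        raise ParameterError(f"t_gltp must be >= 0, got {t_gltp}")
    G = field.Gmag
    M, N = G.shape
    center = G[1:-1, 1:-1]
    codes = np.zeros((M - 2, N - 2, 8), dtype=np.int8)
    for b, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        nb = G[1 + dr:M - 1 + dr, 1 + dc:N - 1 + dc]
        codes[:, :, b] = (nb > center + t_gltp).astype(np.int8) - (
            nb < center - t_gltp
        ).astype(np.int8)
    return TernaryCodeImage(codes=codes, t_gltp=float(t_gltp))


def gltp_split_codes(ternary: TernaryCodeImage) -> GLTPCodePair:
    """Split ternary codes into negative and positive 8-bit decimals.

    n_code = sum_b [code_b < 0] 2^b and p_code = sum_b [code_b > 0] 2^b;
    a bit can be set in at most one of the two codes.
    """
    weights = (1 << np.arange(8)).astype(np.int64)
    neg = (ternary.codes < 0).astype(np.int64)
    pos = (ternary.codes > 0).astype(np.int64)
    return GLTPCodePair(n_codes=neg @ weights, p_codes=pos @ weights)


def gltp_histogram(pair: GLTPCodePair, normalize: bool = False) -> GLTPHistogram:
    """256-bin histograms of the two code images; optionally divided by
    the encoded-pixel count."""
    h_n = np.bincount(pair.n_codes.ravel(), minlength=256).astype(np.float64)
    h_p = np.bincount(pair.p_codes.ravel(), minlength=256).astype(np.float64)
    if normalize:
        total = pair.n_codes.size
        if total > 0:
            h_n = h_n / total
            h_p = h_p / total
    return GLTPHistogram(h_n=h_n, h_p=h_p, normalized=normalize)


def gltp_descriptor(
    image: IntensityImage,
    t_gltp: float = 0.05,
    normalize_hist: bool = True,
    rescale_gmag: bool = True,
) -> GLTPHistogram:
    """Full GLTP path: Sobel -> magnitude -> ternary code -> histograms.

    With ``rescale_gmag`` the magnitude field is divided by its maximum
    before coding, so the default band half-width t=0.05 is comparable
    across images of different contrast.
    """
    field = sobel_gradients(image)
    G = field.Gmag
    if rescale_gmag:
        gmax = G.max()
        if gmax > 0:
            field = GradientField(field.Gi / gmax, field.Gj / gmax, G / gmax)
    return gltp_histogram(gltp_split_codes(gltp_encode(field, t_gltp)),
                          normalize=normalize_hist)


def _shifted(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """a[r+dr, c+dc] with indices clamped to the array (edge replication)."""
    M, N = a.shape
    ri = np.clip(np.arange(M) + dr, 0, M - 1)
    ci = np.clip(np.arange(N) + dc, 0, N - 1)
    return a[np.ix_(ri, ci)]


def tamura_coarseness(
    image: IntensityImage, roi: Optional[Mask] = None, kmax: int = 5
) -> float:
    """Dominant texture scale in pixels (>= 1).

    For each scale k = 0..kmax, local means over 2^k windows are
    differenced across 2^(k-1)-pixel (1 for k=0) horizontal and vertical
    shifts; each pixel keeps the scale with the largest difference (ties
    toward the smaller k) and the feature is the ROI mean of 2^k_best.
    A constant image has all differences zero, so the tie-break yields 1.
    """
    px = image.pixels
    M, N = px.shape
    while kmax > 0 and 2**kmax >= min(M, N):
        kmax -= 1
        log.warning("tamura_coarseness: image %s too small, kmax reduced to %d",
                    px.shape, kmax)
    E = np.zeros((kmax + 1, M, N))
    for k in range(kmax + 1):
        w = 2**k
        A = ndimage.uniform_filter(px, size=w, mode="nearest") if w > 1 else px
        h = max(w // 2, 1)
        E_h = np.abs(_shifted(A, 0, h) - _shifted(A, 0, -h))
        E_v = np.abs(_shifted(A, h, 0) - _shifted(A, -h, 0))
        Ek = np.maximum(E_h, E_v)
        # only pixels whose shifted windows fit entirely are comparable;
        # clamped windows at the border would fake large-scale structure
        m = w // 2 + h
        valid = np.zeros((M, N), dtype=bool)
        if M > 2 * m and N > 2 * m:
            valid[m:M - m, m:N - m] = True
        E[k] = np.where(valid, Ek, 0.0)
    k_best = np.argmax(E, axis=0)  # first occurrence -> smallest k on ties
    s_best = np.power(2.0, k_best)
    if roi is not None:
        if roi.n_set == 0:
            raise ValidationError("roi is empty")
        s_best = s_best[roi.pixels]
    return float(s_best.mean())


def tamura_contrast(image: IntensityImage, roi: Optional[Mask] = None) -> float:
    """sigma / kurtosis^(1/4): wide, heavy-shouldered intensity
    distributions score high. Returns 0 for constant regions."""
    vals = image.pixels[roi.pixels] if roi is not None else image.pixels.ravel()
    if vals.size == 0:
        raise ValidationError("roi is empty")
    if vals.max() == vals.min():
        return 0.0
    mu = vals.mean()
    var = ((vals - mu) ** 2).mean()
    if var <= 0:
        return 0.0
    mu4 = ((vals - mu) ** 4).mean()
    alpha4 = mu4 / var**2
    return float(np.sqrt(var) / alpha4**0.25)


def tamura_directionality(
    image: IntensityImage,
    roi: Optional[Mask] = None,
    n_theta: int = 16,
    grad_floor: float = 1e-6,
) -> float:
    """Concentration of the edge-angle histogram, in [0, 1].

    Edge angles atan2(Gj, Gi) mod pi of pixels with gradient magnitude >=
    ``grad_floor`` are quantized into ``n_theta`` bins over [0, pi). With
    the single-global-peak simplification, directionality is
    1 - n_theta * sum_b H(b) * d(b)^2 where d is the wrapped bin distance
    to the peak as a fraction of the angular range, clipped to [0, 1].
    A single tight peak scores ~1; an isotropic angle distribution ~0.
    """
    field = sobel_gradients(image)
    mag = field.Gmag
    theta = np.mod(np.arctan2(field.Gj, field.Gi), np.pi)
    keep = mag >= grad_floor
    if roi is not None:
        keep &= roi.pixels
    if not keep.any():
        log.warning("tamura_directionality: no pixel passes grad_floor; returning 0")
        return 0.0
    bins = np.minimum((theta[keep] / np.pi * n_theta).astype(int), n_theta - 1)
    H = np.bincount(bins, minlength=n_theta).astype(np.float64)
    H /= H.sum()
    peak = int(np.argmax(H))
    idx = np.arange(n_theta)
    d = np.abs(idx - peak)
    d = np.minimum(d, n_theta - d) / n_theta  # wrapped, fraction of range
    val = 1.0 - n_theta * float((H * d**2).sum())
    return float(np.clip(val, 0.0, 1.0))


def _square_crop(px: np.ndarray, mask: np.ndarray, min_side: int) -> np.ndarray:
    """Crop to the mask bounding box, expanded/padded to a square of at
    least ``min_side`` pixels (edge replication where the image runs out)."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    side = max(r1 - r0, c1 - c0, min_side)
    M, N = px.shape

    def _expand(lo: int, hi: int, limit: int) -> tuple[int, int]:
        need = side - (hi - lo)
        lo = max(0, lo - need // 2)
        hi = min(limit, lo + side)
        lo = max(0, hi - side)
        return lo, hi

    r0, r1 = _expand(r0, r1, M)
    c0, c1 = _expand(c0, c1, N)
    crop = px[r0:r1, c0:c1]
    pad_r = side - crop.shape[0]
    pad_c = side - crop.shape[1]
    if pad_r > 0 or pad_c > 0:
        crop = np.pad(crop, ((0, pad_r), (0, pad_c)), mode="edge")
    return crop


def tamura_block_features(
    crop: np.ndarray, block_grid: int
) -> tuple[np.ndarray, list[str]]:
    """Per-block Tamura triples over a B x B partition of the crop."""
    vals: list[float] = []
    names: list[str] = []
    r_edges = np.linspace(0, crop.shape[0], block_grid + 1).astype(int)
    c_edges = np.linspace(0, crop.shape[1], block_grid + 1).astype(int)
    for i in range(block_grid):
        for j in range(block_grid):
            block = crop[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            img = IntensityImage(block)
            kmax = max(0, int(np.log2(max(min(block.shape) - 1, 1))))
            vals.extend([
                tamura_coarseness(img, kmax=min(5, kmax)),
                tamura_contrast(img),
                tamura_directionality(img),
            ])
            names.extend([
                f"tamura_crs_r{i}c{j}",
                f"tamura_con_r{i}c{j}",
                f"tamura_dir_r{i}c{j}",
            ])
    return np.asarray(vals), names


def extract_features(
    image: IntensityImage,
    mask: Mask,
    block_grid: int = 4,
    t_gltp: float = 0.05,
    normalize_hist: bool = True,
) -> FusedFeatureVector:
    """Fused Tamura + GLTP signature of the masked region.

    The image is cropped to the mask bounding box (expanded to a square,
    minimum side 3 * block_grid or 16). Tamura triples are computed per
    block of a ``block_grid`` x ``block_grid`` partition; the GLTP 512-bin
    histogram is computed over the whole crop. Ordering: all Tamura blocks
    (row-major, coarseness/contrast/directionality within each block),
    then gltp_n_000..255, then gltp_p_000..255.
    """
    if mask.n_set == 0:
        raise ValidationError("mask is empty")
    if mask.shape != image.shape:
        raise ValidationError("mask shape does not match image")
    min_side = max(3 * block_grid, 16)
    crop = _square_crop(image.pixels, mask.pixels, min_side)
    crop_img = IntensityImage(crop)
    tam_vals, tam_names = tamura_block_features(crop, block_grid)
    hist = gltp_descriptor(crop_img, t_gltp=t_gltp, normalize_hist=normalize_hist)
    names = (
        tam_names
        + [f"gltp_n_{i:03d}" for i in range(256)]
        + [f"gltp_p_{i:03d}" for i in range(256)]
    )
    return FusedFeatureVector(
        values=np.concatenate([tam_vals, hist.fused]),
        names=tuple(names),
    )
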