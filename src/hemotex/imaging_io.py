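"""Reading and writing CT slices, masks and feature tables.

Every downstream stage consumes :class:`IntensityImage`: a 2D float grid
normalized to [0, 1]. DICOM input is rescaled to Hounsfield units and passed
through a configurable CT window (default: brain window, center 40 HU, width
80 HU). PNG and NIfTI inputs are assumed pre-windowed; PNG is scaled by its
bit-depth maximum, NIfTI min-max scaled.

Coordinate convention: row-major ``(r, c)``, r counted from the top, 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

#: Standard brain window (center, width) in Hounsfield units.
BRAIN_WINDOW = (40.0, 80.0)


@dataclass(frozen=True)
class IntensityImage:
    """A normalized 2D CT slice.

    pixels are floats in [0, 1]; shape is (M, N) = (height, width) with
    M, N >= 3 so a 3x3 Sobel neighborhood always exists.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2D pixel grid, got ndim={px.ndim}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValidationError(f"image must be at least 3x3, got {px.shape}")
        if not np.isfinite(px).all():
            raise ValidationError("image contains non-finite pixels")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError(
                f"pixels must lie in [0,1], got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Mask:
    """Binary region-membership grid matching a parent image's shape."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"mask must be 2D, got ndim={px.ndim}")
        uniq = np.unique(px)
        if not np.isin(uniq, (0, 1)).all():
            raise ValidationError("mask pixels must be 0/1")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_set(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class Volume:
    """An ordered stack of same-shape slices, optionally with mm spacing."""

    slices: tuple[IntensityImage, ...]
    spacing: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValidationError("a volume needs at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValidationError(f"slices differ in shape: {shapes}")
        object.__setattr__(self, "slices", tuple(self.slices))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.slices), *self.slices[0].shape)


def window_normalize(
    raw: np.ndarray, center: float, width: float, source_id: str = ""
) -> IntensityImage:
    """Map raw intensities through a CT window onto [0, 1].

    output = clip((raw - (center - width/2)) / width, 0, 1). The window
    midpoint maps to 0.5; values a full width above the floor clip to 1.
    """
    if width <= 0:
        raise ParameterError(f"window width must be > 0, got {width}")
    raw = np.asarray(raw, dtype=np.float64)
    lo = center - width / 2.0
    out = np.clip((raw - lo) / width, 0.0, 1.0)
    return IntensityImage(out, source_id=source_id)


def _load_png(path: str) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel grayscale PNG")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise FormatError(f"{path}: unsupported PNG bit depth ({arr.dtype})")


def _load_dicom(path: str, window: tuple[float, float]) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise FormatError(f"{path}: multi-frame DICOM is not supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    center, width = window
    lo = center - width / 2.0
    return np.clip((hu - lo) / width, 0.0, 1.0)


def _minmax(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr, dtype=np.float64)
    return (arr.astype(np.float64) - lo) / (hi - lo)


def load_slice(
    path: str,
    format: str = "auto",
    window: tuple[float, float] = BRAIN_WINDOW,
    slice_index: int = 0,
) -> IntensityImage:
    """Read one CT slice and return it windowed/normalized to [0, 1].

    ``format`` is one of ``dicom``, ``nifti``, ``png``, ``auto`` (by
    extension). DICOM gets rescale slope/intercept then the CT ``window``;
    PNG is divided by its bit-depth maximum; NIfTI is min-max scaled, with
    ``slice_index`` selecting the axial slice of a 3D volume.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        if ext in (".dcm", ".dicom"):
            format = "dicom"
        elif ext == ".png":
            format = "png"
        elif ext in (".nii", ".gz"):
            format = "nifti"
        else:
            raise FormatError(f"cannot infer format from extension of {path}")
    try:
        if format == "png":
            arr = _load_png(path)
        elif format == "dicom":
            arr = _load_dicom(path, window)
        elif format == "nifti":
            import nibabel as nib

            data = np.asarray(nib.load(path).get_fdata())
            if data.ndim == 3:
                data = data[:, :, slice_index]
            if data.ndim != 2:
                raise FormatError(f"{path}: expected 2D/3D NIfTI")
            arr = _minmax(data)
        else:
            raise ParameterError(f"unknown format {format!r}")
    except (FormatError, ParameterError):
        raise
    except Exception as exc:  # corrupt file, parser failure
        raise IOError(f"could not read {path}: {exc}") from exc
    return IntensityImage(arr, source_id=os.path.basename(path))


def load_volume(paths: Sequence[str], **kwargs) -> Volume:
    return Volume(tuple(load_slice(p, **kwargs) for p in paths))


def save_mask_png(mask: Mask, path: str) -> None:
    """Write a mask as an 8-bit PNG with foreground 255."""
    import imageio.v3 as iio

    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))


def load_mask_png(path: str) -> Mask:
    return Mask((_load_png(path) > 0.5).astype(np.uint8))


def save_image_png(image: IntensityImage, path: str) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.round(image.pixels * 255).astype(np.uint8))


def save_features(
    rows: Sequence[tuple[str, str, Sequence[float]]],
    feature_names: Sequence[str],
    path: str,
) -> None:
    """Write a feature table as RFC-4180 CSV: source_id, label, features.

    Feature column names carry provenance prefixes (tamura_*, gltp_n_*,
    gltp_p_*). Ragged rows are rejected.
    """
    n = len(feature_names)
    for sid, _label, vals in rows:
        if len(vals) != n:
            raise ValidationError(
                f"row {sid!r} has {len(vals)} features, expected {n}"
            )
    df = pd.DataFrame(
        [(sid, label, *vals) for sid, label, vals in rows],
        columns=["source_id", "label", *feature_names],
    )
    df.to_csv(path, index=False)


def load_features(path: str) -> tuple[pd.DataFrame, list[str]]:
    """Read a feature CSV back; returns (table, feature column names)."""
    df = pd.read_csv(path)
    feature_cols = [c for c in df.columns if c not in ("source_id", "label")]
    return df, feature_cols
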