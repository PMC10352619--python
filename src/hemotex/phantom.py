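"""Synthetic head-CT phantom slices with ground-truth hemorrhage masks.

Each phantom emulates the gross appearance of a non-contrast axial head CT
slice on the normalized [0, 1] scale: air background (0.0), a bright skull
ring (0.95), mid-intensity brain parenchyma (0.35) and a hyperdense lesion
(0.65) whose shape and location follow the radiological signature of one of
the five hemorrhage subtypes:

* **epidural** — biconvex (lentiform) collection flush against the inner
  skull table, formed as the intersection of the brain disk with an external
  circle;
* **subdural** — thin crescent hugging the inner skull over a >= 90 degree arc;
* **intraparenchymal** — filled ellipse strictly interior to the brain;
* **intraventricular** — blob inside a central hypodense ventricle region
  (the ventricle itself is drawn only for this subtype);
* **subarachnoid** — thin (2-3 px) curvilinear ribbon meandering near the
  cortical margin.

Noise is i.i.d. additive Gaussian, clipped to [0, 1]. Everything is
deterministic given the spec seed; dataset-level seeds are derived as
``base_seed + sample_index`` (samples ordered subtype-major).

A "scan" for sequence classification is a stack of K consecutive slices
sharing one lesion geometry whose extent waxes and wanes across the stack.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import GenerationError, ValidationError
from .imaging_io import IntensityImage, Mask


class Subtype(str, enum.Enum):
    """The five intracranial-hemorrhage subtypes."""

    SUBDURAL = "subdural"
    INTRAPARENCHYMAL = "intraparenchymal"
    SUBARACHNOID = "subarachnoid"
    EPIDURAL = "epidural"
    INTRAVENTRICULAR = "intraventricular"


SUBTYPES: tuple[Subtype, ...] = tuple(Subtype)

#: Minimum image side for feasible lesion geometry.
_MIN_SIDE = 32


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom slice (or scan)."""

    subtype: Subtype
    size: tuple[int, int] = (128, 128)
    brain_level: float = 0.35
    lesion_level: float = 0.65
    skull_level: float = 0.95
    ventricle_level: float = 0.20
    noise_sigma: float = 0.02
    lesion_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lesion_level > self.brain_level):
            raise ValidationError("lesion_level must exceed brain_level "
                                  "(acute blood is hyperdense on CT)")
        if not (self.skull_level > self.lesion_level):
            raise ValidationError("skull_level must exceed lesion_level")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not (0 < self.lesion_scale <= 1):
            raise ValidationError("lesion_scale must be in (0, 1]")
        object.__setattr__(self, "subtype", Subtype(self.subtype))


@dataclass(frozen=True)
class PhantomSample:
    """One labeled slice: image + pixel-level lesion ground truth."""

    image: IntensityImage
    lesion_mask: Mask
    brain_mask: Mask  # brain-interior region (includes ventricle if drawn)
    label: Subtype
    spec: PhantomSpec


@dataclass(frozen=True)
class PhantomScan:
    """K consecutive slices of one lesion, for sequence classification."""

    slices: tuple[PhantomSample, ...]
    label: Subtype
    scan_id: str = ""


def _grids(M: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(M, dtype=np.float64)[:, None]
    c = np.arange(N, dtype=np.float64)[None, :]
    return np.broadcast_to(r, (M, N)), np.broadcast_to(c, (M, N))


def _sample_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Draw the per-lesion nuisance parameters once (position/rotation/arc)."""
    geo = {
        "theta": rng.uniform(0.0, 2.0 * np.pi),
        "phase": rng.uniform(0.0, 2.0 * np.pi),
        "jitter": rng.uniform(0.85, 1.15),
        "offset_frac": rng.uniform(0.0, 0.35),
        "offset_dir": rng.uniform(0.0, 2.0 * np.pi),
        "aspect": rng.uniform(0.6, 1.0),
        "rot": rng.uniform(0.0, np.pi),
        "arc": rng.uniform(np.pi / 2, 5 * np.pi / 6),  # >= 90 degrees
    }
    return geo


def _lesion_mask(
    spec: PhantomSpec,
    geo: dict,
    scale_factor: float,
    Rb: float,
    cy: float,
    cx: float,
    rr: np.ndarray,
    cc: np.ndarray,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Rasterize the subtype-specific lesion; returns (lesion, ventricle)."""
    dist = np.hypot(rr - cy, cc - cx)
    brain = dist < Rb
    s = spec.lesion_scale * geo["jitter"] * scale_factor
    th = geo["theta"]
    ventricle = None

    if spec.subtype is Subtype.EPIDURAL:
        # intersection of the brain disk with an external circle -> lens
        pen = max(3.0, 0.35 * Rb * s)  # penetration depth
        R2 = Rb
        d2 = Rb + R2 - pen
        oy, ox = cy + d2 * np.sin(th), cx + d2 * np.cos(th)
        lesion = brain & (np.hypot(rr - oy, cc - ox) < R2)
    elif spec.subtype is Subtype.SUBDURAL:
        w = max(2.5, 0.10 * Rb * s)
        ang = np.arctan2(rr - cy, cc - cx)
        dang = np.angle(np.exp(1j * (ang - th)))
        lesion = brain & (dist > Rb - w) & (np.abs(dang) < geo["arc"] * s)
    elif spec.subtype is Subtype.INTRAPARENCHYMAL:
        a = max(3.0, 0.30 * Rb * s)
        b = max(2.5, a * geo["aspect"])
        off = min(geo["offset_frac"] * Rb, 0.80 * Rb - a)
        oy = cy + off * np.sin(geo["offset_dir"])
        ox = cx + off * np.cos(geo["offset_dir"])
        co, si = np.cos(geo["rot"]), np.sin(geo["rot"])
        u = (cc - ox) * co + (rr - oy) * si
        v = -(cc - ox) * si + (rr - oy) * co
        lesion = (u / a) ** 2 + (v / b) ** 2 < 1.0
        lesion &= dist < 0.92 * Rb  # strictly interior
    elif spec.subtype is Subtype.INTRAVENTRICULAR:
        va, vb = 0.34 * Rb, 0.20 * Rb
        co, si = np.cos(geo["rot"]), np.sin(geo["rot"])
        u = (cc - cx) * co + (rr - cy) * si
        v = -(cc - cx) * si + (rr - cy) * co
        ventricle = (u / va) ** 2 + (v / vb) ** 2 < 1.0
        la = max(2.5, va * 0.62 * s)
        lb = max(2.0, vb * 0.62 * s)
        oy = cy + 0.15 * vb * np.sin(geo["offset_dir"])
        ox = cx + 0.15 * va * np.cos(geo["offset_dir"])
        u2 = (cc - ox) * co + (rr - oy) * si
        v2 = -(cc - ox) * si + (rr - oy) * co
        lesion = ventricle & ((u2 / la) ** 2 + (v2 / lb) ** 2 < 1.0)
    elif spec.subtype is Subtype.SUBARACHNOID:
        # thin meandering ribbon near the cortical margin
        arc = geo["arc"] * (0.8 + 0.4 * s)
        phi = np.linspace(th - arc, th + arc, 2000)
        rad = Rb * (0.86 + 0.05 * np.sin(3.0 * phi + geo["phase"]))
        pr = np.clip(np.round(cy + rad * np.sin(phi)).astype(int), 0, rr.shape[0] - 1)
        pc = np.clip(np.round(cx + rad * np.cos(phi)).astype(int), 0, rr.shape[1] - 1)
        ribbon = np.zeros(rr.shape, dtype=bool)
        ribbon[pr, pc] = True
        ribbon = ndimage.binary_dilation(ribbon, structure=np.ones((2, 2), bool))
        lesion = ribbon & (dist < Rb - 1.0)
    else:  # pragma: no cover - enum is exhaustive
        raise GenerationError(f"unknown subtype {spec.subtype}")
    return lesion, ventricle


def _render(
    spec: PhantomSpec, geo: dict, scale_factor: float, rng: np.random.Generator
) -> PhantomSample:
    M, N = spec.size
    if min(M, N) < _MIN_SIDE:
        raise GenerationError(
            f"image size {spec.size} too small for lesion geometry "
            f"(need >= {_MIN_SIDE} per side)"
        )
    rr, cc = _grids(M, N)
    cy, cx = (M - 1) / 2.0, (N - 1) / 2.0
    R_out = 0.46 * min(M, N)
    thick = max(3.0, 0.035 * min(M, N))
    Rb = R_out - thick - 1.0

    dist = np.hypot(rr - cy, cc - cx)
    skull = (dist >= Rb + 1.0) & (dist < R_out)
    brain = dist < Rb

    lesion, ventricle = _lesion_mask(spec, geo, scale_factor, Rb, cy, cx, rr, cc)
    if not lesion.any():
        raise GenerationError(
            f"{spec.subtype.value} lesion rasterized empty at size {spec.size}"
        )

    img = np.zeros((M, N), dtype=np.float64)
    img[skull] = spec.skull_level
    img[brain] = spec.brain_level
    if ventricle is not None:
        img[ventricle] = spec.ventricle_level
    img[lesion] = spec.lesion_level

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.clip(img, 0.0, 1.0)

    return PhantomSample(
        image=IntensityImage(img, source_id=f"phantom-{spec.subtype.value}-{spec.seed}"),
        lesion_mask=Mask(lesion.astype(np.uint8)),
        brain_mask=Mask(brain.astype(np.uint8)),
        label=spec.subtype,
        spec=spec,
    )


def generate_slice(spec: PhantomSpec) -> PhantomSample:
    """Generate one labeled slice; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    geo = _sample_geometry(spec, rng)
    return _render(spec, geo, 1.0, rng)


def _wax_wane(K: int) -> np.ndarray:
    # lesion extent rises then falls across the stack, never vanishing
    k = np.arange(K)
    return 0.55 + 0.45 * np.sin(np.pi * (k + 0.5) / K)


def generate_scan(spec: PhantomSpec, n_slices: int = 8) -> PhantomScan:
    """Generate a K-slice scan: one geometry, lesion waxing/waning."""
    if n_slices < 1:
        raise ValidationError("n_slices must be >= 1")
    rng = np.random.default_rng(spec.seed)
    geo = _sample_geometry(spec, rng)
    factors = _wax_wane(n_slices)
    slices = tuple(_render(spec, geo, float(f), rng) for f in factors)
    return PhantomScan(
        slices=slices,
        label=spec.subtype,
        scan_id=f"scan-{spec.subtype.value}-{spec.seed}",
    )


def generate_dataset(
    n_per_class: int,
    base_seed: int = 0,
    spec_overrides: Optional[dict] = None,
) -> list[PhantomSample]:
    """Balanced slice dataset: 5 * n_per_class samples, subtype-major order.

    Per-sample seed = base_seed + global index, so any subset is
    reproducible independently of the rest.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    overrides = dict(spec_overrides or {})
    samples = []
    idx = 0
    for subtype in SUBTYPES:
        for _ in range(n_per_class):
            spec = PhantomSpec(subtype=subtype, seed=base_seed + idx, **overrides)
            samples.append(generate_slice(spec))
            idx += 1
    return samples


def generate_scan_dataset(
    n_per_class: int,
    base_seed: int = 0,
    n_slices: int = 8,
    spec_overrides: Optional[dict] = None,
) -> list[PhantomScan]:
    """Balanced scan dataset (K-slice stacks), same seeding rule as above."""
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    overrides = dict(spec_overrides or {})
    scans = []
    idx = 0
    for subtype in SUBTYPES:
        for _ in range(n_per_class):
            spec = PhantomSpec(subtype=subtype, seed=base_seed + idx, **overrides)
            scans.append(generate_scan(spec, n_slices=n_slices))
            idx += 1
    return scans
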