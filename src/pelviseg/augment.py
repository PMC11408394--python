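"""Random spatial augmentation applied jointly to image and labels.

Four operations are available — elastic deformation, affine warping,
uni-axial rotation and integer-voxel shift.  Images are interpolated
linearly, label index maps by nearest neighbour (then re-one-hotted), and
regions moved in from outside the grid get zero intensity / background label.
Each augmented copy applies a random non-empty subset of the operations;
42 input series with the default 9 copies therefore yield 420 training
series (originals included).

Magnitude defaults (rotation +-15 deg, in-plane shift +-10 voxels,
through-plane +-3, elastic displacement SD 4 mm on a 32 mm control grid,
affine scale 0.9-1.1, shear +-0.05) are chosen to stay anatomy-preserving
and are fully config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import CaseRecord, ImageVolume, LabelVolume, labels_from_indexmap

__all__ = [
    "AugmentConfig",
    "elastic_deform",
    "affine_warp",
    "uniaxial_rotate",
    "shift",
    "augment_case",
    "augment_dataset",
]


@dataclass
class AugmentConfig:
    n_copies: int = 9
    elastic_control_spacing_mm: float = 32.0
    elastic_sd_mm: float = 4.0
    affine_scale_range: tuple[float, float] = (0.9, 1.1)
    affine_shear_max: float = 0.05
    rotation_max_deg: float = 15.0
    shift_max_voxels: tuple[int, int, int] = (10, 10, 3)
    seed: int = 0

    def __post_init__(self):
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")


def _split(image, labels):
    img = np.asarray(image.data, dtype=float)
    idx = labels.indexmap()
    return img, idx


def _rebuild(image, labels, img_new, idx_new):
    out_img = ImageVolume(img_new, spacing=image.spacing, origin=image.origin)
    out_lab = labels_from_indexmap(idx_new, labels.n_channels,
                                   channel_names=labels.channel_names,
                                   spacing=labels.spacing)
    return out_img, out_lab


def elastic_deform(image: ImageVolume, labels: LabelVolume,
                   cfg: AugmentConfig | None = None,
                   rng: np.random.Generator | None = None):
    """Smooth random displacement from a coarse control grid, applied
    identically to image (linear) and label map (nearest)."""
    cfg = cfg or AugmentConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    img, idx = _split(image, labels)
    if cfg.elastic_sd_mm == 0:
        return _rebuild(image, labels, img, idx)
    spacing = np.asarray(image.spacing, dtype=float)
    shape = np.asarray(img.shape)
    ctrl = np.maximum(2, np.ceil(shape * spacing / cfg.elastic_control_spacing_mm)
                      .astype(int) + 1)
    base = np.indices(img.shape).astype(float)
    coords = base.copy()
    for axis in range(3):
        disp_mm = rng.normal(0.0, cfg.elastic_sd_mm, size=tuple(ctrl))
        zoom = shape / ctrl
        disp = ndimage.zoom(disp_mm, zoom, order=3, mode="nearest",
                            grid_mode=True)[: shape[0], : shape[1], : shape[2]]
        coords[axis] += disp / spacing[axis]
    img_new = ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)
    idx_new = ndimage.map_coordinates(idx, coords, order=0, mode="constant", cval=0)
    return _rebuild(image, labels, img_new, idx_new)


def affine_warp(image: ImageVolume, labels: LabelVolume,
                cfg: AugmentConfig | None = None,
                rng: np.random.Generator | None = None,
                matrix: np.ndarray | None = None):
    """Random scale/shear about the grid centre (or an explicit 3x3 matrix)."""
    cfg = cfg or AugmentConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    img, idx = _split(image, labels)
    if matrix is None:
        lo, hi = cfg.affine_scale_range
        m = np.diag(rng.uniform(lo, hi, size=3))
        shear = rng.uniform(-cfg.affine_shear_max, cfg.affine_shear_max, size=(3, 3))
        np.fill_diagonal(shear, 0.0)
        matrix = m + shear
    center = (np.asarray(img.shape) - 1) / 2.0
    offset = center - matrix @ center
    img_new = ndimage.affine_transform(img, matrix, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    idx_new = ndimage.affine_transform(idx, matrix, offset=offset, order=0,
                                       mode="constant", cval=0)
    return _rebuild(image, labels, img_new, idx_new)


def uniaxial_rotate(image: ImageVolume, labels: LabelVolume,
                    cfg: AugmentConfig | None = None,
                    rng: np.random.Generator | None = None,
                    axis: int | None = None, angle_deg: float | None = None):
    """Rotation about exactly one grid axis (randomly chosen by default)."""
    cfg = cfg or AugmentConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    img, idx = _split(image, labels)
    if axis is None:
        axis = int(rng.integers(0, 3))
    if angle_deg is None:
        angle_deg = float(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg))
    plane = tuple(a for a in range(3) if a != axis)
    img_new = ndimage.rotate(img, angle_deg, axes=plane, reshape=False, order=1,
                             mode="constant", cval=0.0)
    idx_new = ndimage.rotate(idx, angle_deg, axes=plane, reshape=False, order=0,
                             mode="constant", cval=0)
    return _rebuild(image, labels, img_new, idx_new)


def shift(image: ImageVolume, labels: LabelVolume,
          cfg: AugmentConfig | None = None,
          rng: np.random.Generator | None = None,
          offset: tuple[int, int, int] | None = None):
    """Integer-voxel translation with zero/background fill (no wrap-around)."""
    cfg = cfg or AugmentConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    img, idx = _split(image, labels)
    if offset is None:
        offset = tuple(int(rng.integers(-m, m + 1)) for m in cfg.shift_max_voxels)
    img_new = np.zeros_like(img)
    idx_new = np.zeros_like(idx)
    src, dst = [], []
    for n, o in zip(img.shape, offset):
        src.append(slice(max(0, -o), min(n, n - o)))
        dst.append(slice(max(0, o), min(n, n + o)))
    if all(s.stop > s.start for s in src):
        img_new[tuple(dst)] = img[tuple(src)]
        idx_new[tuple(dst)] = idx[tuple(src)]
    return _rebuild(image, labels, img_new, idx_new)


_OPERATIONS = (elastic_deform, affine_warp, uniaxial_rotate, shift)


def augment_case(case: CaseRecord, cfg: AugmentConfig, rng: np.random.Generator,
                 copy_index: int) -> CaseRecord:
    """One augmented variant: a random non-empty subset of the four operations."""
    n_ops = int(rng.integers(1, len(_OPERATIONS) + 1))
    chosen = rng.choice(len(_OPERATIONS), size=n_ops, replace=False)
    img, lab = case.image, case.labels
    for op_idx in sorted(chosen):
        img, lab = _OPERATIONS[op_idx](img, lab, cfg, rng)
    return CaseRecord(
        patient_id=case.patient_id,
        series_id=f"{case.series_id}_aug{copy_index}",
        image=img,
        labels=lab,
        is_outlier=case.is_outlier,
        class_vector=case.class_vector,
    )


def augment_dataset(cases: list[CaseRecord], cfg: AugmentConfig) -> list[CaseRecord]:
    """Each input case yields the original plus ``n_copies`` augmented
    variants: ``len(output) == len(cases) * (1 + n_copies)``."""
    rng = np.random.default_rng(cfg.seed)
    out: list[CaseRecord] = []
    for case in cases:
        out.append(case)
        for k in range(cfg.n_copies):
            out.append(augment_case(case, cfg, rng, k))
    return out
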