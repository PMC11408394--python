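"""Case preprocessing: bias correction, grid resampling, structure merging,
per-case class-label assignment, and connected-component post-processing.

The class-label rules encode the two anatomical regimes the masked networks
are conditioned on: an inflated bladder (largest inscribed-sphere radius above
17 mm) and a large tumour (GTV volume more than 4x the uterus volume).  Both
thresholds are strict inequalities and configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import (
    DEFAULT_CHANNELS,
    ImageVolume,
    LabelVolume,
    labels_from_indexmap,
)

__all__ = [
    "ClassLabelVector",
    "PreprocessConfig",
    "bias_correct",
    "resample_to_grid",
    "merge_cgu",
    "max_inscribed_radius",
    "assign_class_labels",
    "class_vector_to_volume",
    "keep_largest_component",
    "normalize_intensity",
]

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ClassLabelVector:
    """Per-case binary vector, one entry per output channel.

    Channel order follows the label channels (background, bladder, CGU,
    rectum); only bladder and CGU ever receive a class rule, so background and
    rectum entries stay 0.
    """

    values: tuple[int, ...]

    def __post_init__(self):
        self.values = tuple(int(v) for v in self.values)
        if any(v not in (0, 1) for v in self.values):
            raise ValueError("class-label entries must be 0 or 1")

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)

    def __eq__(self, other):
        vals = other.values if isinstance(other, ClassLabelVector) else tuple(other)
        return self.values == tuple(int(v) for v in vals)


@dataclass
class PreprocessConfig:
    target_shape: tuple[int, int, int] = (256, 256, 64)
    target_spacing: tuple[float, float, float] = (1.64, 1.64, 3.0)
    bladder_radius_threshold_mm: float = 17.0
    gtv_uterus_ratio_threshold: float = 4.0
    bias_correction: bool = False
    bladder_channel: int = 1
    cgu_channel: int = 2
    n_channels: int = 4

    def __post_init__(self):
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if self.bladder_radius_threshold_mm <= 0 or self.gtv_uterus_ratio_threshold <= 0:
            raise ValueError("thresholds must be positive")


def bias_correct(image: ImageVolume, enabled: bool = True,
                 shrink_factor: int = 2) -> ImageVolume:
    """Intensity-inhomogeneity correction via SimpleITK's N4 algorithm.

    The corrector is a pluggable hook: with ``enabled=False`` the image passes
    through unchanged, and any failure of the external corrector falls back to
    identity with a warning.  Shape and spacing are always preserved.
    """
    if not enabled:
        log.info("bias correction disabled; identity pass-through")
        return image
    try:
        import SimpleITK as sitk

        arr = np.asarray(image.data, dtype=np.float64)
        shift = 0.0
        if arr.min() <= 0:  # N4 works on log intensities; keep them positive
            shift = -arr.min() + 1e-3
        itk = sitk.GetImageFromArray(np.transpose(arr + shift, (2, 1, 0)))
        itk.SetSpacing(tuple(float(s) for s in image.spacing))
        small = sitk.Shrink(itk, [shrink_factor] * 3)
        corrector = sitk.N4BiasFieldCorrectionImageFilter()
        corrector.Execute(small)
        log_bias = corrector.GetLogBiasFieldAsImage(itk)
        bias = np.transpose(sitk.GetArrayFromImage(sitk.Exp(log_bias)), (2, 1, 0))
        corrected = (arr + shift) / bias - shift
        return ImageVolume(corrected, spacing=image.spacing, origin=image.origin)
    except Exception as exc:  # noqa: BLE001 - contract: degrade to identity
        warnings.warn(f"N4 bias correction failed ({exc}); returning input unchanged")
        return image


def resample_to_grid(image: ImageVolume, labels: LabelVolume,
                     cfg: PreprocessConfig) -> tuple[ImageVolume, LabelVolume]:
    """Resample a case onto the network grid, centred on the input's physical
    centre.  Image: trilinear; labels: nearest neighbour on the index map then
    re-one-hot.  Regions outside the input get 0 intensity / background."""
    if image.shape != labels.data.shape[:3]:
        raise ValueError("image and labels must share a grid")
    in_spacing = np.asarray(image.spacing)
    out_shape = tuple(int(s) for s in cfg.target_shape)
    out_spacing = np.asarray(cfg.target_spacing, dtype=float)
    if image.shape == out_shape and np.allclose(in_spacing, out_spacing):
        return image, labels

    center_in = (np.asarray(image.shape) - 1) / 2.0  # voxel index of centre
    center_out = (np.asarray(out_shape) - 1) / 2.0
    # input voxel index sampled at output voxel i: align physical centres
    axes = [
        (np.arange(n) - c_out) * s_out / s_in + c_in
        for n, c_out, s_out, s_in, c_in in zip(
            out_shape, center_out, out_spacing, in_spacing, center_in
        )
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    coords = np.stack(coords, axis=0)
    img_out = ndimage.map_coordinates(
        np.asarray(image.data, dtype=float), coords, order=1, mode="constant", cval=0.0
    )
    idx_out = ndimage.map_coordinates(
        labels.indexmap(), coords, order=0, mode="constant", cval=0
    )
    new_origin = (
        np.asarray(image.origin)
        + center_in * in_spacing
        - center_out * out_spacing
    )
    out_image = ImageVolume(img_out, spacing=tuple(out_spacing), origin=tuple(new_origin))
    out_labels = labels_from_indexmap(
        idx_out, labels.n_channels, channel_names=labels.channel_names,
        spacing=tuple(out_spacing),
    )
    return out_image, out_labels


def merge_cgu(labels: LabelVolume, members: tuple[str, ...] = ("cervix", "gtv", "uterus"),
              merged_name: str = "cgu") -> LabelVolume:
    """Merge the cervix, GTV and uterus channels into a single CGU channel
    (voxelwise union; overlaps counted once).  Other channels are unchanged."""
    names = labels.channel_names
    missing = [m for m in members if m not in names]
    if missing:
        raise KeyError(f"labels lack channel(s) {missing}; have {list(names)}")
    union = np.zeros(labels.data.shape[:3], dtype=np.uint8)
    for m in members:
        union |= labels.channel(m).astype(np.uint8)
    keep = [n for n in names if n not in members]
    first_member = min(names.index(m) for m in members)
    out_names = list(keep)
    insert_at = sum(1 for n in keep if names.index(n) < first_member)
    out_names.insert(insert_at, merged_name)
    out = np.zeros(labels.data.shape[:3] + (len(out_names),), dtype=np.uint8)
    for i, n in enumerate(out_names):
        if n == merged_name:
            out[..., i] = union
        else:
            out[..., i] = labels.channel(n)
            out[..., i] &= 1 - union  # precedence: merged structure wins overlaps
    # re-impose one-hot: voxels claimed by no channel fall to background (0)
    claimed = out.sum(axis=-1)
    out[..., 0] |= (claimed == 0).astype(np.uint8)
    return LabelVolume(out, channel_names=tuple(out_names), spacing=labels.spacing)


def max_inscribed_radius(mask: np.ndarray, spacing) -> float:
    """Largest inscribed-sphere radius (mm) of a binary mask.

    Computed as the maximum over mask voxels of the anisotropic Euclidean
    distance to the nearest background voxel; the volume border counts as
    background.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("max_inscribed_radius: empty mask")
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_edt(padded, sampling=tuple(spacing))
    return float(dist.max())


def assign_class_labels(bladder_mask: np.ndarray, gtv_mask: np.ndarray,
                        uterus_mask: np.ndarray, spacing,
                        cfg: PreprocessConfig | None = None) -> ClassLabelVector:
    """Derive the per-case class-label vector from organ geometry.

    Bladder entry = 1 iff the bladder's largest inscribed-sphere radius is
    strictly above the 17 mm threshold; CGU entry = 1 iff the GTV volume is
    strictly larger than 4x the uterus volume.  Background and rectum stay 0.
    """
    cfg = cfg or PreprocessConfig()
    bladder_mask = np.asarray(bladder_mask).astype(bool)
    if not bladder_mask.any():
        raise ValueError("assign_class_labels: empty bladder mask")
    radius = max_inscribed_radius(bladder_mask, spacing)
    bladder_flag = int(radius > cfg.bladder_radius_threshold_mm)

    voxel_vol = float(np.prod(spacing))
    gtv_vol = float(np.asarray(gtv_mask).astype(bool).sum()) * voxel_vol
    uterus_vol = float(np.asarray(uterus_mask).astype(bool).sum()) * voxel_vol
    if uterus_vol == 0.0:
        if gtv_vol > 0:
            warnings.warn("empty uterus with non-empty GTV: ratio degenerate, flag set to 1")
            cgu_flag = 1
        else:
            cgu_flag = 0
    else:
        cgu_flag = int(gtv_vol > cfg.gtv_uterus_ratio_threshold * uterus_vol)

    values = [0] * cfg.n_channels
    values[cfg.bladder_channel] = bladder_flag
    values[cfg.cgu_channel] = cgu_flag
    return ClassLabelVector(tuple(values))


def class_vector_to_volume(vec: ClassLabelVector | tuple, shape) -> np.ndarray:
    """Broadcast a class vector to a constant ``(X,Y,Z,C)`` volume."""
    values = np.asarray(tuple(vec), dtype=np.float32)
    out = np.empty(tuple(shape) + (len(values),), dtype=np.float32)
    out[...] = values
    return out


def keep_largest_component(labels: LabelVolume) -> LabelVolume:
    """Per foreground channel, retain only the largest 26-connected component.

    Removed voxels become background.  Ties between equal-sized components go
    to the one whose seed voxel comes first in lexicographic scan order (which
    is the lowest label id assigned by the scan).
    """
    out = labels.data.copy()
    for c in range(1, labels.n_channels):
        chan = out[..., c].astype(bool)
        lab, n = ndimage.label(chan, structure=_STRUCT_26)
        if n <= 1:
            continue
        counts = np.bincount(lab.ravel())[1:]
        keep = int(np.argmax(counts)) + 1  # argmax -> lowest label id on ties
        removed = chan & (lab != keep)
        out[..., c][removed] = 0
        out[..., 0][removed] = 1
    return LabelVolume(out, channel_names=labels.channel_names, spacing=labels.spacing)


def normalize_intensity(image: ImageVolume) -> ImageVolume:
    """Per-volume z-score normalisation (mean 0, SD 1)."""
    data = np.asarray(image.data, dtype=np.float32)
    sd = data.std()
    data = (data - data.mean()) / (sd if sd > 0 else 1.0)
    return ImageVolume(data, spacing=image.spacing, origin=image.origin)
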