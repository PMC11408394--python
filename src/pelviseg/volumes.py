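"""Core volumetric data types, coordinate conventions and NIfTI I/O.

Conventions used throughout the package:

* scalar images are 3D arrays in ``(X, Y, Z)`` order with per-axis voxel
  spacing in millimetres;
* label data are carried in memory as one-hot 4D arrays ``(X, Y, Z, C)``,
  channel-last, with channel order ``background, bladder, CGU, rectum`` by
  default (CGU = merged cervix + gross tumour volume + uterus);
* on disk, images and label index maps are NIfTI-1 (`.nii` / `.nii.gz`); the
  one-hot expansion happens in memory only;
* volumes are used in stored voxel order — no reorientation to an anatomical
  frame is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DEFAULT_CHANNELS",
    "VolumeFormatError",
    "ImageVolume",
    "LabelVolume",
    "PredictionVolume",
    "CaseRecord",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "labels_from_indexmap",
    "argmax_labels",
    "load_manifest",
    "save_manifest",
]

DEFAULT_CHANNELS: tuple[str, ...] = ("background", "bladder", "cgu", "rectum")


class VolumeFormatError(ValueError):
    """Raised for unreadable files or payloads with the wrong dimensionality."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid plus voxel spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"ImageVolume requires a 3D grid, got {self.data.ndim}D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume contains NaN or Inf")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_center(self) -> np.ndarray:
        """Physical coordinates (mm) of the grid centre, voxel-centre convention."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )


@dataclass
class LabelVolume:
    """One-hot ground-truth labels over an image grid (symbol ``p``)."""

    data: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise VolumeFormatError("LabelVolume requires a 4D (X,Y,Z,C) grid")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[-1]:
            raise ValueError("channel_names length must match the channel axis")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("LabelVolume entries must be 0 or 1")
        if not (self.data.sum(axis=-1) == 1).all():
            raise ValueError("LabelVolume must be one-hot over channels")
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    def indexmap(self) -> np.ndarray:
        """Collapse the one-hot channels to a 3D integer label map."""
        return np.argmax(self.data, axis=-1).astype(np.int16)

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., self.channel_names.index(name)]


@dataclass
class PredictionVolume:
    """Per-channel probability field over an image grid (symbol ``q``)."""

    data: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise VolumeFormatError("PredictionVolume requires a 4D (X,Y,Z,C) grid")
        self.channel_names = tuple(self.channel_names)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("PredictionVolume values must lie in [0, 1]")
        sums = self.data.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("PredictionVolume channels must sum to 1 per voxel")
        self.spacing = _check_spacing(self.spacing)


@dataclass
class CaseRecord:
    """One labelled image series of one patient.

    ``aux_masks`` optionally carries raw pre-merge component masks (e.g. the
    separate cervix / GTV / uterus masks of a phantom) and ``class_vector`` the
    per-case class-label vector, when known at generation time.
    """

    patient_id: str
    series_id: str
    image: ImageVolume
    labels: LabelVolume
    is_outlier: bool = False
    class_vector: "object | None" = None
    aux_masks: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI-1 file into an :class:`ImageVolume` (X,Y,Z order)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D payload, got {data.ndim}D {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))


def read_labels(path: str | Path, n_channels: int = len(DEFAULT_CHANNELS),
                channel_names: tuple[str, ...] = DEFAULT_CHANNELS) -> LabelVolume:
    """Read an integer index-map NIfTI and expand to a one-hot LabelVolume."""
    vol = read_volume(path)
    lab = labels_from_indexmap(np.rint(vol.data).astype(np.int64), n_channels)
    return LabelVolume(lab.data, channel_names=channel_names, spacing=vol.spacing)


def write_labels(labels: LabelVolume, path: str | Path,
                 origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> None:
    write_volume(
        ImageVolume(labels.indexmap(), spacing=labels.spacing, origin=origin), path
    )


# ---------------------------------------------------------------------------
# Label conversions


def labels_from_indexmap(indexmap: np.ndarray, n_channels: int,
                         channel_names: tuple[str, ...] | None = None,
                         spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """One-hot encode a 3D integer label map into ``(X,Y,Z,C)``."""
    indexmap = np.asarray(indexmap)
    if indexmap.ndim != 3:
        raise VolumeFormatError("indexmap must be 3D")
    bad = (indexmap < 0) | (indexmap >= n_channels)
    if bad.any():
        offending = np.unique(indexmap[bad])
        raise ValueError(
            f"label value(s) {offending.tolist()} outside [0, {n_channels})"
        )
    onehot = np.zeros(indexmap.shape + (n_channels,), dtype=np.uint8)
    np.put_along_axis(onehot, indexmap[..., None].astype(np.int64), 1, axis=-1)
    names = channel_names or (
        DEFAULT_CHANNELS if n_channels == len(DEFAULT_CHANNELS)
        else tuple(f"ch{i}" for i in range(n_channels))
    )
    return LabelVolume(onehot, channel_names=names, spacing=spacing)


def argmax_labels(pred: PredictionVolume) -> LabelVolume:
    """Harden per-voxel probabilities to one-hot; ties go to the lowest channel.

    ``np.argmax`` returns the first maximal index, which implements the
    documented tie-break.
    """
    idx = np.argmax(pred.data, axis=-1)
    return labels_from_indexmap(
        idx, pred.data.shape[-1], channel_names=pred.channel_names, spacing=pred.spacing
    )


# ---------------------------------------------------------------------------
# Dataset manifest


def save_manifest(cases: list[dict], path: str | Path) -> None:
    """Write a JSON manifest: list of {patient_id, series_id, image_path,
    label_path, is_outlier}."""
    Path(path).write_text(json.dumps({"cases": cases}, indent=2))


def load_manifest(path: str | Path, n_channels: int = len(DEFAULT_CHANNELS)) -> list[CaseRecord]:
    """Load every case listed in a JSON manifest (paths relative to it)."""
    path = Path(path)
    entries = json.loads(path.read_text())["cases"]
    root = path.parent
    records = []
    seen = set()
    for e in entries:
        key = (e["patient_id"], e["series_id"])
        if key in seen:
            raise ValueError(f"duplicate (patient_id, series_id): {key}")
        seen.add(key)
        records.append(
            CaseRecord(
                patient_id=e["patient_id"],
                series_id=e["series_id"],
                image=read_volume(root / e["image_path"]),
                labels=read_labels(root / e["label_path"], n_channels=n_channels),
                is_outlier=bool(e.get("is_outlier", False)),
            )
        )
    return records
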