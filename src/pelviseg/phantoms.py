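"""Synthetic pelvic phantoms: image + one-hot labels + per-case class vector.

The generator stands in for clinical female-pelvis T2-weighted MRI.  Each
phantom contains three single-connected-component structures on a coarse
grid (default 48x48x16 voxels at 5x5x10 mm):

* **bladder** — an ellipsoid, bright (fluid on T2);
* **CGU** — the merged cervix + GTV + uterus structure, modelled as a union
  of 2–3 overlapping ellipsoids with one "tumour" component of controllable
  volume, intermediate intensity;
* **rectum** — a curved tube (capsule around a quadratic Bezier centerline),
  dark.

Structures are laid out anterior-to-posterior with margins so they stay
pairwise disjoint and at least two voxels inside the grid; a fixed precedence
order (bladder < CGU < rectum) resolves any contested voxel.  Default organ
volumes are the clinical medians (bladder 200 cm^3, GTV 111.7 cm^3, rectum
57.95 cm^3); population sampling draws volumes log-uniformly, either within a
narrow "small" band or across the full clinical ranges (bladder 30.08–721.8,
GTV 11.42–712.31, rectum 19.3–213.45 cm^3).

The intensity model adds a smooth multiplicative polynomial bias field and
additive Gaussian noise.  It is loosely T2-like by convention only: no k-space
simulation, no relaxometry, no partial-volume modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .preprocessing import PreprocessConfig, assign_class_labels
from .volumes import CaseRecord, DEFAULT_CHANNELS, ImageVolume, labels_from_indexmap

__all__ = [
    "PhantomSpecError",
    "PhantomSpec",
    "generate_phantom",
    "sample_phantom_population",
    "PAPER_VOLUME_RANGES_CM3",
    "SMALL_VOLUME_RANGES_CM3",
    "MEDIAN_VOLUMES_CM3",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: Clinical volume ranges (cm^3) spanned by the source cohort.
PAPER_VOLUME_RANGES_CM3 = {
    "bladder": (30.08, 721.8),
    "gtv": (11.42, 712.31),
    "rectum": (19.3, 213.45),
    "uterus": (30.0, 250.0),  # not reported; plausible adult range
}

#: Narrow band around the medians, for quick well-conditioned experiments.
SMALL_VOLUME_RANGES_CM3 = {
    "bladder": (150.0, 320.0),
    "gtv": (60.0, 180.0),
    "rectum": (40.0, 90.0),
    "uterus": (60.0, 150.0),
}

MEDIAN_VOLUMES_CM3 = {"bladder": 200.0, "gtv": 111.7, "rectum": 57.95, "uterus": 90.0}

_ASPECTS = {
    "bladder": (1.0, 0.85, 0.9),
    "uterus": (0.9, 0.8, 1.0),
    "gtv": (0.95, 0.85, 1.0),
    "cervix": (0.8, 0.7, 1.2),
}

_CERVIX_VOLUME_CM3 = 20.0

DEFAULT_INTENSITIES = {"background": 0.35, "bladder": 0.9, "cgu": 0.55, "rectum": 0.2}


class PhantomSpecError(ValueError):
    """Raised when a structure cannot be placed inside the grid."""


def _semiaxes(volume_cm3: float, aspect: tuple[float, float, float]) -> np.ndarray:
    v_mm3 = volume_cm3 * 1000.0
    r = (3.0 * v_mm3 / (4.0 * math.pi * np.prod(aspect))) ** (1.0 / 3.0)
    return r * np.asarray(aspect)


def _capsule_radius(volume_cm3: float, length_mm: float) -> float:
    """Radius r with pi r^2 L + 4/3 pi r^3 = volume."""
    v = volume_cm3 * 1000.0

    def f(r):
        return math.pi * r * r * length_mm + 4.0 / 3.0 * math.pi * r**3 - v

    return brentq(f, 1e-3, 200.0)


@dataclass
class PhantomSpec:
    """Full geometric and intensity description of one phantom.

    Leave the geometry fields at ``None`` to have them derived from the
    requested structure volumes via the standard anterior-to-posterior layout.
    """

    shape: tuple[int, int, int] = (48, 48, 16)
    spacing: tuple[float, float, float] = (5.0, 5.0, 10.0)
    volumes_cm3: dict = field(default_factory=lambda: dict(MEDIAN_VOLUMES_CM3))
    bladder_center_mm: tuple | None = None
    bladder_semiaxes_mm: tuple | None = None
    uterus_center_mm: tuple | None = None
    uterus_semiaxes_mm: tuple | None = None
    cervix_center_mm: tuple | None = None
    cervix_semiaxes_mm: tuple | None = None
    tumour_center_mm: tuple | None = None
    tumour_semiaxes_mm: tuple | None = None
    rectum_control_points_mm: tuple | None = None
    rectum_radius_mm: float | None = None
    intensity_means: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 0.05
    bias_order: int = 2
    bias_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.bladder_center_mm is None:
            self._derive_layout()

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def _derive_layout(self) -> None:
        ext = self.extent_mm
        sp = np.asarray(self.spacing)
        margin = 2.5 * sp  # structures must clear a 2-voxel border shell
        gap = 2.0 * sp[1]
        vols = {**MEDIAN_VOLUMES_CM3, **self.volumes_cm3}

        b_ax = _semiaxes(vols["bladder"], _ASPECTS["bladder"])
        u_ax = _semiaxes(vols["uterus"], _ASPECTS["uterus"])
        t_ax = _semiaxes(vols["gtv"], _ASPECTS["gtv"])
        c_ax = _semiaxes(_CERVIX_VOLUME_CM3, _ASPECTS["cervix"])

        xc = ext[0] / 2.0
        # anterior-to-posterior rows: bladder | CGU cluster | rectum
        b_cy = margin[1] + b_ax[1]
        # tumour sits offset inside/against the uterus; cervix hangs inferiorly
        t_off = np.array([0.15 * u_ax[0], 0.25 * u_ax[1], -0.10 * u_ax[2]])
        c_off = np.array([0.0, 0.1 * u_ax[1], -(0.8 * u_ax[2] + 0.4 * c_ax[2])])
        cluster_front = max(u_ax[1], -t_off[1] + t_ax[1])
        cluster_back = max(u_ax[1], t_off[1] + t_ax[1], c_off[1] + c_ax[1])
        u_cy = b_cy + b_ax[1] + gap + cluster_front

        z_mid = ext[2] / 2.0
        cluster_down = max(u_ax[2], -t_off[2] + t_ax[2], -c_off[2] + c_ax[2])
        cluster_up = max(u_ax[2], t_off[2] + t_ax[2])
        u_cz = min(max(z_mid, margin[2] + cluster_down),
                   ext[2] - margin[2] - cluster_up)
        b_cz = min(max(z_mid, margin[2] + b_ax[2]), ext[2] - margin[2] - b_ax[2])

        self.bladder_center_mm = (xc, float(b_cy), float(b_cz))
        self.bladder_semiaxes_mm = tuple(b_ax)
        self.uterus_center_mm = (xc, float(u_cy), float(u_cz))
        self.uterus_semiaxes_mm = tuple(u_ax)
        tumour_c = np.array(self.uterus_center_mm) + t_off
        self.tumour_center_mm = tuple(tumour_c)
        self.tumour_semiaxes_mm = tuple(t_ax)
        cervix_c = np.array(self.uterus_center_mm) + c_off
        self.cervix_center_mm = tuple(cervix_c)
        self.cervix_semiaxes_mm = tuple(c_ax)

        # solve tube radius and length jointly so the end caps clear the
        # z margin: length = extent - 2*(margin + radius)
        length = 0.55 * ext[2]
        for _ in range(6):
            r = _capsule_radius(vols["rectum"], length)
            length = min(0.55 * ext[2], ext[2] - 2.0 * (margin[2] + r) - sp[2])
            if length <= 2 * sp[2]:
                raise PhantomSpecError("rectum volume too large for the grid")
        r = _capsule_radius(vols["rectum"], length)
        r_cy = u_cy + cluster_back + gap + r
        z0 = z_mid - length / 2.0
        z1 = z_mid + length / 2.0
        bow = min(6.0, ext[1] - margin[1] - r - r_cy)
        self.rectum_control_points_mm = (
            (xc, r_cy, z0),
            (xc, r_cy + bow, (z0 + z1) / 2.0),
            (xc, r_cy, z1),
        )
        self.rectum_radius_mm = float(r)


def _ellipsoid_mask(grids, center, semiaxes) -> np.ndarray:
    gx, gy, gz = grids
    cx, cy, cz = center
    a, b, c = semiaxes
    return ((gx - cx) / a) ** 2 + ((gy - cy) / b) ** 2 + ((gz - cz) / c) ** 2 <= 1.0


def _capsule_mask(grids, control_points, radius, spacing,
                  target_volume_mm3: float | None = None) -> np.ndarray:
    """Voxels within ``radius`` of a quadratic Bezier centerline.

    With ``target_volume_mm3`` set, the radius is recalibrated (within +-15%)
    on the voxel grid so the rasterized volume matches the request — at
    coarse through-plane spacing the naive threshold misses by several
    percent for thin tubes.
    """
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in control_points)
    t = np.linspace(0.0, 1.0, 256)[:, None]
    curve = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    tree = cKDTree(curve)
    gx, gy, gz = grids
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d, _ = tree.query(pts, k=1)
    if target_volume_mm3 is not None:
        voxel = float(np.prod(spacing))
        k = max(1, int(round(target_volume_mm3 / voxel)))
        d_sorted = np.sort(d)
        if k < len(d_sorted):
            r_cal = 0.5 * (d_sorted[k - 1] + d_sorted[k])
            radius = float(np.clip(r_cal, 0.85 * radius, 1.15 * radius))
    return (d <= radius).reshape(gx.shape)


def _check_margin(mask: np.ndarray, name: str) -> None:
    shell = np.ones(mask.shape, dtype=bool)
    shell[2:-2, 2:-2, 2:-2] = False
    if (mask & shell).any():
        raise PhantomSpecError(f"structure {name!r} violates the 2-voxel grid margin")


def _check_connected(mask: np.ndarray, name: str) -> None:
    if not mask.any():
        raise PhantomSpecError(f"structure {name!r} rasterized to an empty mask")
    _, n = ndimage.label(mask, structure=_STRUCT_26)
    if n != 1:
        raise PhantomSpecError(f"structure {name!r} has {n} connected components")


def _bias_field(shape, rng, order: int, amplitude: float) -> np.ndarray:
    if amplitude == 0.0:
        return np.ones(shape)
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    poly = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue
                poly += rng.normal() * gx**i * gy**j * gz**k
    peak = np.abs(poly).max()
    if peak > 0:
        poly /= peak
    return 1.0 + amplitude * poly


def generate_phantom(spec: PhantomSpec, patient_id: str = "phantom",
                     series_id: str = "s0", is_outlier: bool = False) -> CaseRecord:
    """Rasterize one phantom: image, one-hot labels, raw component masks and
    the derived class-label vector.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.spacing, dtype=float)
    axes = [np.arange(n) * s for n, s in zip(spec.shape, sp)]
    grids = np.meshgrid(*axes, indexing="ij")

    bladder = _ellipsoid_mask(grids, spec.bladder_center_mm, spec.bladder_semiaxes_mm)
    uterus = _ellipsoid_mask(grids, spec.uterus_center_mm, spec.uterus_semiaxes_mm)
    cervix = _ellipsoid_mask(grids, spec.cervix_center_mm, spec.cervix_semiaxes_mm)
    tumour = _ellipsoid_mask(grids, spec.tumour_center_mm, spec.tumour_semiaxes_mm)
    rectum = _capsule_mask(grids, spec.rectum_control_points_mm,
                           spec.rectum_radius_mm, sp,
                           target_volume_mm3=spec.volumes_cm3.get("rectum", 0) * 1000.0
                           if spec.volumes_cm3 else None)
    cgu = uterus | cervix | tumour

    for name, mask in (("bladder", bladder), ("cgu", cgu), ("rectum", rectum)):
        _check_margin(mask, name)

    # fixed precedence: later structures win contested voxels
    indexmap = np.zeros(spec.shape, dtype=np.int16)
    indexmap[bladder] = 1
    indexmap[cgu] = 2
    indexmap[rectum] = 3

    for c, name in ((1, "bladder"), (2, "cgu"), (3, "rectum")):
        _check_connected(indexmap == c, name)

    labels = labels_from_indexmap(indexmap, 4, channel_names=DEFAULT_CHANNELS,
                                  spacing=tuple(sp))

    means = np.array([
        spec.intensity_means["background"],
        spec.intensity_means["bladder"],
        spec.intensity_means["cgu"],
        spec.intensity_means["rectum"],
    ])
    image = means[indexmap]
    image = image * _bias_field(spec.shape, rng, spec.bias_order, spec.bias_amplitude)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    class_vec = assign_class_labels(
        bladder, tumour, uterus, sp,
        PreprocessConfig(target_shape=spec.shape, target_spacing=tuple(sp)),
    )
    return CaseRecord(
        patient_id=patient_id,
        series_id=series_id,
        image=ImageVolume(image, spacing=tuple(sp)),
        labels=labels,
        is_outlier=is_outlier,
        class_vector=class_vec,
        aux_masks={"bladder": bladder, "cervix": cervix, "gtv": tumour,
                   "uterus": uterus, "rectum": rectum},
    )


def sample_phantom_population(n: int, seed: int = 0, variation: str = "small",
                              series_per_patient: int = 1,
                              shape: tuple[int, int, int] | None = None,
                              spacing: tuple[float, float, float] | None = None,
                              ) -> list[CaseRecord]:
    """Draw a reproducible population of ``n`` patients (``n*series_per_patient``
    phantoms) with per-structure volumes log-uniform in the configured range.

    ``variation="paper-range"`` spans the full clinical volume ranges and
    defaults to a 64x64x32 grid at 5 mm isotropic so the largest organs fit;
    ``"small"`` stays near the medians on the default 48x48x16 grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {"small": SMALL_VOLUME_RANGES_CM3,
              "paper-range": PAPER_VOLUME_RANGES_CM3}[variation]
    if shape is None:
        shape = (64, 64, 32) if variation == "paper-range" else (48, 48, 16)
    if spacing is None:
        spacing = (5.0, 5.0, 5.0) if variation == "paper-range" else (5.0, 5.0, 10.0)
    rng = np.random.default_rng(seed)
    cases: list[CaseRecord] = []
    for i in range(n):
        for s in range(series_per_patient):
            for attempt in range(20):
                vols = {
                    k: math.exp(rng.uniform(math.log(lo), math.log(hi)))
                    for k, (lo, hi) in ranges.items()
                }
                spec = PhantomSpec(
                    shape=tuple(shape), spacing=tuple(spacing), volumes_cm3=vols,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                try:
                    case = generate_phantom(spec, patient_id=f"P{i:03d}",
                                            series_id=f"P{i:03d}_s{s}")
                    break
                except PhantomSpecError:
                    continue  # redraw: this volume combination did not fit
            else:
                raise PhantomSpecError(
                    f"could not place structures for patient P{i:03d} after 20 draws"
                )
            cases.append(case)
    return cases
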