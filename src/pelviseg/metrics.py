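"""Evaluation metrics in physical units and the paired statistics used to
compare segmentation approaches.

DSC is unitless overlap; Hausdorff (HD) and mean surface distance (MSD) are
computed between mask surfaces on voxel centres with anisotropic spacing, in
millimetres.  HD is the full (100th percentile) symmetric Hausdorff distance;
MSD is the symmetric average of the two directed mean surface distances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

__all__ = [
    "dsc",
    "surface_voxels",
    "hausdorff",
    "mean_surface_distance",
    "aggregate",
    "paired_wilcoxon",
    "MetricReport",
]

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|a n b| / (|a|+|b|)``; 1 when both empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (N,3) of mask voxels with a face-adjacent background
    neighbour; the volume border counts as background."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, 3), dtype=np.int64)
    interior = ndimage.binary_erosion(mask, structure=_STRUCT_6, border_value=0)
    return np.argwhere(mask & ~interior)


def _surface_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    pts = surface_voxels(mask).astype(float)
    return pts * np.asarray(spacing, dtype=float)


def _directed_distances(a_pts: np.ndarray, b_pts: np.ndarray) -> np.ndarray:
    tree = cKDTree(b_pts)
    d, _ = tree.query(a_pts, k=1)
    return d


def hausdorff(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance (mm) between mask surfaces."""
    pa, pb = _surface_points_mm(a, spacing), _surface_points_mm(b, spacing)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("hausdorff requires two non-empty masks")
    return float(max(_directed_distances(pa, pb).max(),
                     _directed_distances(pb, pa).max()))


def mean_surface_distance(a: np.ndarray, b: np.ndarray,
                          spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric mean surface distance (mm): average of both directed means."""
    pa, pb = _surface_points_mm(a, spacing), _surface_points_mm(b, spacing)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("mean_surface_distance requires two non-empty masks")
    return float(0.5 * (_directed_distances(pa, pb).mean()
                        + _directed_distances(pb, pa).mean()))


def aggregate(rows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-case metric rows to mean/median/sample-SD per structure
    and metric.  A single row yields SD 0 with ``sd_degenerate=True``.

    ``rows`` columns: series_id, structure, plus one column per metric
    (any of dsc, hd, msd)."""
    metric_cols = [c for c in ("dsc", "hd", "msd") if c in rows.columns]
    if rows.empty or not metric_cols:
        raise ValueError("aggregate needs at least one row and one metric column")
    records = []
    for structure, grp in rows.groupby("structure", sort=True):
        for m in metric_cols:
            vals = grp[m].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            degenerate = len(vals) < 2
            records.append(
                dict(
                    structure=structure,
                    metric=m,
                    n=len(vals),
                    mean=float(np.mean(vals)),
                    median=float(np.median(vals)),
                    sd=0.0 if degenerate else float(np.std(vals, ddof=1)),
                    sd_degenerate=degenerate,
                )
            )
    return pd.DataFrame.from_records(records)


def paired_wilcoxon(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    null distribution is used for n <= 25 remaining pairs, the tie-corrected
    normal approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; no test possible")
    if len(d) < 5:
        raise ValueError("fewer than 5 non-zero differences")
    method = "exact" if len(d) <= 25 and len(np.unique(np.abs(d))) == len(d) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=False)
    return float(res.pvalue)


class MetricReport:
    """Per-case metric rows plus recomputable aggregates and pairwise tests."""

    def __init__(self, rows: pd.DataFrame):
        self.rows = rows.reset_index(drop=True)

    def aggregates(self) -> pd.DataFrame:
        return aggregate(self.rows)

    def to_csv(self, rows_path, aggregates_path=None) -> None:
        self.rows.to_csv(rows_path, index=False)
        if aggregates_path is not None:
            self.aggregates().to_csv(aggregates_path, index=False)

    def summary(self) -> str:
        agg = self.aggregates()
        lines = [f"{'structure':<10} {'metric':<6} {'mean':>8} {'median':>8} {'sd':>8}"]
        for _, r in agg.iterrows():
            lines.append(
                f"{r.structure:<10} {r.metric:<6} {r['mean']:8.3f} "
                f"{r['median']:8.3f} {r['sd']:8.3f}"
            )
        return "\n".join(lines)
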