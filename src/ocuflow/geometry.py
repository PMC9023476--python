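"""Vessel segmentation, centreline extraction and EDT diameters.

Vessels are dark tubes on a bright sclera.  Segmentation flattens the
background with a large-kernel Gaussian, enhances dark ridges with a
multi-scale tubularity (Sato) filter, and thresholds the flattened
darkness image, keeping only components supported by the ridge response.
Centrelines come from iterative thinning; branches are split at junction
pixels and short spurs pruned.  Per-point diameter is twice the Euclidean
distance transform of the mask at the centreline, scaled to micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "VesselMask",
    "VesselSegment",
    "segment_vessels",
    "extract_centerlines",
    "edt_diameter",
    "score_quality",
    "include_segment",
    "segments_to_csv",
]


@dataclass
class VesselMask:
    mask: np.ndarray
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be > 0")

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class VesselSegment:
    """One vessel branch: ordered centreline points with diameters.

    ``points`` are (x, y) pixel coordinates ordered end-to-end.
    """

    points: np.ndarray
    um_per_px: float = 1.0
    diameters_um: np.ndarray | None = None
    quality: float = 1.0
    segment_id: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("a segment needs at least two centreline points")
        if self.diameters_um is not None:
            self.diameters_um = np.asarray(self.diameters_um, dtype=float)
            if self.diameters_um.shape[0] != self.points.shape[0]:
                raise ValueError("one diameter per centreline point required")
            if not (self.diameters_um > 0).all():
                raise ValueError("diameters must be > 0")

    @property
    def length_um(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * self.um_per_px)

    @property
    def mean_diameter_um(self) -> float:
        if self.diameters_um is None:
            raise ValueError("diameters not yet estimated")
        return float(self.diameters_um.mean())


# ---------------------------------------------------------------- segmentation
def segment_vessels(frame: np.ndarray, um_per_px: float = 1.0,
                    flatten_sigma_px: float = 25.0,
                    expected_diameter_um: tuple[float, float] = (10.0, 35.0),
                    depth_fraction: float = 0.30,
                    min_object_px: int = 50) -> VesselMask:
    """Binary vessel mask for a grayscale frame with dark vessels.

    ``depth_fraction`` sets the threshold as a fraction of the robust
    vessel darkness, placing the boundary near the three-quarter-coverage
    contour of the tube so EDT diameters stay unbiased.
    A constant-intensity frame yields an empty mask.
    """
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("frame must be 2-D grayscale")
    if np.ptp(f) == 0:
        return VesselMask(np.zeros_like(f, dtype=bool), um_per_px)

    background = ndimage.gaussian_filter(f, flatten_sigma_px)
    darkness = ndimage.gaussian_filter(background - f, 1.0)

    sigmas = np.linspace(expected_diameter_um[0] / um_per_px / 4.0,
                         expected_diameter_um[1] / um_per_px / 2.5, 5)
    ridge = filters.sato(darkness, sigmas=sigmas, black_ridges=False,
                         mode="reflect")
    ridge_pos = ridge[ridge > 0]
    if ridge_pos.size == 0:
        return VesselMask(np.zeros_like(f, dtype=bool), um_per_px)
    ridge_mask = ridge > filters.threshold_otsu(ridge)
    if not ridge_mask.any():
        return VesselMask(np.zeros_like(f, dtype=bool), um_per_px)

    depth = np.percentile(darkness[ridge_mask], 95)
    if depth <= 0:
        return VesselMask(np.zeros_like(f, dtype=bool), um_per_px)
    full = darkness > depth_fraction * depth
    # keep darkness-components supported by the tubularity response
    seed = full & ridge_mask
    mask = morphology.reconstruction(seed, full, method="dilation").astype(bool)
    mask = morphology.remove_small_objects(mask, max_size=min_object_px)
    mask = morphology.closing(mask, morphology.disk(1))
    return VesselMask(mask.astype(bool), um_per_px)


# -------------------------------------------------------------- centrelines
_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbour_count(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOUR_KERNEL,
                            mode="constant") * skel


def _trace_path(coords: set[tuple[int, int]],
                start: tuple[int, int]) -> list[tuple[int, int]]:
    """Walk a degree-<=2 pixel set from one end to the other."""
    path = [start]
    visited = {start}
    current = start
    while True:
        y, x = current
        nxt = None
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                cand = (y + dy, x + dx)
                if cand in coords and cand not in visited:
                    nxt = cand
                    break
            if nxt:
                break
        if nxt is None:
            return path
        path.append(nxt)
        visited.add(nxt)
        current = nxt


def _prune_spurs(skel: np.ndarray, min_spur_px: int) -> np.ndarray:
    """Iteratively remove endpoint branches shorter than ``min_spur_px``."""
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        counts = _neighbour_count(skel)
        end_ys, end_xs = np.nonzero(skel & (counts == 1))
        junction = skel & (counts >= 3)
        for y0, x0 in zip(end_ys, end_xs):
            if not skel[y0, x0]:
                continue
            path = [(y0, x0)]
            prev = None
            hit_junction = False
            while len(path) <= min_spur_px:
                y, x = path[-1]
                nxt = None
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == dx == 0:
                            continue
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < skel.shape[0] and 0 <= xx < skel.shape[1]
                                and skel[yy, xx] and (yy, xx) != prev):
                            if junction[yy, xx]:
                                hit_junction = True
                            else:
                                nxt = (yy, xx)
                            break
                    if nxt or hit_junction:
                        break
                if hit_junction or nxt is None:
                    break
                prev = (y, x)
                path.append(nxt)
            if hit_junction and len(path) <= min_spur_px:
                for (y, x) in path:
                    skel[y, x] = False
                changed = True
    return skel


def extract_centerlines(mask: VesselMask,
                        min_spur_px: int = 10) -> list[VesselSegment]:
    """Ordered centreline segments from a binary mask.

    The mask is thinned to a one-pixel skeleton, side spurs shorter than
    ``min_spur_px`` are pruned, junction pixels split the remainder into
    branches, and branches below the pruning floor are dropped.
    """
    if mask.empty:
        return []
    skel = morphology.skeletonize(mask.mask)
    skel = _prune_spurs(skel, min_spur_px)
    counts = _neighbour_count(skel)
    branches = skel & (counts <= 2)
    labels, n = ndimage.label(branches, structure=np.ones((3, 3)))
    segments: list[VesselSegment] = []
    sid = 0
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if ys.size < max(min_spur_px, 2):
            continue
        coords = set(zip(ys.tolist(), xs.tolist()))
        sub_counts = _neighbour_count(labels == lab)
        end_ys, end_xs = np.nonzero((labels == lab) & (sub_counts <= 1))
        start = ((end_ys[0], end_xs[0]) if end_ys.size
                 else (ys[0], xs[0]))  # cycles: arbitrary start
        path = _trace_path(coords, start)
        if len(path) < max(min_spur_px, 2):
            continue
        pts = np.array([(x, y) for (y, x) in path], dtype=float)
        # light smoothing removes the 8-connected zig-zag, which would
        # otherwise inflate arc length (and hence velocity) by a few %
        if len(pts) >= 7:
            pts = ndimage.uniform_filter1d(pts, size=7, axis=0,
                                           mode="nearest")
        segments.append(VesselSegment(points=pts, um_per_px=mask.um_per_px,
                                      segment_id=sid))
        sid += 1
    return segments


# ------------------------------------------------------------------ diameter
def edt_diameter(mask: VesselMask, segment: VesselSegment) -> VesselSegment:
    """Fill per-point diameters from the Euclidean distance transform.

    D(point) = 2 x (distance to the nearest background pixel) x um_per_px,
    sampled at the nearest pixel to each centreline point.
    """
    edt = ndimage.distance_transform_edt(mask.mask)
    xs = np.clip(np.rint(segment.points[:, 0]).astype(int), 0,
                 mask.mask.shape[1] - 1)
    ys = np.clip(np.rint(segment.points[:, 1]).astype(int), 0,
                 mask.mask.shape[0] - 1)
    inside = mask.mask[ys, xs]
    if not inside.all():
        bad = int(np.flatnonzero(~inside)[0])
        raise ValueError(
            f"centreline point {bad} at (x={segment.points[bad, 0]:.1f}, "
            f"y={segment.points[bad, 1]:.1f}) lies outside the mask foreground")
    diam = 2.0 * edt[ys, xs] * mask.um_per_px
    return VesselSegment(points=segment.points, um_per_px=segment.um_per_px,
                         diameters_um=diam, quality=segment.quality,
                         segment_id=segment.segment_id)


# -------------------------------------------------------------- quality / IO
def score_quality(frame: np.ndarray, segment: VesselSegment,
                  contrast_floor: float = 10.0,
                  flatten_sigma_px: float = 25.0) -> float:
    """Fraction of the centreline with local darkness above a floor."""
    f = np.asarray(frame, dtype=np.float64)
    darkness = ndimage.gaussian_filter(f, flatten_sigma_px) - f
    xs = np.clip(np.rint(segment.points[:, 0]).astype(int), 0, f.shape[1] - 1)
    ys = np.clip(np.rint(segment.points[:, 1]).astype(int), 0, f.shape[0] - 1)
    return float(np.mean(darkness[ys, xs] > contrast_floor))


def include_segment(segment: VesselSegment, quality_floor: float = 0.5,
                    min_length_um: float = 50.0) -> bool:
    """Quality gate for aggregation into patient means."""
    return (segment.quality >= quality_floor
            and segment.length_um >= min_length_um)


def segments_to_csv(segments: list[VesselSegment], path) -> None:
    rows = []
    for seg in segments:
        for i, (x, y) in enumerate(seg.points):
            rows.append({
                "segment_id": seg.segment_id, "point_index": i,
                "x": x, "y": y,
                "diameter_um": (np.nan if seg.diameters_um is None
                                else seg.diameters_um[i]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)
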