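"""Myocardial ring masks, automatic ROI detection, AHA-17 segments, LV mass.

Coordinate conventions (fixed, documented here because formats differ):

* images are ``(row, col)`` arrays, 0-based, pixel centers at integer
  coordinates;
* contour polygons are vertex lists ``[[x, y], ...]`` with x = column
  and y = row, matching the JSON interchange format;
* angles are measured in degrees **clockwise from image-up** (the
  12-o'clock direction of the displayed short-axis slice), so the
  image-right direction is at 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path
from shapely.geometry import Polygon

__all__ = [
    "MyoMask",
    "ROIRef",
    "SegmentLabels",
    "ring_mask_from_contours",
    "masks_from_contours",
    "auto_detect_rois",
    "aha17_segments",
    "lv_mass",
    "MYOCARDIAL_DENSITY_G_PER_ML",
]

#: Conventional myocardial tissue density used for mass computation.
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class MyoMask:
    """Per-slice boolean myocardial ring masks with voxel geometry."""

    masks: np.ndarray  # (n_slices, H, W) bool
    pixel_spacing: float  # mm (isotropic in-plane)
    slice_thickness: float  # mm

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (n_slices, H, W) array")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]


@dataclass
class ROIRef:
    """A labeled pixel subset on one slice (remote or high-SI)."""

    slice_index: int
    pixels: np.ndarray  # (N, 2) int array of (row, col)
    label: str  # "remote" | "high-SI"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        if self.pixels.shape[0] == 0:
            raise ValueError(f"{self.label} ROI is empty")

    def as_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class SegmentLabels:
    """Per-pixel AHA segment labels (0 outside the myocardium)."""

    labels: np.ndarray  # (n_slices, H, W) int
    rv_insertion_angle: float  # degrees, clockwise from image-up


def _validate_polygon(poly: np.ndarray, name: str) -> Polygon:
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError(f"{name} polygon needs at least 3 (x, y) vertices")
    shp = Polygon(poly)
    if not shp.is_valid or shp.area == 0:
        raise ValueError(f"{name} polygon is degenerate or self-intersecting")
    return shp


def ring_mask_from_contours(epi, endo, shape) -> np.ndarray:
    """Rasterize an epicardial/endocardial contour pair to a ring mask.

    A pixel belongs to the ring when its center lies inside the
    epicardial polygon and outside the endocardial polygon. Polygons are
    ``(x=col, y=row)`` vertex arrays. Raises ``ValueError`` for
    degenerate polygons or when endo is not strictly inside epi.
    """
    epi = np.asarray(epi, dtype=float)
    endo = np.asarray(endo, dtype=float)
    shp_epi = _validate_polygon(epi, "epicardial")
    shp_endo = _validate_polygon(endo, "endocardial")
    if not shp_epi.contains_properly(shp_endo):
        raise ValueError("endocardial contour is not strictly inside the epicardial contour")
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    inside_epi = Path(epi).contains_points(pts).reshape(h, w)
    inside_endo = Path(endo).contains_points(pts).reshape(h, w)
    return inside_epi & ~inside_endo


def masks_from_contours(contours, shape, pixel_spacing, slice_thickness) -> MyoMask:
    """Build a :class:`MyoMask` from a per-slice contour list.

    ``contours`` is a sequence of ``{"epi": [[x, y], ...], "endo": ...}``
    mappings, one per slice (the JSON interchange structure).
    """
    masks = np.stack(
        [ring_mask_from_contours(c["epi"], c["endo"], shape) for c in contours]
    )
    return MyoMask(masks=masks, pixel_spacing=pixel_spacing,
                   slice_thickness=slice_thickness)


def pixel_angles_deg(rows, cols, centroid) -> np.ndarray:
    """Angle of pixels about a centroid, degrees clockwise from image-up."""
    dy_up = -(np.asarray(rows, dtype=float) - centroid[0])
    dx = np.asarray(cols, dtype=float) - centroid[1]
    return np.degrees(np.arctan2(dx, dy_up)) % 360.0


def auto_detect_rois(lge_slice, myo_slice_mask, slice_index=0,
                     n_sectors: int = 60, arc_width: int = 5,
                     highsi_px: int | None = 30):
    """Detect remote and high-SI ROIs from extremal-mean angular arcs.

    The myocardial ring is divided into ``n_sectors`` equal angular
    sectors about its centroid; every contiguous (circular) arc of
    ``arc_width`` sectors gets the pixel-weighted mean signal intensity
    of its pixels. The arc with the minimal mean becomes the remote ROI
    and the one with the maximal mean hosts the high-SI ROI; if the two
    arcs would share a sector the next-best non-overlapping high-SI arc
    is taken. Ties are broken toward the lowest starting sector index.

    The remote ROI is the full minimal arc (unbiased reference
    statistics in unenhanced myocardium). The high-SI ROI is compact:
    the ``highsi_px`` brightest pixels within the maximal arc (all arc
    pixels when ``highsi_px`` is None), mimicking the small ROI clinical
    software drops onto the maximal-SI area; a full-thickness arc would
    dilute a subendocardial or mid-wall lesion with remote wall.

    Returns ``(remote, highsi)`` as :class:`ROIRef` objects.
    """
    lge_slice = np.asarray(lge_slice, dtype=float)
    myo = np.asarray(myo_slice_mask, dtype=bool)
    if not (n_sectors >= arc_width >= 1):
        raise ValueError("need n_sectors >= arc_width >= 1")
    rows, cols = np.nonzero(myo)
    if rows.size == 0:
        raise ValueError("empty myocardium mask")
    centroid = (rows.mean(), cols.mean())
    angles = pixel_angles_deg(rows, cols, centroid)
    sector_of = np.minimum((angles / (360.0 / n_sectors)).astype(int), n_sectors - 1)
    si = lge_slice[rows, cols]
    sums = np.bincount(sector_of, weights=si, minlength=n_sectors)
    counts = np.bincount(sector_of, minlength=n_sectors)

    def arc_sectors(start):
        return [(start + j) % n_sectors for j in range(arc_width)]

    means = np.full(n_sectors, np.nan)
    for start in range(n_sectors):
        sec = arc_sectors(start)
        n = counts[sec].sum()
        if n > 0:
            means[start] = sums[sec].sum() / n
    finite = np.isfinite(means)
    if not finite.any():
        raise ValueError("no populated sector arcs")
    # lowest starting index wins ties (np.nanargmin/max return the first).
    remote_start = int(np.nanargmin(means))
    remote_secs = set(arc_sectors(remote_start))
    order = sorted(np.nonzero(finite)[0], key=lambda s: (-means[s], s))
    highsi_start = None
    for start in order:
        if not remote_secs.intersection(arc_sectors(start)):
            highsi_start = start
            break
    if highsi_start is None:
        raise ValueError("cannot place non-overlapping remote and high-SI arcs")

    def roi(start, label, top_px=None):
        sel = np.isin(sector_of, arc_sectors(start))
        r, c, v = rows[sel], cols[sel], si[sel]
        if top_px is not None and r.size > top_px:
            keep = np.argsort(-v, kind="stable")[:top_px]
            r, c = r[keep], c[keep]
        return ROIRef(slice_index=slice_index,
                      pixels=np.column_stack([r, c]), label=label)

    return (roi(remote_start, "remote"),
            roi(highsi_start, "high-SI", top_px=highsi_px))


# Segment numbers encountered walking clockwise (in display) from the
# anterior RV insertion point, which sits on the anterior/anteroseptal
# boundary: first the anterior segment, then lateral and inferior walls,
# ending at the anteroseptal segment.
_BASAL_ORDER = (1, 6, 5, 4, 3, 2)
_MID_ORDER = (7, 12, 11, 10, 9, 8)
_APICAL_ORDER = (13, 16, 15, 14)  # anterior, lateral, inferior, septal


def aha17_segments(myo: MyoMask, rv_insertion_angle: float = 300.0,
                   slice_thirds=None) -> SegmentLabels:
    """Assign AHA 17-segment-model labels to every myocardial pixel.

    Slices are partitioned into basal/mid/apical thirds (slice 0 is
    basal); basal and mid slices are split into six 60-deg sectors and
    apical slices into four 90-deg sectors, counted clockwise from the
    anterior RV insertion angle. Standard numbering: 1 = basal anterior
    ... 16 = apical septal; the apical-cap segment 17 is not assigned
    from short-axis rings. For stacks with fewer than three slices an
    explicit ``slice_thirds`` sequence of ``{"basal","mid","apical"}``
    per slice is required.
    """
    n = myo.n_slices
    if slice_thirds is None:
        if n < 3:
            raise ValueError("fewer than 3 slices: pass an explicit slice_thirds mapping")
        groups = np.array_split(np.arange(n), 3)
        slice_thirds = [None] * n
        for name, idx in zip(("basal", "mid", "apical"), groups):
            for i in idx:
                slice_thirds[i] = name
    elif len(slice_thirds) != n:
        raise ValueError("slice_thirds length must equal the slice count")

    labels = np.zeros(myo.masks.shape, dtype=np.int16)
    for s in range(n):
        rows, cols = np.nonzero(myo.masks[s])
        if rows.size == 0:
            continue
        centroid = (rows.mean(), cols.mean())
        angles = (pixel_angles_deg(rows, cols, centroid) - rv_insertion_angle) % 360.0
        third = slice_thirds[s]
        if third in ("basal", "mid"):
            order = _BASAL_ORDER if third == "basal" else _MID_ORDER
            sec = np.minimum((angles / 60.0).astype(int), 5)
        elif third == "apical":
            order = _APICAL_ORDER
            sec = np.minimum((angles / 90.0).astype(int), 3)
        else:
            raise ValueError(f"unknown slice third {third!r} for slice {s}")
        labels[s, rows, cols] = np.asarray(order, dtype=np.int16)[sec]
    return SegmentLabels(labels=labels, rv_insertion_angle=rv_insertion_angle)


def lv_mass(myo: MyoMask, density: float = MYOCARDIAL_DENSITY_G_PER_ML) -> float:
    """LV myocardial mass in grams from the ring masks.

    mass = pixel count x in-plane pixel area x slice thickness x density,
    with volume converted from mm^3 to mL.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    voxel_ml = myo.pixel_spacing ** 2 * myo.slice_thickness / 1000.0
    return float(myo.masks.sum()) * voxel_ml * density
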