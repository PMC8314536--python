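"""Signal-intensity thresholding primitives for LGE scar segmentation.

Two threshold families are implemented:

* **n-SD**: scar = myocardial pixels with SI strictly above
  ``mean + n * SD`` of the remote-myocardium reference ROI;
* **FWHM** (full-width half-maximum): scar = myocardial pixels at or
  above half of the maximal SI of a hyperenhanced seed region, with an
  optional remote-baseline-corrected variant.

Inequality conventions are fixed for reproducibility: strict ``>`` for
n-SD, ``>=`` for FWHM. A threshold selected on the mid-ventricular
slice is propagated to the remaining slices either by re-estimating
remote statistics per slice (default; robust to slice-wise SI scaling
of PSIR images) or by applying the absolute SI value everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _cc_label

from .contours import MyoMask, ROIRef, SegmentLabels, auto_detect_rois, lv_mass, \
    MYOCARDIAL_DENSITY_G_PER_ML

__all__ = [
    "RemoteStats",
    "ThresholdSelection",
    "ScarResult",
    "remote_stats",
    "nsd_mask",
    "fwhm_mask",
    "propagate_threshold",
    "filter_components",
    "scar_result",
]


class DegenerateThresholdError(ValueError):
    """Raised when the remote SD is zero and an n-SD threshold is undefined."""


@dataclass(frozen=True)
class RemoteStats:
    """Mean and sample SD of remote-myocardium signal intensity."""

    mean_si: float
    sd_si: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.sd_si < 0:
            raise ValueError("sd_si must be non-negative")


@dataclass(frozen=True)
class ThresholdSelection:
    """A chosen threshold: method, n (for n-SD), absolute SI value, scenario."""

    method: str  # "nsd" | "fwhm"
    n: float | None
    absolute_threshold: float
    scenario: str = "n/a"  # "scar" | "non-scar" | "n/a"


@dataclass
class ScarResult:
    """Scar masks plus derived mass and percentage summaries."""

    masks: np.ndarray  # (n_slices, H, W) bool
    scar_mass_g: float
    lv_mass_g: float
    scar_percent: float
    per_segment_percent: dict[int, float] = field(default_factory=dict)


def remote_stats(lge_slice, remote: ROIRef) -> RemoteStats:
    """Mean and sample SD (n-1 denominator) of SI over the remote ROI."""
    si = np.asarray(lge_slice, dtype=float)[remote.pixels[:, 0], remote.pixels[:, 1]]
    if si.size < 2:
        raise ValueError("remote ROI needs at least 2 pixels for an SD")
    return RemoteStats(mean_si=float(si.mean()), sd_si=float(si.std(ddof=1)),
                       n_pixels=int(si.size))


def nsd_mask(lge_slice, myo_slice_mask, stats: RemoteStats, n: float):
    """Scar mask at SI > mean + n*SD of the remote reference.

    Raises :class:`DegenerateThresholdError` when ``stats.sd_si`` is 0
    (a constant remote ROI cannot define an n-SD threshold).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if stats.sd_si <= 0:
        raise DegenerateThresholdError("remote SD is zero: n-SD threshold undefined")
    thr = stats.mean_si + n * stats.sd_si
    mask = np.asarray(myo_slice_mask, dtype=bool) & (np.asarray(lge_slice, float) > thr)
    return mask, ThresholdSelection(method="nsd", n=float(n), absolute_threshold=float(thr))


def fwhm_mask(lge_slice, myo_slice_mask, seed_roi: ROIRef,
              baseline_corrected: bool = False, remote: RemoteStats | None = None):
    """Scar mask at SI >= half the maximal seed-region SI.

    ``S_max`` is the maximum SI over the seed ROI (the hyperenhanced
    region, typically the auto-detected high-SI ROI). Default threshold
    is ``S_max / 2``; with ``baseline_corrected`` the half-height is
    taken above the remote mean: ``mu + 0.5 * (S_max - mu)``.
    """
    lge_slice = np.asarray(lge_slice, dtype=float)
    s_max = float(lge_slice[seed_roi.pixels[:, 0], seed_roi.pixels[:, 1]].max())
    if baseline_corrected:
        if remote is None:
            raise ValueError("baseline-corrected FWHM needs remote statistics")
        if s_max <= remote.mean_si:
            raise ValueError("seed maximum does not exceed the remote mean")
        thr = remote.mean_si + 0.5 * (s_max - remote.mean_si)
    else:
        thr = s_max / 2.0
    mask = np.asarray(myo_slice_mask, dtype=bool) & (lge_slice >= thr)
    return mask, ThresholdSelection(method="fwhm", n=None, absolute_threshold=float(thr))


def propagate_threshold(stack, myo: MyoMask, selection: ThresholdSelection,
                        per_slice_remote: bool = True,
                        n_sectors: int = 60, arc_width: int = 5):
    """Apply a mid-slice threshold selection to every slice of the stack.

    With ``per_slice_remote`` (default) an n-SD selection re-detects the
    remote ROI on each slice and applies the same n to that slice's
    remote statistics; otherwise (or for FWHM selections) the absolute
    SI threshold is applied unchanged. A slice whose remote ROI is
    degenerate (zero SD) falls back to the absolute threshold and is
    reported in the returned warning list.

    Returns ``(masks, warnings)``.
    """
    data = np.asarray(stack.data, dtype=float)
    masks = np.zeros_like(myo.masks)
    warns: list[str] = []
    for s in range(myo.n_slices):
        myo_s = myo.masks[s]
        if not myo_s.any():
            continue
        if selection.method == "nsd" and per_slice_remote:
            try:
                remote, _ = auto_detect_rois(data[s], myo_s, slice_index=s,
                                             n_sectors=n_sectors, arc_width=arc_width)
                stats = remote_stats(data[s], remote)
                masks[s], _ = nsd_mask(data[s], myo_s, stats, selection.n)
                continue
            except (DegenerateThresholdError, ValueError) as exc:
                warns.append(f"slice {s}: {exc}; using absolute threshold")
        if selection.method == "fwhm":
            masks[s] = myo_s & (data[s] >= selection.absolute_threshold)
        else:
            masks[s] = myo_s & (data[s] > selection.absolute_threshold)
    return masks, warns


def filter_components(masks, min_component_px: int = 5, connectivity: int = 8):
    """Remove in-slice connected components smaller than a pixel count.

    ``connectivity`` is 4 (edge neighbors) or 8 (edge+corner neighbors).
    ``min_component_px = 0`` (or 1) is the identity. The operation is
    idempotent. Serves as the automated stand-in for manual erasure of
    small acquisition artifacts.
    """
    if min_component_px < 0:
        raise ValueError("min_component_px must be non-negative")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    masks = np.asarray(masks, dtype=bool)
    if min_component_px <= 1:
        return masks.copy()
    out = np.zeros_like(masks)
    conn = 1 if connectivity == 4 else 2
    for s in range(masks.shape[0]):
        labels = _cc_label(masks[s], connectivity=conn)
        if labels.max() == 0:
            continue
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_component_px
        keep[0] = False
        out[s] = keep[labels]
    return out


def scar_result(masks, myo: MyoMask, segments: SegmentLabels | None = None,
                density: float = MYOCARDIAL_DENSITY_G_PER_ML) -> ScarResult:
    """Scar mass (g), LV mass (g), global and per-segment scar percent.

    Global percent is ``100 * scar_mass / LV_mass``; the per-segment
    percent uses pixel counts within each segment as the denominator.
    Raises ``ValueError`` if any scar pixel lies outside the myocardium.
    """
    masks = np.asarray(masks, dtype=bool)
    if np.any(masks & ~myo.masks):
        raise ValueError("scar mask contains pixels outside the myocardium")
    voxel_ml = myo.pixel_spacing ** 2 * myo.slice_thickness / 1000.0
    scar_mass = float(masks.sum()) * voxel_ml * density
    total_mass = lv_mass(myo, density)
    percent = 100.0 * scar_mass / total_mass if total_mass > 0 else 0.0
    per_segment: dict[int, float] = {}
    if segments is not None:
        labs = segments.labels
        for seg in np.unique(labs[labs > 0]):
            in_seg = labs == seg
            per_segment[int(seg)] = 100.0 * float((masks & in_seg).sum()) / float(in_seg.sum())
    return ScarResult(masks=masks, scar_mass_g=scar_mass, lv_mass_g=total_mass,
                      scar_percent=percent, per_segment_percent=per_segment)
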