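"""Extracellular volume fraction (ECV) mapping from pre/post-contrast T1.

ECV is the fraction of myocardial tissue volume occupied by the
extracellular space. It is computed pixelwise from the change in
longitudinal relaxation rate (R1 = 1/T1) of myocardium relative to the
blood pool, scaled by the plasma volume fraction of blood::

    ECV = (1 - Hct) * (dR1_myo / dR1_blood),   dR1 = 1/T1_post - 1/T1_pre

where Hct is the hematocrit. Blood T1 values enter as scalars (ROI means
supplied upstream); myocardial T1 values are per-pixel maps sharing the
grid of the mid-ventricular LGE slice. ECV is reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["T1PairAndHct", "ECVMap", "compute_ecv", "sample_at_roi"]


@dataclass
class T1PairAndHct:
    """Pre/post-contrast myocardial T1 maps plus blood T1 and hematocrit.

    Myocardial maps are 2-D float arrays in milliseconds with NaN where
    the map is undefined (outside the traced myocardium). Blood-pool T1
    values are scalars in milliseconds; hematocrit is a fraction.
    """

    t1_myo_pre: np.ndarray
    t1_myo_post: np.ndarray
    t1_blood_pre: float
    t1_blood_post: float
    hematocrit: float

    def __post_init__(self) -> None:
        self.t1_myo_pre = np.asarray(self.t1_myo_pre, dtype=float)
        self.t1_myo_post = np.asarray(self.t1_myo_post, dtype=float)
        if self.t1_myo_pre.shape != self.t1_myo_post.shape:
            raise ValueError(
                f"T1 map shapes differ: {self.t1_myo_pre.shape} vs "
                f"{self.t1_myo_post.shape}"
            )
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        if self.t1_blood_pre <= 0 or self.t1_blood_post <= 0:
            raise ValueError("blood T1 values must be positive")
        for name, arr in (("t1_myo_pre", self.t1_myo_pre),
                          ("t1_myo_post", self.t1_myo_post)):
            defined = np.isfinite(arr)
            if np.any(arr[defined] <= 0):
                raise ValueError(f"{name} contains non-positive defined values")


@dataclass
class ECVMap:
    """Per-pixel ECV in percent with a validity mask.

    ``valid_mask`` marks pixels where both T1 maps were defined.
    ``out_of_range`` flags valid pixels outside the physical [0, 100]%
    band; they are retained (clipping would bias ROI means) but flagged.
    """

    ecv: np.ndarray
    valid_mask: np.ndarray
    out_of_range: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ecv = np.asarray(self.ecv, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.ecv.shape != self.valid_mask.shape:
            raise ValueError("ecv and valid_mask shapes differ")
        if self.out_of_range is None:
            self.out_of_range = self.valid_mask & (
                (self.ecv < 0.0) | (self.ecv > 100.0)
            )


def compute_ecv(pair: T1PairAndHct) -> ECVMap:
    """Compute the pixelwise ECV map (in percent) from a T1 pair.

    Pixels where either myocardial T1 map is undefined (NaN) are
    excluded from the validity mask. Raises ``ValueError`` when the
    blood relaxation-rate change is zero (degenerate input).
    """
    d_r1_blood = 1.0 / pair.t1_blood_post - 1.0 / pair.t1_blood_pre
    if d_r1_blood == 0.0:
        raise ValueError("blood pre/post T1 are equal: dR1_blood = 0 is degenerate")
    valid = np.isfinite(pair.t1_myo_pre) & np.isfinite(pair.t1_myo_post)
    ecv = np.full(pair.t1_myo_pre.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_r1_myo = 1.0 / pair.t1_myo_post - 1.0 / pair.t1_myo_pre
    ecv[valid] = 100.0 * (1.0 - pair.hematocrit) * (d_r1_myo[valid] / d_r1_blood)
    return ECVMap(ecv=ecv, valid_mask=valid)


def sample_at_roi(map2d, roi) -> float:
    """Mean value of a 2-D map (ECV or native T1) over an ROI.

    ``map2d`` is either an :class:`ECVMap` or a plain 2-D array (native
    T1 map); ``roi`` is a :class:`~ecvlge.contours.ROIRef`. Pixels of
    the ROI falling outside the validity mask are excluded from the
    mean; an ROI with no valid pixel raises ``ValueError``.
    """
    if isinstance(map2d, ECVMap):
        values, valid = map2d.ecv, map2d.valid_mask
    else:
        values = np.asarray(map2d, dtype=float)
        valid = np.isfinite(values)
    rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
    if rows.size == 0:
        raise ValueError("empty ROI")
    ok = valid[rows, cols]
    if not np.any(ok):
        raise ValueError("ROI lies entirely outside the valid map region")
    return float(np.mean(values[rows[ok], cols[ok]]))
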