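"""Container for short-axis LGE signal-intensity stacks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LGEStack"]


@dataclass
class LGEStack:
    """A short-axis LGE volume with acquisition geometry.

    ``data`` is ``(n_slices, H, W)`` float signal intensity (PSIR images
    are signed, so negative values are legal). ``mid_index`` marks the
    mid-ventricular slice carrying the co-registered T1/ECV maps.
    """

    data: np.ndarray
    pixel_spacing: float  # mm, isotropic in-plane
    slice_thickness: float  # mm
    mid_index: int = field(default=-1)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("LGE stack must be (n_slices, H, W)")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")
        if self.mid_index == -1:
            self.mid_index = self.data.shape[0] // 2
        if not (0 <= self.mid_index < self.data.shape[0]):
            raise ValueError("mid_index out of range")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape2d(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]
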