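"""Compute an extracellular-volume (ECV) map from pre/post-contrast T1.

ECV = (1 - Hct) * (dR1_myo / dR1_blood) with dR1 = 1/T1post - 1/T1pre.
A worked scalar example, then the pixelwise round-trip on a phantom.
"""

import numpy as np

from ecvlge import (PhantomSpec, T1PairAndHct, compute_ecv, generate_phantom,
                    sample_at_roi)
from ecvlge.contours import ROIRef

# Myocardium 1200 -> 400 ms, blood 1800 -> 300 ms, hematocrit 0.40:
# dR1_myo = 1/600, dR1_blood = 1/360, ECV = 0.6 * 0.6 = 36%.
pair = T1PairAndHct(np.full((2, 2), 1200.0), np.full((2, 2), 400.0),
                    t1_blood_pre=1800.0, t1_blood_post=300.0, hematocrit=0.40)
print(f"hand example ECV: {compute_ecv(pair).ecv[0, 0]:.1f}%  (expected 36.0%)")

# Phantom round-trip: the T1 pair is built by inverting the formula, so
# recomputing ECV must reproduce the specified map to machine precision.
out = generate_phantom(PhantomSpec(mode="non-ischemic", noise_sd=0.0, seed=1))
computed = compute_ecv(out.t1pair)
v = out.ecv_true.valid_mask
err = np.nanmax(np.abs(computed.ecv[v] - out.ecv_true.ecv[v]))
print(f"phantom round-trip max |error|: {err:.2e} percentage points")

mid = out.lge.mid_index
lesion_px = np.argwhere(out.truth_masks[mid])
roi = ROIRef(mid, lesion_px, "high-SI")
print(f"mean ECV inside a lesion: {sample_at_roi(computed, roi):.1f}% "
      f"(remote myocardium: 27.1%)")
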