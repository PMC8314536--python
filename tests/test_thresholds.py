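"""n-SD / FWHM thresholding, propagation, component filtering, scar mass."""

import numpy as np
import pytest

from ecvlge import (LGEStack, MyoMask, ROIRef, RemoteStats, SegmentLabels,
                    filter_components, fwhm_mask, nsd_mask,
                    propagate_threshold, remote_stats, scar_result)
from ecvlge.thresholds import DegenerateThresholdError, ThresholdSelection


def roi(pixels, label="remote"):
    return ROIRef(slice_index=0, pixels=np.asarray(pixels), label=label)


def test_remote_stats_hand_arithmetic():
    img = np.zeros((2, 3))
    img[0] = [90.0, 100.0, 110.0]
    s = remote_stats(img, roi([(0, 0), (0, 1), (0, 2)]))
    assert s.mean_si == 100.0 and s.sd_si == pytest.approx(10.0)
    assert s.n_pixels == 3
    with pytest.raises(ValueError):
        remote_stats(img, roi([(0, 0)]))


def test_remote_stats_constant_roi_gives_zero_sd():
    img = np.full((2, 2), 42.0)
    s = remote_stats(img, roi([(0, 0), (0, 1), (1, 0)]))
    assert s.sd_si == 0.0


def test_nsd_strict_inequality():
    """Threshold mu + 5*sd = 150: SI 151 included, SI exactly 150 excluded."""
    img = np.array([[151.0, 150.0, 149.0]])
    myo = np.ones((1, 3), bool)
    mask, sel = nsd_mask(img, myo, RemoteStats(100.0, 10.0, 10), 5.0)
    assert mask.tolist() == [[True, False, False]]
    assert sel.absolute_threshold == 150.0 and sel.n == 5.0


def test_nsd_zero_n_is_above_mean():
    img = np.array([[99.0, 100.0, 101.0]])
    mask, _ = nsd_mask(img, np.ones((1, 3), bool), RemoteStats(100.0, 10.0, 10), 0.0)
    assert mask.tolist() == [[False, False, True]]


def test_nsd_degenerate_sd_errors():
    with pytest.raises(DegenerateThresholdError):
        nsd_mask(np.ones((2, 2)), np.ones((2, 2), bool),
                 RemoteStats(100.0, 0.0, 10), 3.0)


def test_nsd_monotone_in_n():
    rng = np.random.default_rng(1)
    img = rng.normal(100, 10, (32, 32))
    myo = np.zeros((32, 32), bool)
    myo[8:24, 8:24] = True
    stats = RemoteStats(100.0, 10.0, 50)
    counts = [nsd_mask(img, myo, stats, n)[0].sum() for n in np.arange(0, 4.1, 0.25)]
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_fwhm_half_maximum_and_corrected():
    img = np.array([[400.0, 200.0, 199.0, 100.0]])
    myo = np.ones((1, 4), bool)
    seed = roi([(0, 0)], "high-SI")
    mask, sel = fwhm_mask(img, myo, seed)
    assert sel.absolute_threshold == 200.0
    assert mask.tolist() == [[True, True, False, False]]  # >= semantics
    mask_c, sel_c = fwhm_mask(img, myo, seed, baseline_corrected=True,
                              remote=RemoteStats(100.0, 10.0, 10))
    assert sel_c.absolute_threshold == 250.0
    assert mask_c.tolist() == [[True, False, False, False]]


def test_fwhm_agrees_with_nsd_at_equal_threshold():
    """Coinciding absolute thresholds give identical masks off the boundary."""
    img = np.array([[240.0, 130.0, 119.9, 110.0, 121.3]])
    myo = np.ones((1, 5), bool)
    n_mask, n_sel = nsd_mask(img, myo, RemoteStats(100.0, 10.0, 10), 2.0)
    # seed pixel 240 makes S_max/2 == 120 == mu + 2 sd
    f_mask, f_sel = fwhm_mask(img, myo, roi([(0, 0)], "high-SI"))
    assert f_sel.absolute_threshold == n_sel.absolute_threshold == 120.0
    assert np.array_equal(n_mask, f_mask)  # no pixel sits exactly on 120


def stack_of(slices):
    return LGEStack(np.asarray(slices, float), pixel_spacing=1.0,
                    slice_thickness=8.0)


def ring_stack(n_slices, size=64, seed=0, lesion=False):
    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    rows, cols = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    rad = np.hypot(rows - c, cols - c)
    myo2d = (rad > 12) & (rad <= 20)
    data = np.zeros((n_slices, size, size))
    for s in range(n_slices):
        sl = np.full((size, size), 0.0)
        sl[myo2d] = 100.0
        if lesion:
            sl[myo2d & (rows < c - 14)] = 180.0
        data[s] = sl + rng.normal(0, 10, (size, size))
    myo = MyoMask(np.repeat(myo2d[None], n_slices, axis=0), 1.0, 8.0)
    return stack_of(data), myo


def test_propagate_single_slice_identity():
    stack, myo = ring_stack(1, lesion=True)
    sel = ThresholdSelection("nsd", 5.0, 150.0)
    masks, _ = propagate_threshold(stack, myo, sel, per_slice_remote=False)
    assert np.array_equal(masks[0], myo.masks[0] & (stack.data[0] > 150.0))


def test_propagate_identical_slices_identical_masks():
    stack, myo = ring_stack(1, lesion=True)
    data = np.repeat(stack.data, 4, axis=0)
    stack4 = stack_of(data)
    myo4 = MyoMask(np.repeat(myo.masks, 4, axis=0), 1.0, 8.0)
    sel = ThresholdSelection("nsd", 5.0, 150.0)
    for flag in (True, False):
        masks, _ = propagate_threshold(stack4, myo4, sel, per_slice_remote=flag)
        for s in range(1, 4):
            assert np.array_equal(masks[s], masks[0])


def test_propagate_rescaled_slice_needs_per_slice_remote():
    """Doubling one slice's SI: per-slice remote stats reproduce the
    unscaled mask, the absolute threshold does not."""
    stack, myo = ring_stack(3, lesion=True, seed=4)
    scaled = stack.data.copy()
    scaled[2] *= 2.0
    stack2 = stack_of(scaled)
    sel = ThresholdSelection("nsd", 4.0, 0.0)
    ref, _ = propagate_threshold(stack, myo, sel, per_slice_remote=True)
    adaptive, _ = propagate_threshold(stack2, myo, sel, per_slice_remote=True)
    assert np.array_equal(adaptive[2], ref[2])
    sel_abs = ThresholdSelection("nsd", 4.0, 140.0)
    absolute, _ = propagate_threshold(stack2, myo, sel_abs, per_slice_remote=False)
    assert not np.array_equal(absolute[2], ref[2])


def test_filter_components_cases():
    m = np.zeros((1, 10, 10), bool)
    m[0, 1:2, 1:4] = True  # 3-pixel component
    assert filter_components(m, min_component_px=5).sum() == 0
    assert np.array_equal(filter_components(m, min_component_px=0), m)
    two = np.zeros((1, 12, 12), bool)
    two[0, 0:2, 0:2] = True  # 4 px
    two[0, 5:10, 5:9] = True  # 20 px
    kept = filter_components(two, min_component_px=5, connectivity=8)
    assert kept.sum() == 20 and not kept[0, 0, 0]
    # diagonal pixels merge under 8- but not 4-connectivity
    diag = np.zeros((1, 6, 6), bool)
    for i in range(5):
        diag[0, i, i] = True
    assert filter_components(diag, 5, connectivity=8).sum() == 5
    assert filter_components(diag, 5, connectivity=4).sum() == 0


def test_filter_components_idempotent():
    rng = np.random.default_rng(3)
    m = rng.random((2, 30, 30)) > 0.7
    once = filter_components(m, 5)
    assert np.array_equal(filter_components(once, 5), once)


def seg_labels_for(myo):
    labels = np.zeros(myo.masks.shape, np.int16)
    h = myo.masks.shape[1] // 2
    labels[:, :h][myo.masks[:, :h]] = 1
    labels[:, h:][myo.masks[:, h:]] = 2
    return SegmentLabels(labels=labels, rv_insertion_angle=0.0)


def test_scar_result_arithmetic():
    """10 of 100 myo px (1x1x10 mm, 1.05 g/mL): 0.105 g scar, 10%."""
    myo_masks = np.zeros((1, 20, 20), bool)
    myo_masks[0, :10, :10] = True
    myo = MyoMask(myo_masks, 1.0, 10.0)
    scar = np.zeros_like(myo_masks)
    scar[0, 0, :10] = True
    res = scar_result(scar, myo, seg_labels_for(myo))
    assert res.scar_mass_g == pytest.approx(0.105)
    assert res.lv_mass_g == pytest.approx(1.05)
    assert res.scar_percent == pytest.approx(10.0)
    assert res.per_segment_percent[1] == pytest.approx(100 * 10 / 100)
    assert res.per_segment_percent.get(2, 0.0) == 0.0


def test_scar_result_empty_and_validation():
    myo_masks = np.zeros((1, 8, 8), bool)
    myo_masks[0, 2:6, 2:6] = True
    myo = MyoMask(myo_masks, 1.0, 8.0)
    res = scar_result(np.zeros_like(myo_masks), myo)
    assert res.scar_mass_g == 0.0 and res.scar_percent == 0.0
    bad = np.zeros_like(myo_masks)
    bad[0, 0, 0] = True
    with pytest.raises(ValueError):
        scar_result(bad, myo)
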