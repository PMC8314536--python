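"""Synthetic short-axis LGE/ECV phantoms with ground-truth scar masks.

The phantom emulates the image structure this analysis runs on, without
any real anatomy: a ring-shaped myocardium (annulus between concentric
endo- and epicardial circles) over a stack of short-axis slices, a
bright blood pool, and hyperenhanced lesions of two kinds:

* ``non-ischemic`` — several small, compact, low-contrast patches
  confined to the mid-wall/epicardial half of the ring (diffuse patchy
  fibrosis pattern);
* ``ischemic`` — one contiguous subendocardial wedge of high contrast
  (dense focal infarct pattern);
* ``clean`` — no lesion.

Signal intensity is piecewise constant (remote myocardium at
``remote_si_mean``, each lesion at ``remote_si_mean + k * remote_si_sd``)
plus additive Gaussian noise of SD ``noise_sd`` (defaulting to
``remote_si_sd``, so remote pixels are Normal(mean, sd^2)). The
mid-ventricular slice carries a co-registered pre/post-contrast T1 map
pair constructed by inverting the ECV formula pixelwise, so that ECV
computation reproduces the specified ECV values exactly: the remote ECV
default of 27.1% and lesion ECV draws around 34% (non-ischemic, kept
above the 31.5% scar cutoff) or around 52% (ischemic) follow the values
observed in vivo for these lesion types.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import nibabel as nib

from .contours import MyoMask, masks_from_contours
from .ecv import ECVMap, T1PairAndHct
from .stack import LGEStack

__all__ = ["PhantomSpec", "PhantomOutput", "generate_phantom",
           "write_phantom", "read_phantom"]

_CIRCLE_VERTICES = 96


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic short-axis phantom.

    Defaults describe a patchy non-ischemic case: 8 slices of a
    128x128 grid at 1 mm in-plane / 8 mm slice thickness, a 20-30 mm
    myocardial ring, 6 lesion patches totalling 5% of the myocardium.
    ``patch_contrast_k`` (SD multiples above remote) and
    ``scar_ecv_pct`` may be a scalar, a per-patch sequence, or None for
    a seeded draw (one k per case from U(3,18) patchy / U(8,18)
    ischemic; per-patch ECV from U(27.4, 40.6) truncated above the scar
    cutoff, or N(52.2, 3.9) for the ischemic wedge).
    """

    n_slices: int = 8
    image_size: int = 128
    pixel_spacing: float = 1.0
    slice_thickness: float = 8.0
    endo_radius: float = 20.0
    epi_radius: float = 30.0
    mode: str = "non-ischemic"  # "non-ischemic" | "ischemic" | "clean"
    n_patches: int = 6
    patch_contrast_k: float | Sequence[float] | None = None
    target_scar_fraction: float | None = None
    remote_si_mean: float = 25.0
    remote_si_sd: float = 8.0
    remote_ecv_pct: float = 27.1
    scar_ecv_pct: float | Sequence[float] | None = None
    hematocrit: float = 0.42
    noise_sd: float | None = None
    t1_myo_pre_ms: float = 1300.0
    t1_blood_pre_ms: float = 1900.0
    t1_blood_post_ms: float = 350.0
    ecv_cutoff_pct: float = 31.5
    explicit_patches: tuple | None = None
    seed: int = 0

    def resolved_target_fraction(self) -> float:
        if self.mode == "clean":
            return 0.0
        if self.target_scar_fraction is None:
            return 0.05 if self.mode == "non-ischemic" else 0.25
        return self.target_scar_fraction

    def resolved_noise_sd(self) -> float:
        return self.remote_si_sd if self.noise_sd is None else self.noise_sd

    def validate(self) -> None:
        if self.mode not in ("non-ischemic", "ischemic", "clean"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.endo_radius < self.epi_radius):
            raise ValueError("need 0 < endo_radius < epi_radius")
        if self.epi_radius / self.pixel_spacing >= self.image_size / 2 - 1:
            raise ValueError("epicardial circle does not fit inside the image")
        f = self.resolved_target_fraction()
        if not (0.0 <= f <= 1.0):
            raise ValueError("target_scar_fraction must be in [0, 1]")
        if self.remote_si_sd <= 0:
            raise ValueError("remote_si_sd must be positive")
        if not (0 < self.hematocrit < 1):
            raise ValueError("hematocrit must be in (0, 1)")
        if self.resolved_noise_sd() < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_slices < 1 or self.image_size < 8:
            raise ValueError("need at least 1 slice and an 8-pixel image")
        if self.mode != "clean" and self.explicit_patches is None \
                and f > 0 and self.n_patches < 1:
            raise ValueError("lesions requested but n_patches < 1")


@dataclass
class PhantomOutput:
    """Everything a downstream analysis needs, plus the ground truth."""

    lge: LGEStack
    contours: list  # per-slice {"epi": [[x, y], ...], "endo": ...}
    myo: MyoMask
    t1pair: T1PairAndHct
    ecv_true: ECVMap
    truth_masks: np.ndarray  # (n_slices, H, W) bool
    truth_scar_percent: float
    patch_table: list  # per-patch {"slice", "k", "ecv_pct", "n_pixels"}
    spec_echo: PhantomSpec


def _circle_polygon(center_px: float, radius_px: float) -> list:
    t = np.linspace(0.0, 2.0 * np.pi, _CIRCLE_VERTICES, endpoint=False)
    x = center_px + radius_px * np.cos(t)
    y = center_px + radius_px * np.sin(t)
    return np.column_stack([x, y]).tolist()


def _patch_slice_order(n_slices: int, mid: int) -> list[int]:
    """Mid slice first, then alternating outward; repeats cyclically."""
    order = [mid]
    for d in range(1, n_slices):
        if mid + d < n_slices:
            order.append(mid + d)
        if mid - d >= 0:
            order.append(mid - d)
    return order


def _as_sequence(value, n: int, name: str) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    seq = [float(v) for v in value]
    if len(seq) != n:
        raise ValueError(f"{name} sequence length {len(seq)} != n_patches {n}")
    return seq


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate a phantom; byte-identical output for identical spec+seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    c = (size - 1) / 2.0
    endo_px = spec.endo_radius / spec.pixel_spacing
    epi_px = spec.epi_radius / spec.pixel_spacing

    contours = [{"epi": _circle_polygon(c, epi_px), "endo": _circle_polygon(c, endo_px)}
                for _ in range(spec.n_slices)]
    myo = masks_from_contours(contours, (size, size), spec.pixel_spacing,
                              spec.slice_thickness)
    rows, cols = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    radius = np.hypot(rows - c, cols - c)
    angle = np.degrees(np.arctan2(cols - c, -(rows - c))) % 360.0  # cw from up
    blood = radius < endo_px
    mid = spec.n_slices // 2

    patches = _place_patches(spec, rng, myo, radius, angle, mid, endo_px, epi_px)

    truth = np.zeros(myo.masks.shape, dtype=bool)
    for p in patches:
        if p["ecv_pct"] >= spec.ecv_cutoff_pct:
            truth[p["slice"]][p["pixel_index"]] = True

    # --- signal intensity -------------------------------------------------
    base = np.zeros((spec.n_slices, size, size))
    for s in range(spec.n_slices):
        sl = base[s]
        sl[myo.masks[s]] = spec.remote_si_mean
        sl[blood] = spec.remote_si_mean + 12.0 * spec.remote_si_sd
    for p in patches:
        base[p["slice"]][p["pixel_index"]] = (
            spec.remote_si_mean + p["k"] * spec.remote_si_sd)
    noise_sd = spec.resolved_noise_sd()
    data = base if noise_sd == 0 else base + rng.normal(0.0, noise_sd, base.shape)
    lge = LGEStack(data=data, pixel_spacing=spec.pixel_spacing,
                   slice_thickness=spec.slice_thickness, mid_index=mid)

    # --- mid-slice ECV and the T1 pair that inverts to it ------------------
    ecv_pct = np.full((size, size), np.nan)
    ecv_pct[myo.masks[mid]] = spec.remote_ecv_pct
    for p in patches:
        if p["slice"] == mid:
            ecv_pct[p["pixel_index"]] = p["ecv_pct"]
    t1pair = _t1_pair_from_ecv(spec, ecv_pct)
    ecv_true = ECVMap(ecv=ecv_pct, valid_mask=np.isfinite(ecv_pct))

    total_myo = int(myo.masks.sum())
    truth_percent = 100.0 * float(truth.sum()) / total_myo if total_myo else 0.0
    table = [{k: p[k] for k in ("slice", "k", "ecv_pct", "n_pixels")}
             for p in patches]
    return PhantomOutput(lge=lge, contours=contours, myo=myo, t1pair=t1pair,
                         ecv_true=ecv_true, truth_masks=truth,
                         truth_scar_percent=truth_percent, patch_table=table,
                         spec_echo=spec)


def _place_patches(spec, rng, myo, radius, angle, mid, endo_px, epi_px):
    """Select lesion pixel sets. Returns dicts with slice/k/ecv/pixel_index."""
    if spec.mode == "clean":
        return []
    if spec.explicit_patches is not None:
        return [_explicit_patch(spec, p, myo, radius, angle, endo_px, epi_px)
                for p in spec.explicit_patches]

    total_myo = int(myo.masks.sum())
    n_target = int(round(spec.resolved_target_fraction() * total_myo))
    if n_target == 0:
        return []

    if spec.mode == "non-ischemic":
        n_patches = spec.n_patches
        k_default = float(rng.uniform(3.0, 18.0))
        ks = _as_sequence(spec.patch_contrast_k if spec.patch_contrast_k is not None
                          else k_default, n_patches, "patch_contrast_k")
        lo = max(spec.ecv_cutoff_pct, 34.0 - 6.6)
        ecvs = (_as_sequence(spec.scar_ecv_pct, n_patches, "scar_ecv_pct")
                if spec.scar_ecv_pct is not None
                else [float(rng.uniform(lo, 34.0 + 6.6)) for _ in range(n_patches)])
        quota = [n_target // n_patches] * n_patches
        for i in range(n_target % n_patches):
            quota[i] += 1
        slice_order = _patch_slice_order(spec.n_slices, mid)
        taken = np.zeros(myo.masks.shape, dtype=bool)
        mid_wall = (endo_px + epi_px) / 2.0
        patches = []
        for i in range(n_patches):
            if quota[i] == 0:
                continue
            s = slice_order[i % len(slice_order)]
            theta = float(rng.uniform(0.0, 360.0))
            rho = float(rng.uniform(mid_wall, epi_px))
            avail = myo.masks[s] & (radius >= mid_wall) & ~taken[s]
            ar, ac = np.nonzero(avail)
            if ar.size < quota[i]:
                raise ValueError(
                    "target_scar_fraction unreachable with the given geometry "
                    f"(slice {s}: {ar.size} available < {quota[i]} requested)")
            cy = (spec.image_size - 1) / 2.0 - rho * np.cos(np.radians(theta))
            cx = (spec.image_size - 1) / 2.0 + rho * np.sin(np.radians(theta))
            d = np.hypot(ar - cy, ac - cx)
            pick = np.argsort(d, kind="stable")[: quota[i]]
            idx = (ar[pick], ac[pick])
            taken[s][idx] = True
            patches.append({"slice": s, "k": ks[i], "ecv_pct": ecvs[i],
                            "n_pixels": int(quota[i]), "pixel_index": idx})
        return patches

    # ischemic: one contiguous subendocardial wedge spanning all slices
    k = float(spec.patch_contrast_k) if np.isscalar(spec.patch_contrast_k) \
        else float(rng.uniform(8.0, 18.0))
    ecv = (float(spec.scar_ecv_pct) if np.isscalar(spec.scar_ecv_pct)
           else float(np.clip(rng.normal(52.2, 3.9), spec.ecv_cutoff_pct, None)))
    depth = endo_px + 0.75 * (epi_px - endo_px)
    theta0 = float(rng.uniform(0.0, 360.0))
    band_counts = [int((myo.masks[s] & (radius <= depth)).sum())
                   for s in range(spec.n_slices)]
    total_band = sum(band_counts)
    if total_band < n_target:
        raise ValueError("target_scar_fraction unreachable: subendocardial band too small")
    patches = []
    remaining = n_target
    for s in range(spec.n_slices):
        quota_s = min(band_counts[s],
                      int(round(n_target * band_counts[s] / total_band)))
        if s == spec.n_slices - 1:
            quota_s = min(band_counts[s], remaining)
        quota_s = min(quota_s, remaining)
        remaining -= quota_s
        if quota_s == 0:
            continue
        br, bc = np.nonzero(myo.masks[s] & (radius <= depth))
        dang = np.abs((angle[br, bc] - theta0 + 180.0) % 360.0 - 180.0)
        pick = np.argsort(dang, kind="stable")[:quota_s]
        idx = (br[pick], bc[pick])
        patches.append({"slice": s, "k": k, "ecv_pct": ecv,
                        "n_pixels": int(quota_s), "pixel_index": idx})
    return patches


def _explicit_patch(spec, p, myo, radius, angle, endo_px, epi_px):
    """Build one patch from an explicit description (constructed scenarios).

    ``p`` maps: slice, angle_deg, n_pixels, k, ecv_pct, and optionally
    depth ("outer" mid-wall/epicardial half, default, or "inner"
    subendocardial band).
    """
    s = int(p["slice"])
    mid_wall = (endo_px + epi_px) / 2.0
    if p.get("depth", "outer") == "inner":
        avail = myo.masks[s] & (radius <= endo_px + 0.75 * (epi_px - endo_px))
        rho = (endo_px + mid_wall) / 2.0
    else:
        avail = myo.masks[s] & (radius >= mid_wall)
        rho = (mid_wall + epi_px) / 2.0
    ar, ac = np.nonzero(avail)
    n_px = int(p["n_pixels"])
    if ar.size < n_px:
        raise ValueError(f"explicit patch on slice {s} does not fit ({ar.size} < {n_px})")
    c = (spec.image_size - 1) / 2.0
    theta = float(p["angle_deg"])
    cy = c - rho * np.cos(np.radians(theta))
    cx = c + rho * np.sin(np.radians(theta))
    d = np.hypot(ar - cy, ac - cx)
    pick = np.argsort(d, kind="stable")[:n_px]
    idx = (ar[pick], ac[pick])
    return {"slice": s, "k": float(p["k"]), "ecv_pct": float(p["ecv_pct"]),
            "n_pixels": n_px, "pixel_index": idx}


def _t1_pair_from_ecv(spec: PhantomSpec, ecv_pct: np.ndarray) -> T1PairAndHct:
    """Invert the ECV formula for post-contrast myocardial T1 per pixel."""
    d_r1_blood = 1.0 / spec.t1_blood_post_ms - 1.0 / spec.t1_blood_pre_ms
    t1_pre = np.where(np.isfinite(ecv_pct), spec.t1_myo_pre_ms, np.nan)
    d_r1_myo = (ecv_pct / 100.0) * d_r1_blood / (1.0 - spec.hematocrit)
    with np.errstate(invalid="ignore"):
        t1_post = 1.0 / (1.0 / t1_pre + d_r1_myo)
    return T1PairAndHct(t1_myo_pre=t1_pre, t1_myo_post=t1_post,
                        t1_blood_pre=spec.t1_blood_pre_ms,
                        t1_blood_post=spec.t1_blood_post_ms,
                        hematocrit=spec.hematocrit)


def _nifti(arr3d: np.ndarray, spec_like) -> nib.Nifti1Image:
    affine = np.diag([spec_like.pixel_spacing, spec_like.pixel_spacing,
                      spec_like.slice_thickness, 1.0])
    return nib.Nifti1Image(np.ascontiguousarray(arr3d.transpose(2, 1, 0)), affine)


def write_phantom(out: PhantomOutput, directory) -> dict:
    """Write a phantom to disk; returns the file map.

    Volumes (LGE, T1 pre/post, ECV, truth and myocardium masks) go to
    NIfTI; contours and the spec echo (plus blood T1 / hematocrit /
    truth summary) to JSON. Float volumes are stored at full precision
    so the round-trip through :func:`read_phantom` is bitwise lossless.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = out.spec_echo
    size = spec.image_size

    def vol(path, arr, dtype):
        img = _nifti(np.asarray(arr, dtype=dtype), spec)
        nib.save(img, str(path))
        return path

    files = {
        "lge": vol(directory / "lge.nii.gz", out.lge.data, np.float64),
        "t1_pre": vol(directory / "t1_pre.nii.gz",
                      out.t1pair.t1_myo_pre.reshape(1, size, size), np.float64),
        "t1_post": vol(directory / "t1_post.nii.gz",
                       out.t1pair.t1_myo_post.reshape(1, size, size), np.float64),
        "ecv": vol(directory / "ecv.nii.gz",
                   out.ecv_true.ecv.reshape(1, size, size), np.float64),
        "truth": vol(directory / "truth_masks.nii.gz", out.truth_masks, np.uint8),
        "myo": vol(directory / "myo_masks.nii.gz", out.myo.masks, np.uint8),
    }
    meta = {
        "spec": dataclasses.asdict(spec),
        "t1_blood_pre_ms": out.t1pair.t1_blood_pre,
        "t1_blood_post_ms": out.t1pair.t1_blood_post,
        "hematocrit": out.t1pair.hematocrit,
        "mid_index": out.lge.mid_index,
        "truth_scar_percent": out.truth_scar_percent,
        "patch_table": out.patch_table,
    }
    (directory / "contours.json").write_text(json.dumps(out.contours))
    (directory / "spec.json").write_text(json.dumps(meta, indent=2))
    files["contours"] = directory / "contours.json"
    files["spec"] = directory / "spec.json"
    return files


def read_phantom(directory) -> PhantomOutput:
    """Read back a phantom written by :func:`write_phantom`."""
    directory = Path(directory)
    meta = json.loads((directory / "spec.json").read_text())
    raw_spec = dict(meta["spec"])
    if raw_spec.get("explicit_patches") is not None:
        raw_spec["explicit_patches"] = tuple(raw_spec["explicit_patches"])
    if isinstance(raw_spec.get("patch_contrast_k"), list):
        raw_spec["patch_contrast_k"] = tuple(raw_spec["patch_contrast_k"])
    if isinstance(raw_spec.get("scar_ecv_pct"), list):
        raw_spec["scar_ecv_pct"] = tuple(raw_spec["scar_ecv_pct"])
    spec = PhantomSpec(**raw_spec)
    contours = json.loads((directory / "contours.json").read_text())

    def vol(name):
        img = nib.load(str(directory / name))
        return np.asarray(img.dataobj).transpose(2, 1, 0)

    lge = LGEStack(data=vol("lge.nii.gz"), pixel_spacing=spec.pixel_spacing,
                   slice_thickness=spec.slice_thickness,
                   mid_index=int(meta["mid_index"]))
    t1_pre = vol("t1_pre.nii.gz")[0]
    t1_post = vol("t1_post.nii.gz")[0]
    t1pair = T1PairAndHct(t1_myo_pre=t1_pre, t1_myo_post=t1_post,
                          t1_blood_pre=meta["t1_blood_pre_ms"],
                          t1_blood_post=meta["t1_blood_post_ms"],
                          hematocrit=meta["hematocrit"])
    ecv = vol("ecv.nii.gz")[0]
    truth = vol("truth_masks.nii.gz").astype(bool)
    myo = MyoMask(masks=vol("myo_masks.nii.gz").astype(bool),
                  pixel_spacing=spec.pixel_spacing,
                  slice_thickness=spec.slice_thickness)
    return PhantomOutput(lge=lge, contours=contours, myo=myo, t1pair=t1pair,
                         ecv_true=ECVMap(ecv=ecv, valid_mask=np.isfinite(ecv)),
                         truth_masks=truth,
                         truth_scar_percent=float(meta["truth_scar_percent"]),
                         patch_table=meta["patch_table"], spec_echo=spec)
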