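"""End-to-end orchestration: file-based runs and phantom benchmarks."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

from . import __version__
from .contours import MyoMask, aha17_segments, auto_detect_rois, masks_from_contours
from .ecv import ECVMap, T1PairAndHct, compute_ecv
from .guided import ECVGuidedConfig, ECVGuidedReport, run_ecv_guided
from .phantom import PhantomOutput, PhantomSpec, generate_phantom
from .stack import LGEStack
from .stats import AgreementResult, agreement
from .thresholds import (ScarResult, filter_components, fwhm_mask, nsd_mask,
                         propagate_threshold, remote_stats, scar_result)

__all__ = ["RunConfig", "run_pipeline", "benchmark_population",
           "fixed_nsd_analysis", "fwhm_analysis", "guided_analysis"]


@dataclass
class RunConfig:
    """Configuration of a file-based analysis run."""

    lge_path: str
    contours_path: str
    out_dir: str
    method: str = "ecv-guided"  # "ecv-guided" | "nsd" | "fwhm"
    n: float | None = None  # fixed n for method="nsd"
    ecv_path: str | None = None
    t1_pre_path: str | None = None
    t1_post_path: str | None = None
    blood_json_path: str | None = None  # blood T1 scalars + hematocrit
    pixel_spacing: float = 1.0
    slice_thickness: float = 8.0
    mid_index: int | None = None
    seed: int = 0
    guided: ECVGuidedConfig = field(default_factory=ECVGuidedConfig)

    def required_paths(self) -> list[str]:
        paths = [self.lge_path, self.contours_path]
        if self.method == "ecv-guided":
            if self.ecv_path is not None:
                paths.append(self.ecv_path)
            else:
                paths += [p for p in (self.t1_pre_path, self.t1_post_path,
                                      self.blood_json_path) if p is not None]
        return paths


def _load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).transpose(2, 1, 0)


def fixed_nsd_analysis(stack: LGEStack, myo: MyoMask, n: float,
                       config: ECVGuidedConfig | None = None) -> ScarResult:
    """Comparator: fixed n-SD threshold from the mid-slice remote ROI."""
    config = config or ECVGuidedConfig()
    mid = stack.mid_index
    remote, _ = auto_detect_rois(stack.data[mid], myo.masks[mid], slice_index=mid,
                                 n_sectors=config.n_sectors, arc_width=config.arc_width)
    stats = remote_stats(stack.data[mid], remote)
    _, selection = nsd_mask(stack.data[mid], myo.masks[mid], stats, n)
    masks, _ = propagate_threshold(stack, myo, selection,
                                   per_slice_remote=config.per_slice_remote,
                                   n_sectors=config.n_sectors,
                                   arc_width=config.arc_width)
    masks = filter_components(masks, config.min_component_px, config.connectivity)
    segments = aha17_segments(myo, config.rv_insertion_angle) if myo.n_slices >= 3 else None
    return scar_result(masks, myo, segments, density=config.density)


def fwhm_analysis(stack: LGEStack, myo: MyoMask,
                  config: ECVGuidedConfig | None = None,
                  baseline_corrected: bool = False) -> ScarResult:
    """Comparator: FWHM threshold seeded at the mid-slice high-SI ROI."""
    config = config or ECVGuidedConfig()
    mid = stack.mid_index
    remote, highsi = auto_detect_rois(stack.data[mid], myo.masks[mid],
                                      slice_index=mid, n_sectors=config.n_sectors,
                                      arc_width=config.arc_width,
                                      highsi_px=config.highsi_px)
    stats = remote_stats(stack.data[mid], remote)
    _, selection = fwhm_mask(stack.data[mid], myo.masks[mid], highsi,
                             baseline_corrected=baseline_corrected, remote=stats)
    masks, _ = propagate_threshold(stack, myo, selection, per_slice_remote=False)
    masks = filter_components(masks, config.min_component_px, config.connectivity)
    segments = aha17_segments(myo, config.rv_insertion_angle) if myo.n_slices >= 3 else None
    return scar_result(masks, myo, segments, density=config.density)


def guided_analysis(out: PhantomOutput,
                    config: ECVGuidedConfig | None = None) -> ECVGuidedReport:
    """ECV-guided analysis of a phantom, using its T1 pair for the ECV map."""
    return run_ecv_guided(out.lge, out.contours, out.t1pair, config, myo=out.myo)


def run_pipeline(config: RunConfig) -> dict:
    """Run one file-based analysis and write report files.

    Pre-flight checks every referenced input path and fails listing all
    missing ones. Outputs (under ``config.out_dir``): ``report.json``
    with the scenario/threshold/scar summary plus a config echo and the
    package version, ``scar_masks.nii.gz``, and ``segments.csv``.
    """
    missing = [p for p in config.required_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError("missing input files: " + ", ".join(map(str, missing)))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    data = _load_volume(config.lge_path)
    stack = LGEStack(data=data, pixel_spacing=config.pixel_spacing,
                     slice_thickness=config.slice_thickness,
                     mid_index=(config.mid_index if config.mid_index is not None else -1))
    contours = json.loads(Path(config.contours_path).read_text())
    myo = masks_from_contours(contours, stack.shape2d, stack.pixel_spacing,
                              stack.slice_thickness)

    report: dict = {"method": config.method, "seed": config.seed,
                    "version": __version__,
                    "config": _config_echo(config)}
    if config.method == "ecv-guided":
        if config.ecv_path is not None:
            ecv_arr = _load_volume(config.ecv_path)[0]
            ecv = ECVMap(ecv=ecv_arr, valid_mask=np.isfinite(ecv_arr))
        elif config.t1_pre_path and config.t1_post_path and config.blood_json_path:
            blood = json.loads(Path(config.blood_json_path).read_text())
            pair = T1PairAndHct(t1_myo_pre=_load_volume(config.t1_pre_path)[0],
                                t1_myo_post=_load_volume(config.t1_post_path)[0],
                                t1_blood_pre=blood["t1_blood_pre_ms"],
                                t1_blood_post=blood["t1_blood_post_ms"],
                                hematocrit=blood["hematocrit"])
            ecv = compute_ecv(pair)
        else:
            raise ValueError("ecv-guided needs --ecv or a T1 pair with blood JSON")
        rep = run_ecv_guided(stack, contours, ecv, config.guided, myo=myo)
        scar = rep.scar
        report.update(roi_ecv=rep.roi_ecv, scenario=rep.scenario,
                      selected_n=rep.selected_n, mid_slice_dice=rep.mid_slice_dice,
                      warnings=rep.warnings)
    elif config.method == "nsd":
        if config.n is None:
            raise ValueError("method 'nsd' needs an explicit n")
        scar = fixed_nsd_analysis(stack, myo, config.n, config.guided)
        report["n"] = config.n
    elif config.method == "fwhm":
        scar = fwhm_analysis(stack, myo, config.guided)
    else:
        raise ValueError(f"unknown method {config.method!r}")

    report.update(scar_mass_g=scar.scar_mass_g, lv_mass_g=scar.lv_mass_g,
                  scar_percent=scar.scar_percent,
                  per_segment_percent={str(k): v for k, v in
                                       scar.per_segment_percent.items()})
    affine = np.diag([stack.pixel_spacing, stack.pixel_spacing,
                      stack.slice_thickness, 1.0])
    nib.save(nib.Nifti1Image(scar.masks.astype(np.uint8).transpose(2, 1, 0), affine),
             str(out_dir / "scar_masks.nii.gz"))
    pd.DataFrame(
        [{"segment": k, "scar_percent": v}
         for k, v in sorted(scar.per_segment_percent.items())]
        + [{"segment": "global", "scar_percent": scar.scar_percent}]
    ).to_csv(out_dir / "segments.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["guided"]["n_grid"] = list(echo["guided"]["n_grid"])
    return echo


def _phantom_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def benchmark_population(pop_specs, methods, seed: int = 0,
                         config: ECVGuidedConfig | None = None) -> dict:
    """Compare scar-quantification methods across a phantom population.

    ``pop_specs`` is a sequence of :class:`PhantomSpec` (their ``seed``
    fields are replaced by values derived from ``seed``). ``methods``
    are names among ``"ecv-guided"``, ``"nsd:<n>"`` (e.g. ``"nsd:2"``),
    ``"fwhm"``, ``"truth"``. Returns per-method scar percentages and
    pairwise CCC / Bland-Altman agreement.
    """
    if len(pop_specs) < 2:
        raise ValueError("a population benchmark needs at least 2 phantoms")
    config = config or ECVGuidedConfig()
    per_method: dict[str, list[float]] = {m: [] for m in methods}
    for i, spec in enumerate(pop_specs):
        spec_i = dataclasses.replace(spec, seed=_phantom_seed(seed, i))
        try:
            out = generate_phantom(spec_i)
            for m in methods:
                per_method[m].append(_run_method(m, out, config))
        except Exception as exc:
            raise RuntimeError(f"phantom {i} failed: {exc}") from exc
    pairwise: dict[str, AgreementResult] = {}
    names = list(methods)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            pairwise[f"{names[a]}|{names[b]}"] = agreement(
                per_method[names[a]], per_method[names[b]])
    return {"seed": seed, "scar_percent": per_method, "pairwise": pairwise}


def _run_method(name: str, out: PhantomOutput, config: ECVGuidedConfig) -> float:
    if name == "truth":
        return out.truth_scar_percent
    if name == "ecv-guided":
        return guided_analysis(out, config).scar.scar_percent
    if name == "fwhm":
        return fwhm_analysis(out.lge, out.myo, config).scar_percent
    if name.startswith("nsd:"):
        return fixed_nsd_analysis(out.lge, out.myo, float(name[4:]),
                                  config).scar_percent
    raise ValueError(f"unknown method {name!r}")
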