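# ecvlge — ECV-guided LGE scar quantification for cardiac MRI

Quantifying myocardial scar on late gadolinium enhancement (LGE) images
is hard in non-ischemic disease: fibrosis is diffuse and patchy, its
contrast is low, and fixed signal-intensity thresholds (2-SD, 6-SD,
FWHM) that work well for dense ischemic infarcts either drown the
lesion in noise or miss it entirely. Manual delineation, the usual
fallback, tends to overestimate scar and reproduces poorly.

`ecvlge` implements an **ECV-guided** analysis that uses the
co-registered mid-ventricular extracellular-volume (ECV) map as an
arbiter for the LGE threshold choice, together with the conventional
comparators and everything needed to exercise them without patient
data. It is a library for cardiac-MRI image analysts and methods
researchers, with a thin `ecvlge` command-line wrapper.

## The method

Per pixel, the ECV fraction is computed from pre/post-contrast T1 of
myocardium and blood pool and the hematocrit Hct:

    ECV = (1 − Hct) · (ΔR1_myo / ΔR1_blood),   ΔR1 = 1/T1_post − 1/T1_pre

The ECV-guided analysis of one case then proceeds on the mid-LV slice
(the slice carrying the T1 maps):

1. auto-detect the **remote** (minimal-SI) and **high-SI** (maximal-SI)
   regions of the myocardial ring on the LGE image;
2. sample the ECV map at the high-SI region and apply the decision
   rule: ECV ≥ 31.5 % ⇒ the bright area is **scar**; ECV < 31.5 % ⇒
   **non-scar** (artifact, partial volume, …);
3. *scar*: select the n-SD threshold (scar = SI > μ_remote + n·σ_remote)
   whose mask best matches the ECV-defined scar region (Dice overlap,
   ties toward larger n); *non-scar*: select the smallest n that no
   longer highlights the high-SI region;
4. propagate the selected n to all slices (re-estimating remote
   statistics per slice), remove small components, and report scar
   mass (g), global scar (%), and AHA 17-segment involvement.

The per-case n adapts to lesion contrast (values from ~3 to ~18 SD are
expected), which is exactly what fixed-threshold methods cannot do.

## Worked example

Every analysis stage runs on built-in synthetic phantoms (ring-shaped
myocardium, patchy or wedge lesions, co-registered T1/ECV maps, known
ground truth), so the whole pipeline is testable offline:

```python
from ecvlge import PhantomSpec, generate_phantom, guided_analysis

out = generate_phantom(PhantomSpec(mode="non-ischemic",
                                   patch_contrast_k=8.0, seed=11))
rep = guided_analysis(out)
```

which prints (see `examples/04_ecv_guided.py`):

```
high-SI ROI ECV: 36.0%  ->  scenario: scar
selected threshold: 6.5 SD (absolute SI 70.9)
mid-slice Dice vs the ECV-defined scar region: 1.000
scar mass: 4.87 g of 105.1 g LV
global scar: 4.64%  (ground truth 5.00%)
```

The bright mid-slice region has ECV 36.0 %, above the 31.5 % cutoff, so
it is accepted as scar; the optimizer picks 6.5 SD for this k = 8
lesion contrast, and the propagated segmentation recovers the simulated
5 % scar burden within 0.4 percentage points. The `examples/` scripts
walk through each capability the same way (phantom generation, ECV
mapping, n-SD/FWHM thresholding, population benchmarks, diagnostic
statistics).

## Command line

```bash
ecvlge simulate --out case/ --seed 3
ecvlge quantify --lge case/lge.nii.gz --contours case/contours.json \
                --ecv case/ecv.nii.gz --out result/
ecvlge stats diag --n-positive 50 --n-negative 30 \
                  --sensitivity 0.68 --specificity 0.70
```

See `docs/methods.md` for the model assumptions, parameter defaults,
and the phantom's known simplifications.
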