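# liverdwi

Correction of cardiac-pulsation signal loss in multi-repetition
diffusion-weighted MRI (DWI) of the liver.

Free-breathing liver DWI acquires each slice many times (several repetitions
of several diffusion directions, typically N = 12 images at b = 800 s/mm²).
The beating heart dephases spins in nearby tissue, randomly destroying signal
— predominantly in the **left liver lobe** — in a subset of those images.
Plain averaging then leaves a dark left lobe where lesions can disappear;
naive "keep the bright pixels" corrections fill the dropouts but also
brighten vessels, which then mimic lesions. This package implements, end to
end, a framework for navigating that trade-off, aimed at MR-physics and
image-analysis researchers:

* **`liverdwi.qscore`** — a four-feature, ROI-based quality score.
  For an image $I$ with left-lobe ROI $R_1$, right-lobe ROI $R_2$, vessel,
  lesion and background-parenchyma ROIs:

  $$\mathrm{PA} = \frac{\langle I\rangle_{R_1}}{\langle I\rangle_{R_2}},\qquad
  \mathrm{VD} = \frac{\langle I\rangle_{\mathrm{bg}}}{\langle I\rangle_{\mathrm{vessel}}},\qquad
  \mathrm{CNR} = \frac{\langle I\rangle_{\mathrm{lesion}}-\langle I\rangle_{\mathrm{bg}}}{\sigma_{\mathrm{bg}}},\qquad
  \mathrm{DC} = \Big(1-\tfrac{\langle|I-I_{\mathrm{ref}}|\rangle_{R_2}}{\langle I_{\mathrm{ref}}\rangle_{R_2}}\Big)_{+}$$

  Higher is better for all four. Each score is normalized to the value of
  the unprocessed trace-weighted reference image $I_\mathrm{ref}$
  (geometric mean over directions, arithmetic mean over repetitions), and
  their mean is the total quality score $Q_\mathrm{total}$; values above 1
  mean the processing improved the image.

* **`liverdwi.combine`** — five conventional repetition-combination
  algorithms (weighted averaging, p-mean, percentile, iterative outlier
  exclusion, exception set) plus an exhaustive parameter search maximizing
  $Q_\mathrm{total}$. The outlier-exclusion optimum k = 10, ks2 = 21,
  thr = 0.3 is the default.

* **`liverdwi.floss` / `liverdwi.nettrain` / `liverdwi.unet`** — a
  feature-guided U-Net: instead of regressing onto target images (which do
  not exist for this artifact), the network minimizes

  $$L = -\lambda_{DC}DC - \lambda_{CNR}CNR - \lambda_{PA}PA - \lambda_{VD}VD
        + \lambda_{DI}\,\mathrm{Var}(DC,CNR,PA,VD) + \lambda_{PA,2}PA_2 + \lambda_\xi\,\xi$$

  with $PA_2 = \langle \mathrm{MIP}\rangle_{R_1} - \langle I_\mathrm{pred}\rangle_{R_1}$
  (MIP = voxelwise maximum over repetitions) and $\xi$ the RMS deviation from
  the reference. Defaults:
  $\lambda_{DC}{=}0.5,\ \lambda_{CNR}{=}1.5,\ \lambda_{PA}{=}\lambda_{VD}{=}1,\
  \lambda_{DI}{=}0.5,\ \lambda_{PA,2}{=}\lambda_\xi{=}0.05$.
  Training (MSE pretraining on the reference, then feature-guided epochs with
  a moving-window early-stopping rule and best-weights selection) runs on a
  compact numpy reverse-mode autodiff engine — no GPU or deep-learning
  framework required.

* **`liverdwi.phantom`** — a synthetic phantom with exactly the assumed
  statistical structure (smooth left-lobe dropouts, bright-vessel flicker,
  lesions, parenchyma texture, noise) plus ground-truth masks, so every
  stage is testable without patient data.

## Worked example

```python
import liverdwi as ld
from liverdwi.io import run_benchmark

slices = ld.generate_dataset(n_patients=2, slices_per_patient=3, seed=7)
table = run_benchmark(
    slices,
    {
        "plain_mean": lambda s: s.mean(axis=2),
        "outlier_exclusion": ld.OutlierExclusion(k=10, ks2=21, thr=0.3).transform,
    },
)
print(table.round(3).to_string(index=False))
```

prints

```
           method  pa_n  dc_n  vd_n  cnr_n  qtotal
       plain_mean 1.035 0.998 0.913  1.120   1.017
outlier_exclusion 1.192 0.992 0.883  1.826   1.223
```

Reading the outlier-exclusion row: the left-lobe/right-lobe intensity ratio
recovers (pa_n = 1.19 > 1, dropouts filled) and lesion contrast improves
markedly (cnr_n = 1.83), at the cost of slightly brightened vessels
(vd_n = 0.88 < 1) and a small consistency loss in the artifact-free lobe
(dc_n = 0.99) — the characteristic signature of conventional
bright-pixel-weighted correction. The feature-guided network
(`ld.FeatureGuidedUNet(...).fit(train).predict(stack)`) targets the same
gains while keeping vessels dark (vd_n ≥ 1).

The same pipeline is scriptable from the shell via the `liverdwi` command
(`phantom`, `score`, `combine`, `sweep`, `train`, `predict`,
`evaluate-loss`, `benchmark`), exchanging NIfTI volumes, YAML configs and
CSV reports.

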