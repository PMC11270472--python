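# eatquant

Fully automated quantification of **epicardial adipose tissue (EAT)** from
cardiac CT: volume (EATv, mL) and mean attenuation (EATd, HU), computed by a
three-stage framework

1. **slice selection** — a residual CNN classifies every axial slice for EAT
   presence (removing slices above the pulmonary-trunk bifurcation or below
   the cardiac apex), trained with a class-weighted binary cross-entropy to
   counter the EAT-present / EAT-absent imbalance;
2. **segmentation** — a UNet-style encoder–decoder produces a per-pixel EAT
   posterior on each selected slice (sparse categorical cross-entropy,
   two-class softmax), upscaled to the native CT grid by area interpolation
   and binarized;
3. **quantification** — masks become physical quantities:

```
A_i = n_i · s_x · s_y                 per-slice EAT area (mm²)
V   = Σ_i (A_i + A_{i+1})/2 · Δz_i    trapezoidal EATv (mm³ → mL)
EATd = (1/M) Σ_i Σ_j x_i(j)           mean HU over the M mask pixels
                                      inside the adipose window [−190, −30] HU
```

EAT volume correlates with atrial-fibrillation prevalence and recurrence,
and EAT attenuation with inflammation and plaque risk; automating both
removes inter-observer variability from a tedious manual protocol.  The
package is aimed at imaging researchers who want a reproducible,
configurable reference implementation together with a fully synthetic test
bed: clinical EAT datasets are rarely shareable, so a **phantom generator**
produces CT-like stacks with analytically known EATv/EATd that exercise
every stage of the pipeline — including learnability of both networks.

The networks are implemented in a compact numpy engine (convolutions via
im2col/GEMM, batch norm, RMSProp/Adam with the corresponding learning-rate
schedules) with hand-written backpropagation; full-scale presets mirror the
original training recipe (224×224 inputs, 60 epochs, batch 128/64, initial
lr 1e-4), and desk-scale presets train in minutes on one CPU.

## Worked example

```python
import numpy as np
import eatquant as eq

# synthetic patient: 10 slices, EAT ring on slices 2..8, known ground truth
spec = eq.PhantomSpec(n_slices=10, eat_slice_range=(2, 8), grid_size=512,
                      noise_sd=0.0, eat_hu_sd=0.0, eat_hu_mean=-90.0, seed=6)
series, masks, gt = eq.generate_phantom_series(spec)
res = eq.quantify_patient(series, masks)
print(f"analytic EATv {gt.eatv_ml:.2f} mL, measured {res.eatv_ml:.2f} mL")
print(f"analytic EATd {gt.eatd_hu:.1f} HU, measured {res.eatd_hu:.1f} HU")
```

prints

```
analytic EATv 149.69 mL, measured 149.71 mL
analytic EATd -90.0 HU, measured -90.0 HU
```

i.e. the mask → volume pathway reproduces the closed-form phantom volume to
rasterization precision (&lt;0.1% at the native 512 grid), and a noiseless
phantom recovers its fat attenuation exactly.  The `examples/` scripts walk
through each capability (phantom generation, dataset splitting, training
both networks at desk scale, the end-to-end pipeline with agreement
statistics); a thin CLI (`eatquant simulate/split/train-classifier/
train-segmenter/predict/quantify/evaluate`) wraps the same functions.

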