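"""Generate a synthetic patient and quantify its EAT from the label masks.

The phantom's EAT ring has analytically known per-slice areas, so the
trapezoidal volume and windowed attenuation computed from the rasterized
masks can be checked against closed-form ground truth.
"""

import eatquant as eq

spec = eq.PhantomSpec(
    n_slices=10, eat_slice_range=(2, 8), grid_size=512,
    noise_sd=0.0, eat_hu_sd=0.0, eat_hu_mean=-90.0, seed=6,
)
series, masks, gt = eq.generate_phantom_series(spec)
res = eq.quantify_patient(series, masks)

print(f"slices: {len(series)}, EAT-bearing: {int(gt.slice_labels.sum())}")
print(f"analytic EATv {gt.eatv_ml:.2f} mL, measured {res.eatv_ml:.2f} mL "
      f"(rel. err {abs(res.eatv_ml - gt.eatv_ml) / gt.eatv_ml:.2e})")
print(f"analytic EATd {gt.eatd_hu:.1f} HU, measured {res.eatd_hu:.1f} HU")
# The volume difference is pure rasterization error (<0.1% at grid 512);
# a noiseless phantom recovers its fat attenuation exactly.
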