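"""End-to-end pipeline with oracle stubs + cohort agreement statistics.

Oracle stubs answer from the ground-truth masks, isolating the mask ->
volume/attenuation pathway: predicted EATv must agree with the analytic
value to rasterization precision, and the cohort Pearson r is ~1.
"""

import numpy as np

import eatquant as eq

specs = eq.generate_phantom_cohort(10, seed=5, grid_size=512,
                                   noise_sd=0.0, eat_hu_sd=0.0)
cohort, truth, gts = [], {}, {}
for sp in specs:
    series, masks, gt = eq.generate_phantom_series(sp)
    cohort.append(series)
    truth[series.patient_id] = masks
    gts[series.patient_id] = gt

reports = eq.run_pipeline(cohort, eq.OracleClassifier(truth), eq.OracleSegmenter(truth))
true_v = [gts[r.patient_id].eatv_ml for r in reports]
pred_v = [r.eatv_ml for r in reports]
for r, tv in zip(reports[:3], true_v):
    print(f"{r.patient_id}: EATv {r.eatv_ml:.2f} mL (analytic {tv:.2f}), "
          f"EATd {r.eatd_hu:.1f} HU, {r.n_slices_selected}/{r.n_slices_total} slices")

rep = eq.agreement_report(true_v, pred_v)
print(f"cohort agreement (n={rep.n}): r={rep.pearson_r:.4f}, "
      f"mean diff {rep.mean_diff:.3f} mL, LoA [{rep.loa_low:.3f}, {rep.loa_high:.3f}] mL")
# r ~ 1 and near-zero limits of agreement: the quantification pathway itself
# adds essentially no error; any real-world disagreement comes from the models.
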