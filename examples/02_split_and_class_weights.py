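"""Dataset splitting and the imbalance weights of the classification loss.

The holdout is floor(0.15 n) rounded down to even, halved into validation
and test.  Class weights are inverse-frequency: lambda_i = (1/k_i)(N/C).
"""

import eatquant as eq

for n in (41979, 23771):
    s = eq.split_dataset(n, holdout_fraction=0.15, seed=0)
    print(f"n={n}: train/val/test = {s.sizes}")

cw = eq.compute_class_weights([20234, 15449])
print(f"class counts {cw.counts} -> weights "
      f"lambda_0={cw.weights[0]:.3f}, lambda_1={cw.weights[1]:.3f}")
print(f"normalization sum k_i*lambda_i = {sum(k*w for k, w in zip(cw.counts, cw.weights)):.1f}"
      f" (= N = {cw.n_total})")
# EAT-present slices (the rarer class here) are weighted above 1, absent below.
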