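"""Line intercross and the Castle-Wright effective QTL number.

Crosses two diverged lines fixed for alternate alleles at 8 equal-effect
QTL: F1 phenotypes fall between the parental means, F2 variance exceeds F1
variance (segregation variance released), and the Castle-Wright estimator
n_E = (P1-P2)^2 / (8 (Var_F2 - Var_F1)) recovers the simulated QTL count.
"""

import numpy as np

import rotbreed as rb
from rotbreed.quantgen import simulate_intercross_experiment

r = simulate_intercross_experiment(n_qtl=8, seed=1)
print(f"parental means: high {r.mean_p1:.2f}, low {r.mean_p2:.2f}")
print(f"F1 mean {r.mean_f1:.2f} (intermediate), "
      f"Var(F1) {r.var_f1:.2f} < Var(F2) {r.var_f2:.2f}")
cw = rb.castle_wright(r.mean_p1, r.mean_p2, r.var_f1, r.var_f2)
print(f"Castle-Wright n_E = {cw.n_e:.1f}  (8 QTL simulated)")

nes = []
for s in range(20):
    ri = simulate_intercross_experiment(n_qtl=8, seed=s)
    nes.append(rb.castle_wright(ri.mean_p1, ri.mean_p2, ri.var_f1, ri.var_f2).n_e)
print(f"over 20 seeds: n_E = {np.mean(nes):.1f} "
      f"(range {min(nes):.1f}-{max(nes):.1f})")
# the estimator is noisy and biased by linkage/unequal effects; order of
# magnitude, not a locus count
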