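"""Familiarity training on a small network and its single-neuron statistics.

Runs a shortened version of the scaled familiarity protocol (Hebbian rule)
and prints the suppression index and lifetime-sparsity change of the
responsive neurons between the pre-training and final probes.
"""

import numpy as np

from famcirc import familiarity as fam
from famcirc.runner import ExperimentConfig, run_experiment

cfg = ExperimentConfig.familiarity_scaled(seed=2, epochs=10)
probes = list(run_experiment(cfg))
pre, post = probes[0].rates, probes[-1].rates

si, retained = fam.suppression_index(pre, post)
sp_pre = fam.lifetime_sparsity(pre[retained])
sp_post = fam.lifetime_sparsity(post[retained])
d_sparsity = fam.relative_change(sp_pre, sp_post)

print(f"probes at epochs {[p.epoch for p in probes]}")
print(f"{retained.sum()} responsive neurons of {cfg.network.n_exc}")
print(f"mean suppression index  {np.mean(si):+.3f}  "
      "(negative = stimulus-averaged responses suppressed)")
print(f"mean lifetime sparsity  pre {np.nanmean(sp_pre):.3f} -> "
      f"post {np.nanmean(sp_post):.3f} "
      f"(relative change {np.nanmean(d_sparsity):+.4f})")
curve_pre = fam.population_tuning_curve(pre[retained])
curve_post = fam.population_tuning_curve(post[retained])
print("rank-ordered population tuning (top 5 ranks), pre :",
      np.round(curve_pre[:5], 2))
print("                                          post:",
      np.round(curve_post[:5], 2))
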