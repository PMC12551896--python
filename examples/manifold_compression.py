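"""Association training and the relative-distance (manifold compression) view.

Runs a shortened association protocol (targets plus salt-and-pepper variants
at 10/30/50% noise) and prints the evolution of the relative level and
residual distances.  A decrease means the noise-variant manifolds shrink
relative to the separation between target representations.
"""

import numpy as np

from famcirc.manifold import manifold_objective
from famcirc.runner import ExperimentConfig, run_experiment

cfg = ExperimentConfig.association_scaled(seed=2, epochs=12,
                                          n_targets=2, samples_per_level=3)
print("stimuli: 2 targets x (1 clean + 3 levels x 3 samples) =",
      2 * (1 + 3 * 3))
for p in run_experiment(cfg):
    df = p.distances
    obj = manifold_objective(p.table)
    print(f"epoch {p.epoch:3d}:  R_lev {df.R_lev.mean():.3f}  "
          f"R_res {df.R_res.mean():.3f}  D_sig {df.D_sig.mean():8.2f}  "
          f"objective {obj:.3f}  ({p.n_nonconverged} non-converged)")
# R_lev / R_res: distances to same-target variants normalized by the
# distance to other targets at the same noise level; the objective sums the
# within/across squared-distance ratios over targets
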