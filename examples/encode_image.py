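"""Learn a sparse-coding dictionary on synthetic textures and encode one.

Builds a small set of correlated textures, learns 9x9 filters on patches
sampled from them, and encodes one texture into the strided convolutional
sparse code that drives the recurrent circuit.
"""

import numpy as np

from famcirc import sparse_coding as sc
from famcirc.stimuli import make_synthetic_targets

targets = make_synthetic_targets(8, side=18, seed=0)
patches = sc.sample_patches([t.pixels for t in targets], filter_side=9,
                            n_patches=1000, seed=1)
dictionary = sc.learn_dictionary(patches, n_filters=32, n_iter=6, seed=2)
print(f"learned {dictionary.n_filters} filters of size "
      f"{dictionary.filter_side}x{dictionary.filter_side}")
print("patch objective per iteration:",
      [round(v, 1) for v in dictionary.objective_history])

code = sc.encode(targets[0].pixels, dictionary, scale=30.0, sparsity=0.1)
recon = sc.decode(code, dictionary, 18)
err = np.linalg.norm(recon - targets[0].pixels) / np.linalg.norm(targets[0].pixels)
print(f"code grid {code.grid_shape} x {code.n_channels} channels, "
      f"{code.nonzero_fraction():.1%} nonzero, max drive {np.abs(code.flat()).max():.1f}")
print(f"relative reconstruction error {err:.2f}")
# the nonzero fraction is the working sparsity of the feedforward drive; the
# reconstruction error is dominated by the mean luminance, which the
# near-zero-mean filters do not encode
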