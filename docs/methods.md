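# Methods

## Model

`famcirc` simulates a rate-based recurrent circuit of primary visual cortex
organised as an `N_r x N_c` grid of hypercolumns with `N_d` feature channels.
Each grid position holds `N_d` excitatory neurons (one per channel) and as
many inhibitory neurons, giving `N_e = N_i = N_r N_c N_d` of each. The
excitatory and inhibitory rates evolve as

    tau_e dr_e/dt = -r_e + sigma(W_ee r_e + W_ei r_i + alpha)
    tau_i dr_i/dt = -r_i + sigma(W_ie r_e),       sigma(z) = max(z, 0)^2

with `tau_e = 40`, `tau_i = 20` time units. The supralinear (squared-ReLU)
gain makes the circuit a stabilized-supralinear-type network: responses are
shaped by the balance between mutual facilitation and recurrent inhibition
rather than by single-cell saturation.

Wiring. Excitatory neuron `k` receives plastic E-E input from every channel
of the hypercolumns within Chebyshev radius `R_e = 2` of its own (its
excitatory neighborhood `NE(k)`, `|NE(k)| = N_d (2R_e+1)^2` in the grid
interior). Inhibitory neuron `k` pools excitatory input from same-channel
neurons within radius `R_i = 1` (iso-feature surround suppression) and from
the other `N_d - 1` channels of its own hypercolumn (divisive
normalization); its input weights are uniform `w_ie / |NI(k)|`. Every
inhibitory neuron projects back to all excitatory neurons with the fixed
weight `-1/N_i`, so the total inhibitory feedback reduces to subtracting the
mean inhibitory rate. Neighborhoods are clipped at the grid border (no
wraparound) and row normalizations use the clipped sizes, so weight-row sums
are exact everywhere. The neighborhood contains the neuron itself; the
resulting autapse is part of the wiring but is excluded from plasticity (see
below).

Feedforward drive. Images (square grayscale in [0, 1], default 32 px) are
encoded by a convolutional sparse-coding front end: a dictionary of `N_d`
unit-norm `9x9` filters applied at stride 3 with no padding, giving one
coefficient field entry per (grid position, channel) — an `8x8 x 64` code
for the default geometry, a 4x overcomplete representation. Filters are
pre-trained on patches of the image ensemble being encoded (alternating L1
sparse coding with a least-squares dictionary update; the joint objective is
recorded per outer iteration) and held fixed during all circuit training.
Inference is ISTA with an L1 penalty (a greedy L0 mode is available); the
default penalty 0.4 leaves roughly 5-10% of coefficients nonzero on texture
stimuli. Coefficients are signed; rectification is left to the neuronal
gain. The code is scaled by a drive factor of 30 for both training and
probing.

## Plasticity

Only `W_ee` is plastic, and only on its initial support. Two rules:

* BCM: `dW_kl/dt = r_l r_k (r_k - xi_k) / tau_w`, with the sliding threshold
  `xi_k` an exponential moving average of the squared rate
  (`tau_xi dxi_k/dt = -xi_k + r_k^2`). Thresholds are initialised to each
  neuron's mean response magnitude over all stimuli and time steps of the
  untrained network. Weights are clipped at zero after depression (E-E
  synapses stay excitatory).
* General Hebbian: `dW_kl/dt = r_l r_k^2 / tau_w`, purely potentiating;
  paired with normalization it behaves like an Oja rule, with depression
  supplied by synaptic scaling instead of a threshold.

Synaptic resources are conserved by multiplicative row normalization after
every presentation: each row of `W_ee` is rescaled to sum to `w_ee = 5`
(rows that lose all mass are reset to the uniform initial profile). During a
presentation the state is reset to zero and the dynamics are integrated for
300 time units (forward Euler, `dt = 1`) with plasticity driven by the
current step's rates. The per-step weight increments are rank-1 in the
rates; they are accumulated and committed every 25 steps as a single matrix
product. The committed increments are exactly the per-step ones — only
their feedback onto the within-presentation dynamics is deferred by at most
25 time units, which is negligible against `tau_w`. Setting
`plasticity_chunk = 1` restores strict per-step application.

Autapses are excluded from plasticity. With associative potentiation
proportional to `r_l r_k^2`, a neuron that is the sole responder to a
stimulus directs all learning into its self-connection, creating a
self-amplifying loop that drives the supralinear dynamics to finite-time
divergence. Associative rules classically exclude the self term; the frozen
autapse keeps the wiring (and all neighborhood arithmetic) intact while
removing the pathological loop.

## Protocols

* Familiarity: clean stimuli only, each presented once per epoch (shuffled),
  probes every few epochs. Full scale: 25 images, 80 epochs, `w_ie = 20`.
* Association: each target plus 10 salt-and-pepper variants at each noise
  level in {10%, 30%, 50%} (a variant replaces `round(n P)` distinct pixels
  with U(0,1) draws; variants are a fixed set, not resampled per epoch).
  Per epoch each target appears 30 times and each variant once, shuffled.
  Full scale: 5 targets (155 stimuli), 350 epochs, `w_ie = 30`.

Probes freeze plasticity and compute, for every stimulus, the fixed point of
the dynamics from the zero state: integration continues until the max-norm
step change stays below `tol = 1e-6` for 20 consecutive time units (cap
1000 time units), and the representation `r*` is the mean excitatory rate
over the final 20 time units. Non-converged stimuli are flagged and excluded
from distance tables. The squared-ReLU gain is unbounded, so rates above a
divergence bound (default `1e6`) raise an error naming the offending
population rather than saturating silently.

## Statistics and manifold metrics

Familiarity statistics operate on pre/post response matrices of steady-state
rates. The suppression index of a neuron is the per-stimulus contrast
`(post - pre)/(post + pre)` averaged over the stimuli at which the neuron
responds in at least one phase (the contrast of stimulus-averaged rates is
available as an option); neurons whose stimulus-averaged rate stays below
1e-3 in both phases are excluded. The per-stimulus floor matters: without
it, numerically silent stimulus pairs (rates ~1e-9 decaying to exactly zero)
inject hard ±1 terms that dominate the index. Tuning sharpening is
quantified by the Vinje-Gallant lifetime sparsity
`S = n/(n-1) (1 - (sum r / n)^2 / (sum r^2 / n))` and by peak rates, with
relative changes `(post - pre)/(post + pre)`.

Manifold metrics live on the fixed-point table indexed by (noise level,
target, sample). For each noisy sample, the level distance (mean Euclidean
distance to the same target's samples at the adjacent lower level; the clean
target is the single level-0 sample), residual distance (other samples at
the same level and target) and signal distance (other targets' samples at
the same level) are formed, and the relative distances `R_lev = D_lev/D_sig`
and `R_res = D_res/D_sig` quantify compression of the variants manifold
relative to the concept manifold. All distances use excitatory rates only.

## Linear analysis

Around each attractor the stacked fixed-point map linearizes to
`J = (I - S W)^(-1) S = M S` with `S = diag(sigma'(W r* + alpha))` and `W`
the block connectivity. Eigendecomposing the recurrent gain `M` gives gain
modes `(mu_i, w_i, v_i)` (left/right eigenvectors biorthonormalized;
near-defective cases fall back to a Schur basis and are flagged).
Diagonalizing the Gram matrix of output patterns — formed from the
excitatory blocks, after dropping zero-gain modes that can never be excited
— yields collective modes with spectrum `lambda_k` and effective input
filters `phi_k`, satisfying `||P J dalpha||^2 = sum_k lambda_k
|phi_k^H dalpha|^2` exactly at full rank. Nonsymmetric `M` has complex
eigenpairs; Hermitian inner products keep the Gram matrix PSD and the
identity exact. Input deltas are unit-normalized sparse-code differences
paired exactly as in the distance classes; alignments are
`g_k = phi_k^H <dalpha dalpha^H> phi_k`. Analyses default to the top 10
modes. Mode correspondence across epochs is greedy matching by normalized
input-filter overlap (rank matching is available as a robustness check).
Sensitivities of the fractional linear distance change follow from
`D = sum_k lambda_k g_k`: the spectrum sensitivity of mode `k` is its
alignment share, the alignment sensitivity its spectrum share; both
weighted sums equal 1 identically.

## Synthetic stimuli

Targets are spatially correlated Gaussian textures (low-pass sigma 3 px,
min-max normalized to [0, 1]). Each set mixes a common component
(`shared_fraction = 0.6`) with independent per-target components: natural
photograph sets are strongly mutually correlated, and this correlation is
what lets single neurons respond to several stimuli of a set. Fully
independent textures give every stimulus a disjoint responsive population —
lifetime sparsity starts at ~1 and tuning statistics degenerate. What the
generator does not emulate: multi-scale (1/f) structure, oriented contours,
occlusion-by-objects, or any semantic content; conclusions about real
natural images rest on the full-scale protocol of the original experiments,
not on these textures.

## Scaled-down profiles

The full-scale protocols (4096+4096 neurons, 80-350 epochs) are beyond a
desk-scale run, so `familiarity_scaled` / `association_scaled` profiles
shrink the grid to 4x4 with 32 channels (512+512 neurons, 18-px images), 10
textures (familiarity) or 3 targets x 3 levels x 4 samples with 12 target
repetitions (association), 30-40 epochs with probes every few epochs. Three
constants are rescaled with the size, each for a stated structural reason:

* `w_ie = 30` in both profiles. The inhibitory strength is the model's
  designated stability parameter; the full-scale familiarity value (20)
  destabilizes training at this size.
* sparse-code penalty 0.1, keeping the absolute number of active
  feedforward inputs per stimulus (~130) comparable to full scale (~290);
  the active-input count, not its fraction, sets the inhibitory operating
  point.
* `tau_w = 1e8` (familiarity) / `5e8` (association). The smaller network
  runs at lower steady rates, and the weight drive is cubic in the rates,
  so the full-scale constant would leave weights essentially frozen over a
  scaled protocol; matching the full-scale per-presentation relative weight
  change would require ~3e7, which is dynamically unstable at this size, so
  each profile uses the fastest value at which every presentation is stable
  and every probe converges (the association schedule presents ~7x more
  stimuli per epoch, hence its lower stable learning rate).

Known limitations of the scaled surrogate. At every scale the network
responds in a near winner-take-all regime (~0.5% of excitatory neurons
active per stimulus), so the 512-neuron network retains only ~10-25
responsive neurons per run; the familiarity significance tests therefore
pool the retained populations of three replicate stimulus draws. More
fundamentally, tuning-curve sharpening and the late (rebound) phase of the
relative-distance trajectory require order-one restructuring of the E-E
rows into stimulus-specific assemblies, and at this network size the
supralinear dynamics lose stability (a finite-time divergence of the
zero-reset transient, racing the delayed inhibition) once the restructuring
exceeds a few multiples of the initial weights. The scaled protocols
therefore realize only the weak-learning phase: population suppression and
monotone early-phase manifold compression with the correct
distance-ordering, but not sharpening or the two-phase trajectory. Those
effects belong to the full-scale configuration, where the same relative
restructuring is spread over ~20-neuron assemblies and a ~20x larger
responsive population.
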