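"""Synthetic stimulus generation: textured targets, occluded variants, schedules.

The familiarity experiments use small grayscale images as stimuli.  Instead of
an external natural-image dataset, targets are spatially correlated random
textures (low-pass filtered white noise, min-max normalized to [0, 1]), which
share the key property natural patches have for this model: smooth spatial
correlation structure that a local filter dictionary can encode sparsely.
Nuisance variants are salt-and-pepper occlusions: a fixed fraction of pixel
positions replaced by independent U(0, 1) draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TargetImage",
    "NoisySample",
    "StimulusSet",
    "Schedule",
    "make_synthetic_targets",
    "occlude",
    "build_association_set",
    "build_familiarity_set",
    "build_epoch_schedule",
    "load_grayscale_image",
]


@dataclass(frozen=True)
class TargetImage:
    """A clean target stimulus: square grayscale image with values in [0, 1]."""

    pixels: np.ndarray
    target_id: int

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("target image must be a square 2-D array")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("target pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class NoisySample:
    """An occluded variant of a target image.

    ``mask`` marks the replaced pixel positions; exactly ``round(n * P)``
    positions are replaced for noise level ``n`` on a ``P``-pixel image.
    """

    pixels: np.ndarray
    target_id: int
    noise_level: float
    sample_index: int
    seed: tuple
    mask: np.ndarray


@dataclass(frozen=True)
class Stimulus:
    """One enumerable element of a stimulus set (clean target or variant)."""

    stimulus_id: int
    target_id: int
    noise_level: float  # 0.0 for the clean target
    sample_index: int  # 0 for the clean target
    pixels: np.ndarray


@dataclass
class StimulusSet:
    """An enumerable stimulus collection: T targets x (1 + L levels x K samples).

    Enumeration order is stable and seed-independent: for each target, the
    clean image first, then levels in ascending order, samples in ascending
    order.  Only presentation schedules shuffle.
    """

    targets: list[TargetImage]
    levels: tuple[float, ...]
    samples_per_level: int
    stimuli: list[Stimulus] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def keys(self) -> list[tuple[float, int, int]]:
        """(noise_level, target_id, sample_index) key per stimulus, in order."""
        return [(s.noise_level, s.target_id, s.sample_index) for s in self.stimuli]


@dataclass(frozen=True)
class Schedule:
    """Seeded presentation order for one epoch, as stimulus ids into a set."""

    order: np.ndarray
    epoch: int
    seed: int


def make_synthetic_targets(
    n: int,
    side: int = 32,
    correlation_length: float = 3.0,
    seed: int = 0,
    shared_fraction: float = 0.6,
    min_side: int | None = None,
) -> list[TargetImage]:
    """Generate ``n`` spatially correlated random textures in [0, 1].

    Each target mixes a texture component common to the whole set with an
    independent per-target component.  Sets of natural photographs are
    strongly mutually correlated (shared low-frequency content and global
    statistics), which makes individual neurons respond to several stimuli
    of a set; fully independent textures would give every stimulus a
    disjoint responsive population, an unrealistic regime for tuning-curve
    statistics.

    Parameters
    ----------
    n
        Number of targets (>= 1).
    side
        Image side length in pixels.
    correlation_length
        Gaussian low-pass sigma in pixels; 0 gives pixelwise-independent noise.
    seed
        Base seed; outputs are deterministic functions of (seed, index).
    shared_fraction
        Mixing weight of the set-common component in [0, 1); 0 gives
        mutually independent textures.
    min_side
        Optional geometry guard (e.g. the front-end filter size).
    """
    if n < 1:
        raise ValueError("need at least one target")
    if not 0.0 <= shared_fraction < 1.0:
        raise ValueError("shared_fraction must lie in [0, 1)")
    if min_side is not None and side < min_side:
        raise ValueError(
            f"image side {side} is below the required minimum {min_side}"
        )

    def _texture(rng):
        img = rng.standard_normal((side, side))
        if correlation_length > 0:
            img = ndimage.gaussian_filter(img, sigma=correlation_length,
                                          mode="reflect")
        return img

    common = _texture(
        np.random.default_rng(np.random.SeedSequence((seed, 0xC0117707)))
    )
    targets = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        img = shared_fraction * common + (1.0 - shared_fraction) * _texture(rng)
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (img - lo) / (hi - lo)
        else:  # degenerate flat draw
            img = np.full_like(img, 0.5)
        targets.append(TargetImage(pixels=img, target_id=i))
    return targets


def occlude(image: TargetImage, n: float, seed) -> NoisySample:
    """Replace ``round(n * P)`` distinct pixels of ``image`` with U(0, 1) draws.

    ``seed`` may be an int or a tuple; the same seed reproduces the same
    replacement mask and values.  Unmasked pixels are preserved bit-exactly.
    """
    if not 0.0 <= n <= 1.0:
        raise ValueError("noise level must lie in [0, 1]")
    pix = image.pixels
    p_total = pix.size
    n_replace = int(round(n * p_total))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    flat_idx = rng.choice(p_total, size=n_replace, replace=False)
    out = pix.copy()
    mask = np.zeros(p_total, dtype=bool)
    mask[flat_idx] = True
    out.ravel()[flat_idx] = rng.uniform(0.0, 1.0, size=n_replace)
    return NoisySample(
        pixels=out,
        target_id=image.target_id,
        noise_level=n,
        sample_index=-1,
        seed=tuple(np.atleast_1d(seed)) if not np.isscalar(seed) else (seed,),
        mask=mask.reshape(pix.shape),
    )


def _variant_seed(base_seed: int, target_id: int, level_index: int, k: int) -> tuple:
    # variants are a fixed set across epochs: the seed is a pure function of
    # (base seed, target, level, sample), never of the epoch
    return (base_seed, target_id, level_index, k)


def build_association_set(
    targets: list[TargetImage],
    levels: tuple[float, ...] = (0.1, 0.3, 0.5),
    samples_per_level: int = 10,
    base_seed: int = 0,
) -> StimulusSet:
    """Build the association stimulus set: clean targets plus occluded variants.

    Size is ``T * (1 + L * K)`` (155 for the default 5-target configuration
    with 3 levels and 10 samples per level).
    """
    if not targets:
        raise ValueError("targets must be nonempty")
    ids = [t.target_id for t in targets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate target ids")
    levels = tuple(sorted(float(l) for l in levels))
    stimuli: list[Stimulus] = []
    sid = 0
    for t in targets:
        stimuli.append(
            Stimulus(sid, t.target_id, 0.0, 0, t.pixels.copy())
        )
        sid += 1
        for li, lvl in enumerate(levels):
            for k in range(samples_per_level):
                samp = occlude(t, lvl, _variant_seed(base_seed, t.target_id, li, k))
                stimuli.append(Stimulus(sid, t.target_id, lvl, k + 1, samp.pixels))
                sid += 1
    return StimulusSet(
        targets=list(targets),
        levels=levels,
        samples_per_level=samples_per_level,
        stimuli=stimuli,
    )


def build_familiarity_set(n_images: int, side: int = 32, seed: int = 0,
                          correlation_length: float = 3.0,
                          shared_fraction: float = 0.6) -> StimulusSet:
    """Build the familiarity stimulus set: clean textures only, no variants."""
    targets = make_synthetic_targets(
        n_images, side=side, correlation_length=correlation_length, seed=seed,
        shared_fraction=shared_fraction,
    )
    stimuli = [
        Stimulus(i, t.target_id, 0.0, 0, t.pixels.copy())
        for i, t in enumerate(targets)
    ]
    return StimulusSet(targets=targets, levels=(), samples_per_level=0,
                       stimuli=stimuli)


def build_epoch_schedule(
    stimulus_set: StimulusSet,
    target_reps: int = 30,
    seed: int = 0,
    epoch: int = 0,
) -> Schedule:
    """Presentation order for one epoch.

    The epoch multiset holds ``target_reps`` copies of each clean target and
    one copy of each variant, permuted with an epoch-specific seeded RNG.
    """
    entries: list[int] = []
    for s in stimulus_set:
        if s.noise_level == 0.0:
            entries.extend([s.stimulus_id] * target_reps)
        else:
            entries.append(s.stimulus_id)
    order = np.array(entries, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence((seed, epoch)))
    rng.shuffle(order)
    return Schedule(order=order, epoch=epoch, seed=seed)


def load_grayscale_image(path) -> np.ndarray:
    """Load a stimulus image from PNG (ITU-R 601 luminance) or a text matrix.

    Returns a float array scaled to [0, 1].
    """
    path = str(path)
    if path.endswith(".png"):
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=float) / 255.0
        return arr
    arr = np.loadtxt(path, dtype=float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        arr = np.clip(arr, 0.0, 1.0)
    return arr
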