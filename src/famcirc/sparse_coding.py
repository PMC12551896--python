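"""Convolutional sparse-coding front end.

A dictionary of small square filters (default 64 filters of size 9x9) is
learned on image patches by alternating sparse coding and a least-squares
dictionary update.  Images are then encoded into a strided convolutional
sparse code: a coefficient field alpha over (row, column, channel) obtained by
ISTA on the generative model

    image ~ sum_{r,c,d} alpha[r,c,d] * filter_d placed at (r*stride, c*stride)

with an L1 penalty (optionally a greedy L0 mode).  With the default 32-pixel
images, 9-pixel filters, stride 3 and no padding this yields an 8x8 grid of
hypercolumns, one coefficient per filter channel per grid cell: a 4x
overcomplete representation of the image.  The coefficient field, scaled by a
drive factor (default 30), is the feedforward input to the recurrent circuit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import sparse_encode

__all__ = [
    "Dictionary",
    "SparseCode",
    "conv_grid_shape",
    "learn_dictionary",
    "encode",
    "decode",
    "sample_patches",
]


class GeometryError(ValueError):
    """Raised when filter/image/stride geometry is inconsistent."""


def conv_grid_shape(image_side: int, filter_side: int, stride: int) -> tuple[int, int]:
    """Feature-map grid shape for valid (no-padding) strided convolution.

    ``N = floor((image_side - filter_side) / stride) + 1`` per side;
    (32, 9, 3) -> (8, 8).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if filter_side > image_side:
        raise GeometryError(
            f"filter side {filter_side} exceeds image side {image_side}"
        )
    n = (image_side - filter_side) // stride + 1
    return (n, n)


@dataclass
class Dictionary:
    """A set of unit-norm convolution filters with a fixed stride.

    ``filters`` has shape (n_filters, f, f); each filter has unit Euclidean
    norm after learning.  ``objective_history`` records the (monitored,
    non-increasing) patch reconstruction objective per outer learning
    iteration.
    """

    filters: np.ndarray
    stride: int = 3
    seed: int | None = None
    objective_history: list = field(default_factory=list)

    def __post_init__(self):
        f = np.asarray(self.filters, dtype=float)
        if f.ndim != 3 or f.shape[1] != f.shape[2]:
            raise ValueError("filters must have shape (n_filters, f, f)")
        if f.shape[0] < 1:
            raise ValueError("need at least one filter")
        self.filters = f

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def filter_side(self) -> int:
        return self.filters.shape[1]

    def grid_shape(self, image_side: int) -> tuple[int, int]:
        return conv_grid_shape(image_side, self.filter_side, self.stride)

    def save(self, path) -> None:
        np.savez(
            path,
            filters=self.filters,
            stride=np.array(self.stride),
            norm_flag=np.array(True),
            seed=np.array(-1 if self.seed is None else self.seed),
        )

    @classmethod
    def load(cls, path) -> "Dictionary":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(
                filters=z["filters"],
                stride=int(z["stride"]),
                seed=None if seed < 0 else seed,
            )


@dataclass
class SparseCode:
    """Sparse coefficient field over (row, column, channel), times a drive scale.

    ``coefficients`` already includes the scale factor.  ``flat()`` returns the
    field in the circuit's neuron order: flat index k = (r * N_c + c) * N_d + d.
    """

    coefficients: np.ndarray  # (N_r, N_c, N_d)
    scale: float = 1.0

    def flat(self) -> np.ndarray:
        return self.coefficients.reshape(-1)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.coefficients.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[2]

    def nonzero_fraction(self) -> float:
        return float(np.mean(self.coefficients != 0.0))


def sample_patches(
    images, filter_side: int, n_patches: int, seed: int = 0, center: bool = True
) -> np.ndarray:
    """Sample square patches uniformly from a list of images.

    Returns an array of shape (n_patches, f, f); per-patch mean subtracted
    when ``center`` is set.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9A7C)))
    images = [np.asarray(im, dtype=float) for im in images]
    patches = np.empty((n_patches, filter_side, filter_side))
    for i in range(n_patches):
        im = images[rng.integers(len(images))]
        if im.shape[0] < filter_side or im.shape[1] < filter_side:
            raise GeometryError("image smaller than the patch size")
        r = rng.integers(im.shape[0] - filter_side + 1)
        c = rng.integers(im.shape[1] - filter_side + 1)
        patches[i] = im[r : r + filter_side, c : c + filter_side]
    if center:
        patches -= patches.mean(axis=(1, 2), keepdims=True)
    return patches


def _patch_objective(X, codes, D, penalty):
    resid = X - codes @ D
    return 0.5 * float(np.sum(resid**2)) + penalty * float(np.abs(codes).sum())


def _encode_batch(X, D, penalty):
    """L1 sparse coding of a patch batch; coordinate descent is run to a
    fixed generous iteration cap and its residual-tolerance warnings (common
    on near-degenerate texture patches) are silenced."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=Warning,
                                module="sklearn")
        return sparse_encode(X, D, algorithm="lasso_cd", alpha=penalty,
                             max_iter=2000)


def learn_dictionary(
    patches: np.ndarray,
    n_filters: int = 64,
    sparsity: float = 0.05,
    n_iter: int = 30,
    seed: int = 0,
    stride: int = 3,
) -> Dictionary:
    """Learn a unit-norm filter dictionary on image patches.

    Alternates L1 sparse coding of the patch batch against the current
    dictionary with a least-squares (MOD) dictionary update, renormalizing
    filters to unit norm each iteration.  The joint objective
    ``0.5 ||X - A D||^2 + sparsity * |A|_1`` is recorded per outer iteration
    and is non-increasing up to the renormalization step.

    Parameters
    ----------
    patches
        Array (n_patches, f, f) of (typically zero-mean) training patches.
    sparsity
        L1 penalty weight of the coding step.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    P = np.asarray(patches, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("patches contain non-finite values")
    if P.ndim != 3 or P.shape[1] != P.shape[2]:
        raise ValueError("patches must have shape (n, f, f)")
    if P.shape[0] < n_filters:
        raise ValueError("need at least n_filters patches")
    f = P.shape[1]
    X = P.reshape(P.shape[0], -1)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD1C7)))
    init_idx = rng.choice(X.shape[0], size=n_filters, replace=False)
    D = X[init_idx].copy()
    norms = np.linalg.norm(D, axis=1)
    # replace degenerate (zero-norm) initial atoms with random noise
    dead = norms < 1e-12
    if np.any(dead):
        D[dead] = rng.standard_normal((int(dead.sum()), D.shape[1]))
        norms = np.linalg.norm(D, axis=1)
    D /= norms[:, None]

    history = []
    for _ in range(n_iter):
        codes = _encode_batch(X, D, sparsity)
        history.append(_patch_objective(X, codes, D, sparsity))
        # MOD update: D <- argmin ||X - A D||^2, regularized for unused atoms
        gram = codes.T @ codes
        gram[np.diag_indices_from(gram)] += 1e-10
        D_new = np.linalg.solve(gram, codes.T @ X)
        norms = np.linalg.norm(D_new, axis=1)
        alive = norms > 1e-10
        D[alive] = D_new[alive] / norms[alive][:, None]
        # dead atoms: re-seed from the worst-reconstructed patch
        if np.any(~alive):
            resid = X - codes @ D
            worst = np.argsort(np.sum(resid**2, axis=1))[::-1]
            for j, atom in enumerate(np.flatnonzero(~alive)):
                v = X[worst[j % len(worst)]]
                nv = np.linalg.norm(v)
                D[atom] = v / nv if nv > 1e-12 else rng.standard_normal(D.shape[1])
                D[atom] /= np.linalg.norm(D[atom])
    codes = _encode_batch(X, D, sparsity)
    history.append(_patch_objective(X, codes, D, sparsity))

    return Dictionary(
        filters=D.reshape(n_filters, f, f),
        stride=stride,
        seed=seed,
        objective_history=history,
    )


def _extract_patch_grid(image: np.ndarray, f: int, stride: int) -> np.ndarray:
    """View the strided patch grid of an image as (N_r, N_c, f, f)."""
    n_r, n_c = conv_grid_shape(image.shape[0], f, stride)
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(image, (f, f))[::stride, ::stride]
    return win[:n_r, :n_c]


def _conv_forward(coeff: np.ndarray, filters: np.ndarray, stride: int,
                  image_side: int) -> np.ndarray:
    """Synthesis operator: scatter-add stride-placed filters."""
    n_r, n_c, n_d = coeff.shape
    f = filters.shape[1]
    out = np.zeros((image_side, image_side))
    # patch contribution per grid cell: (n_r, n_c, f, f)
    contrib = np.tensordot(coeff, filters, axes=([2], [0]))
    for r in range(n_r):
        for c in range(n_c):
            out[r * stride : r * stride + f, c * stride : c * stride + f] += contrib[r, c]
    return out


def _conv_adjoint(image: np.ndarray, filters: np.ndarray, stride: int) -> np.ndarray:
    """Analysis operator: correlate with each filter at every grid placement."""
    f = filters.shape[1]
    patches = _extract_patch_grid(image, f, stride)
    return np.tensordot(patches, filters, axes=([2, 3], [1, 2]))


def _operator_norm_sq(filters: np.ndarray, stride: int, image_side: int,
                      n_iter: int = 30) -> float:
    """Squared spectral norm of the synthesis operator, by power iteration."""
    n_r, n_c = conv_grid_shape(image_side, filters.shape[1], stride)
    v = np.ones((n_r, n_c, filters.shape[0]))
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = _conv_adjoint(_conv_forward(v, filters, stride, image_side),
                          filters, stride)
        lam = float(np.linalg.norm(w))
        if lam <= 1e-30:
            return 1.0
        v = w / lam
    return lam


def encode(
    image: np.ndarray,
    dictionary: Dictionary,
    scale: float = 30.0,
    sparsity: float = 0.4,
    n_iter: int = 200,
    mode: str = "l1",
    l0_budget: int | None = None,
) -> SparseCode:
    """Encode a grayscale image into a strided convolutional sparse code.

    ``mode='l1'`` runs ISTA from the all-zero code (final objective, hence
    residual, never exceeds the zero code's).  ``mode='l0'`` runs a greedy
    matching-pursuit variant keeping at most ``l0_budget`` coefficients.
    The returned coefficient field is multiplied by ``scale``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise GeometryError("image must be square")
    if img.min() < 0.0 or img.max() > 1.0:
        warnings.warn("image values outside [0, 1]; clamping", stacklevel=2)
        img = np.clip(img, 0.0, 1.0)
    side = img.shape[0]
    n_r, n_c = dictionary.grid_shape(side)
    filters = dictionary.filters
    stride = dictionary.stride

    if mode == "l0":
        coeff = _greedy_l0(img, filters, stride, side,
                           l0_budget or max(1, n_r * n_c * filters.shape[0] // 20))
        return SparseCode(coefficients=coeff * scale, scale=scale)
    if mode != "l1":
        raise ValueError("mode must be 'l1' or 'l0'")

    L = max(_operator_norm_sq(filters, stride, side), 1e-12)
    step = 1.0 / L
    thresh = sparsity * step
    coeff = np.zeros((n_r, n_c, filters.shape[0]))
    for _ in range(n_iter):
        resid = img - _conv_forward(coeff, filters, stride, side)
        grad = _conv_adjoint(resid, filters, stride)
        z = coeff + step * grad
        coeff = np.sign(z) * np.maximum(np.abs(z) - thresh, 0.0)
    return SparseCode(coefficients=coeff * scale, scale=scale)


def _greedy_l0(img, filters, stride, side, budget):
    """Matching pursuit on the strided placement grid."""
    coeff = np.zeros(conv_grid_shape(side, filters.shape[1], stride) + (filters.shape[0],))
    resid = img.copy()
    norms_sq = np.sum(filters**2, axis=(1, 2))
    norms_sq[norms_sq < 1e-12] = 1.0
    for _ in range(budget):
        corr = _conv_adjoint(resid, filters, stride)
        sel = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        a = corr[sel] / norms_sq[sel[2]]
        if abs(corr[sel]) < 1e-10:
            break
        coeff[sel] += a
        r0, c0 = sel[0] * stride, sel[1] * stride
        f = filters.shape[1]
        resid[r0 : r0 + f, c0 : c0 + f] -= a * filters[sel[2]]
    return coeff


def decode(code: SparseCode, dictionary: Dictionary, image_side: int) -> np.ndarray:
    """Reconstruct an image from a sparse code (undoing the drive scale)."""
    coeff = code.coefficients / (code.scale if code.scale else 1.0)
    return _conv_forward(coeff, dictionary.filters, dictionary.stride, image_side)
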