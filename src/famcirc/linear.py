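"""Attractor linearization, recurrent-gain modes and collective-mode analysis.

Around each stimulus-specific attractor r* of the stacked E-I system, the
fixed-point map r = sigma(W r + alpha) linearizes to

    dr = J dalpha,   J = (I - S W)^(-1) S =: M S,

where S = diag(sigma'(W r* + alpha)) is the local sensitivity and M the
recurrent gain matrix.  Eigendecomposing M = sum_i mu_i w_i v_i^H gives the
gain modes; their non-orthogonal output patterns interact, and diagonalizing
the Gram matrix G_ij = w_i^H w_j = sum_k lambda_k q_k q_k^H yields orthogonal
*collective modes*.  The squared linear response then splits exactly into
per-mode contributions

    ||J dalpha||^2 = sum_k lambda_k |phi_k^H dalpha|^2,

with effective input filters phi_k = sum_i (q_k)_i conj(mu_i) S v_i.  The
spectrum lambda_k is the mode's amplification gain and the alignment
g_k = phi_k^H <dalpha dalpha^H> phi_k measures how much input variation it
captures.  Nonsymmetric M generally has complex eigenpairs; Hermitian inner
products are used throughout so G stays Hermitian PSD, lambda stays real, and
the decomposition identity is exact.

Distances are evaluated on the excitatory coordinates only (the manifold
metrics use excitatory rates), so the Gram matrix is formed from the
excitatory blocks of the output patterns and the input filters live in the
excitatory input (sparse-code) space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .circuit import Connectivity, activation, activation_deriv

__all__ = [
    "Linearization",
    "GainModeSet",
    "CollectiveModeSet",
    "IllConditionedLinearization",
    "linearize",
    "gain_modes",
    "collective_modes",
    "input_deltas",
    "class_pairs",
    "linearized_distance",
    "alignment",
    "classify_orientation",
    "match_modes",
    "mode_change_stats",
    "sensitivities",
    "compression_condition",
]


class IllConditionedLinearization(RuntimeError):
    """Raised when (I - S W) is singular or numerically ill-conditioned."""


@dataclass
class Linearization:
    """First-order expansion of the stacked fixed-point map at one attractor."""

    sigma_prime: np.ndarray  # diagonal entries of S, length 2 N_e
    M: np.ndarray  # recurrent gain matrix (I - S W)^(-1)
    J: np.ndarray  # Jacobian M S
    W: np.ndarray  # stacked block connectivity
    n_exc: int
    stimulus_key: tuple | None = None
    active: np.ndarray = None  # coordinates with non-negligible sensitivity

    def __post_init__(self):
        if self.active is None:
            # coordinates whose local sensitivity is a vanishing fraction of
            # the largest carry a correspondingly vanishing share of J; they
            # are treated as silent, which keeps the active eigenproblem
            # well separated from the degenerate unit block
            floor = 1e-8 * float(np.max(self.sigma_prime, initial=0.0))
            self.active = np.flatnonzero(self.sigma_prime > floor)

    def jacobian_exc(self) -> np.ndarray:
        """Excitatory-output / excitatory-input block of J."""
        n = self.n_exc
        return self.J[:n, :n]


@dataclass
class GainModeSet:
    """Eigenmodes of the recurrent gain matrix M.

    Columns of ``w`` are right eigenvectors (output patterns), columns of
    ``v`` are left eigenvectors scaled so v_i^H w_j = delta_ij; ``v_tilde``
    holds the effective input filters S^T v_i.
    """

    mu: np.ndarray
    w: np.ndarray
    v: np.ndarray
    v_tilde: np.ndarray
    n_exc: int
    active: np.ndarray = None  # stacked coordinates the modes live on
    defective: bool = False

    def __post_init__(self):
        if self.active is None:
            self.active = np.arange(self.w.shape[0])


@dataclass
class CollectiveModeSet:
    """Orthogonal collective modes of one attractor's linearization.

    ``lam`` (descending, real >= 0) is the spectrum; ``phi`` stacks the
    effective input filters column-wise over the excitatory input coordinates;
    ``q`` holds the orthonormal Gram eigenvectors.
    """

    lam: np.ndarray
    q: np.ndarray
    phi: np.ndarray
    n_exc: int
    stimulus_key: tuple | None = None

    def top(self, k: int) -> "CollectiveModeSet":
        return CollectiveModeSet(
            lam=self.lam[:k], q=self.q[:, :k], phi=self.phi[:, :k],
            n_exc=self.n_exc, stimulus_key=self.stimulus_key,
        )


def linearize(conn: Connectivity, r_e_star: np.ndarray, alpha: np.ndarray,
              cond_limit: float = 1e12, stimulus_key=None) -> Linearization:
    """Linearize the stacked E-I fixed-point map around an attractor.

    ``r_e_star`` is the converged excitatory state; the inhibitory steady
    state is recovered from it as sigma(W_ie r_e*).  The condition number of
    (I - S W) is estimated in the 1-norm; values above ``cond_limit`` raise.
    """
    n = conn.config.n_exc
    r_i_star = activation(conn.w_ie @ r_e_star)
    r = np.concatenate([r_e_star, r_i_star])
    W = conn.block_matrix()
    drive = np.concatenate([np.asarray(alpha, dtype=float), np.zeros(n)])
    net = W @ r + drive
    s = activation_deriv(net)
    A = np.eye(2 * n) - s[:, None] * W
    try:
        M = linalg.solve(A, np.eye(2 * n))
    except linalg.LinAlgError as exc:  # pragma: no cover - singular A
        raise IllConditionedLinearization(str(exc)) from exc
    cond1 = np.linalg.norm(A, 1) * np.linalg.norm(M, 1)
    if not np.isfinite(cond1) or cond1 > cond_limit:
        raise IllConditionedLinearization(
            f"1-norm condition estimate {cond1:.3e} exceeds {cond_limit:.1e}"
        )
    J = M * s[None, :]
    return Linearization(sigma_prime=s, M=M, J=J, W=W, n_exc=n,
                         stimulus_key=stimulus_key)


def gain_modes(lin: Linearization, cond_tol: float = 1e12) -> GainModeSet:
    """Eigendecomposition of the recurrent gain on the active subspace.

    The Jacobian vanishes identically on coordinates with zero local
    sensitivity (silent neurons): their J rows and columns are exactly zero,
    and they load the gain matrix with a large degenerate unit eigenvalue
    block that makes the full eigenproblem numerically defective.  The
    decomposition is therefore performed on the active restriction
    ``M[A, A] = (I - S_A W_AA)^(-1)``, which carries the entire linear
    response.  Left eigenvectors are the inverse-transpose of the right
    eigenvector matrix, enforcing v_i^H w_j = delta_ij exactly for
    diagonalizable restrictions; a right eigenbasis with condition number
    above ``cond_tol`` falls back to a unitary Schur basis, flagged
    ``defective``.
    """
    act = lin.active
    if act.size == 0:
        empty = np.zeros((0, 0), dtype=complex)
        return GainModeSet(mu=np.zeros(0, dtype=complex), w=empty, v=empty,
                           v_tilde=empty, n_exc=lin.n_exc, active=act)
    M_r = lin.M[np.ix_(act, act)]
    mu, vr = linalg.eig(M_r)
    if np.linalg.cond(vr) > cond_tol:
        T, Z = linalg.schur(M_r.astype(complex), output="complex")
        mu = np.diag(T)
        v_tilde = lin.sigma_prime[act, None] * Z
        return GainModeSet(mu=mu, w=Z, v=Z, v_tilde=v_tilde,
                           n_exc=lin.n_exc, active=act, defective=True)
    vl = np.linalg.inv(vr).conj().T  # v_i^H w_j = delta_ij by construction
    v_tilde = lin.sigma_prime[act, None] * vl
    return GainModeSet(mu=mu, w=vr, v=vl, v_tilde=v_tilde, n_exc=lin.n_exc,
                       active=act)


def collective_modes(modes: GainModeSet, project_exc: bool = True,
                     gain_tol: float = 1e-10) -> CollectiveModeSet:
    """Diagonalize the Gram matrix of gain-mode output patterns.

    With ``project_exc`` (the default) the Gram matrix is formed from the
    excitatory block of the output patterns and the input filters are
    restricted to the excitatory input coordinates, matching the manifold
    metrics, which measure distances on excitatory rates driven by sparse-code
    inputs.  Gain modes with |mu| below ``gain_tol`` times the largest gain
    are dropped first: their output patterns can never be excited (p_i = 0
    for every input) but would otherwise contribute spurious Gram spectrum.
    """
    n = modes.n_exc
    act = modes.active
    dim = n if project_exc else 2 * n
    if act.size == 0:
        return CollectiveModeSet(lam=np.zeros(0), q=np.zeros((0, 0)),
                                 phi=np.zeros((dim, 0), dtype=complex),
                                 n_exc=n)
    keep = np.abs(modes.mu) > gain_tol * np.max(np.abs(modes.mu), initial=0.0)
    mu = modes.mu[keep]
    out_rows = act < n if project_exc else np.ones(act.size, dtype=bool)
    w_out = modes.w[out_rows][:, keep]
    G = w_out.conj().T @ w_out
    G = 0.5 * (G + G.conj().T)
    lam, q = linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    q = q[:, order]
    # input filters live on the active excitatory coordinates; embed them
    # back into the full input space with zeros elsewhere
    in_rows = act < n if project_exc else np.ones(act.size, dtype=bool)
    v_in = modes.v_tilde[in_rows][:, keep]
    # phi_k = sum_i (q_k)_i conj(mu_i) S v_i, chosen so that
    # sum_k lam_k |phi_k^H d|^2 == ||P J d||^2 holds exactly at full rank
    phi_r = v_in @ (q * mu.conj()[:, None])
    phi = np.zeros((dim, phi_r.shape[1]), dtype=complex)
    phi[act[in_rows]] = phi_r
    return CollectiveModeSet(lam=lam.real, q=q, phi=phi, n_exc=n)


def class_pairs(keys, anchor, direction_class):
    """Partner keys of ``anchor`` = (level, target, sample) for a distance class.

    ``signal``: other targets at the same level; ``level``: same target at the
    adjacent lower level; ``residual``: other samples at the same
    (level, target).
    """
    level, target, sample = anchor
    levels = sorted({k[0] for k in keys})
    if direction_class == "signal":
        return [k for k in keys if k[0] == level and k[1] != target]
    if direction_class == "level":
        i = levels.index(level)
        if i == 0:
            raise ValueError("lowest level has no lower neighbor")
        lower = levels[i - 1]
        return [k for k in keys if k[0] == lower and k[1] == target]
    if direction_class == "residual":
        return [
            k for k in keys
            if k[0] == level and k[1] == target and k[2] != sample
        ]
    raise ValueError("direction_class must be 'signal', 'level' or 'residual'")


def input_deltas(codes: dict, direction_class: str, anchor=None) -> np.ndarray:
    """Unit-norm sparse-code difference vectors for one distance class.

    ``codes`` maps (level, target, sample) keys to flat alpha vectors.  With
    ``anchor`` given, only that stimulus's pairings are emitted; otherwise all
    anchors able to form the class are pooled.  Zero differences are dropped.
    Returns an array of shape (n_pairs, dim).
    """
    keys = list(codes)
    anchors = [anchor] if anchor is not None else keys
    out = []
    for a in anchors:
        try:
            partners = class_pairs(keys, a, direction_class)
        except ValueError:
            continue
        for p in partners:
            d = codes[a] - codes[p]
            nrm = np.linalg.norm(d)
            if nrm > 0:
                out.append(d / nrm)
    if not out:
        raise ValueError(f"no input pairs available for class '{direction_class}'")
    return np.asarray(out)


def linearized_distance(cms: CollectiveModeSet, deltas: np.ndarray,
                        top_k: int | None = 10) -> float:
    """Mean squared linear response over unit input deltas, top-K modes.

    D_hat = mean_dalpha sum_{k<=K} lambda_k |phi_k^H dalpha|^2; with K equal
    to the full rank this equals the mean of ||P J dalpha||^2 exactly.
    """
    k = cms.lam.size if top_k is None else min(top_k, cms.lam.size)
    proj = deltas @ cms.phi[:, :k].conj()  # (n_pairs, k)
    contrib = (np.abs(proj) ** 2) @ cms.lam[:k]
    return float(np.mean(contrib))


def alignment(cms: CollectiveModeSet, delta_cov: np.ndarray,
              top_k: int | None = 10) -> np.ndarray:
    """Per-mode alignment g_k = phi_k^H C phi_k with an input covariance C."""
    k = cms.lam.size if top_k is None else min(top_k, cms.lam.size)
    phi = cms.phi[:, :k]
    g = np.einsum("ik,ij,jk->k", phi.conj(), delta_cov, phi)
    return np.real(g)


def delta_covariance(deltas: np.ndarray) -> np.ndarray:
    """Second-moment matrix <dalpha dalpha^H> of a set of unit input deltas."""
    return (deltas.conj().T @ deltas) / deltas.shape[0]


def classify_orientation(g_signal: np.ndarray, g_noise: np.ndarray,
                         threshold: float = 0.1) -> np.ndarray:
    """Label modes signal- / noise-oriented / neutral from pre-training alignments.

    A mode is signal-oriented when its signal alignment exceeds its noise
    alignment by more than ``threshold`` times the maximum absolute
    difference observed across modes (and vice versa); otherwise neutral.
    """
    diff = np.asarray(g_signal, dtype=float) - np.asarray(g_noise, dtype=float)
    m = np.max(np.abs(diff), initial=0.0)
    labels = np.full(diff.shape, "neutral", dtype=object)
    if m == 0:
        return labels
    labels[diff > threshold * m] = "signal"
    labels[diff < -threshold * m] = "noise"
    return labels


def match_modes(pre: CollectiveModeSet, post: CollectiveModeSet,
                method: str = "overlap") -> np.ndarray:
    """Correspondence between pre- and post-training collective modes.

    ``overlap`` greedily pairs modes by maximal normalized input-filter
    overlap |phi_pre^H phi_post|; ``rank`` pairs by spectrum rank.  Returns an
    array mapping pre-mode index -> post-mode index (-1 when unmatched).
    """
    n_pre, n_post = pre.lam.size, post.lam.size
    if method == "rank":
        m = min(n_pre, n_post)
        out = -np.ones(n_pre, dtype=int)
        out[:m] = np.arange(m)
        return out
    if method != "overlap":
        raise ValueError("method must be 'overlap' or 'rank'")
    pn = np.linalg.norm(pre.phi, axis=0)
    qn = np.linalg.norm(post.phi, axis=0)
    denom = np.outer(pn, qn)
    denom[denom == 0] = np.inf
    ov = np.abs(pre.phi.conj().T @ post.phi) / denom
    out = -np.ones(n_pre, dtype=int)
    ov = ov.copy()
    for _ in range(min(n_pre, n_post)):
        i, j = np.unravel_index(np.argmax(ov), ov.shape)
        if not np.isfinite(ov[i, j]) or ov[i, j] < 0:
            break
        out[i] = j
        ov[i, :] = -np.inf
        ov[:, j] = -np.inf
    return out


def mode_change_stats(
    pre: CollectiveModeSet,
    post: CollectiveModeSet,
    pre_alignments: dict,
    post_alignments: dict,
    inclusion_threshold: float = 0.1,
    orientation_threshold: float = 0.1,
    matching: str = "overlap",
) -> pd.DataFrame:
    """Per-mode spectrum and alignment changes between two probe epochs.

    ``pre_alignments`` / ``post_alignments`` map the class names ``signal``,
    ``level`` and ``residual`` to per-mode alignment arrays (same truncation
    as the mode sets).  Changes are max-normalized per quantity; a mode is
    ``included`` in density summaries when its change magnitude exceeds
    ``inclusion_threshold`` times the maximum change.  Orientation labels use
    the pre-training signal alignment against the mean of the level and
    residual alignments.
    """
    idx = match_modes(pre, post, method=matching)
    matched = np.flatnonzero(idx >= 0)
    post_idx = idx[matched]

    def _norm(x):
        m = np.max(np.abs(x), initial=0.0)
        return x / m if m > 0 else x

    k = matched.size
    d_lam = post.lam[post_idx] - pre.lam[matched]
    rows = dict(
        mode=matched,
        post_mode=post_idx,
        lam_pre=pre.lam[matched],
        lam_post=post.lam[post_idx],
        d_lam=_norm(d_lam),
        included_lam=np.abs(d_lam) > inclusion_threshold * np.max(np.abs(d_lam), initial=0.0),
    )
    g_noise_pre = 0.5 * (
        np.asarray(pre_alignments["level"]) + np.asarray(pre_alignments["residual"])
    )
    rows["orientation"] = classify_orientation(
        np.asarray(pre_alignments["signal"])[matched],
        g_noise_pre[matched],
        threshold=orientation_threshold,
    )
    for cls in ("signal", "level", "residual"):
        dg = (np.asarray(post_alignments[cls])[post_idx]
              - np.asarray(pre_alignments[cls])[matched])
        rows[f"d_g_{cls}"] = _norm(dg)
        rows[f"included_g_{cls}"] = np.abs(dg) > inclusion_threshold * np.max(
            np.abs(dg), initial=0.0
        )
    return pd.DataFrame(rows)


def sensitivities(lam_pre: np.ndarray, g_pre: np.ndarray) -> dict:
    """First-order sensitivities of the fractional linear distance change.

    With D = sum_k lambda_k g_k and D~ = dD / D_pre, a mode's spectrum
    sensitivity is its pre-training alignment share and its alignment
    sensitivity its pre-training spectrum share:

        dD~/dΔlambda_k = g_k / sum_j lambda_j g_j,
        dD~/dΔg_k      = lambda_k / sum_j lambda_j g_j.

    The weighted sums sum_k lambda_k dD~/dΔlambda_k and
    sum_k g_k dD~/dΔg_k both equal 1.  Returns NaN arrays when the
    pre-training distance vanishes.
    """
    lam = np.asarray(lam_pre, dtype=float)
    g = np.asarray(g_pre, dtype=float)
    denom = float(np.sum(lam * g))
    if denom == 0:
        nanv = np.full(lam.shape, np.nan)
        return dict(d_lambda=nanv, d_g=nanv.copy(), d_pre=0.0)
    return dict(d_lambda=g / denom, d_g=lam / denom, d_pre=denom)


def compression_condition(d_sig_pre: float, d_noise_pre: float,
                          d_sig_post: float, d_noise_post: float) -> dict:
    """First-order change of the linear relative distance R = D_noise/D_sig.

    ΔR ≈ (D_sig,pre ΔD_noise − D_noise,pre ΔD_sig) / D_sig,pre²; compression
    (ΔR < 0) holds iff the fractional signal-distance change exceeds the
    fractional noise-distance change.
    """
    dd_sig = d_sig_post - d_sig_pre
    dd_noise = d_noise_post - d_noise_pre
    delta_r = (d_sig_pre * dd_noise - d_noise_pre * dd_sig) / d_sig_pre**2
    frac_sig = dd_sig / d_sig_pre
    frac_noise = dd_noise / d_noise_pre if d_noise_pre else float("nan")
    return dict(
        delta_R=float(delta_r),
        frac_sig=float(frac_sig),
        frac_noise=float(frac_noise),
        compresses=bool(frac_sig > frac_noise),
    )
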