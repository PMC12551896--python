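"""Single-neuron and population familiarity statistics.

All metrics operate on steady-state excitatory response matrices
(neurons x stimuli), one recorded before training ("pre") and one after
("post").  The headline quantities are the suppression index
SI = (post - pre)/(post + pre) and the Vinje-Gallant lifetime sparsity of
each neuron's tuning curve, whose relative change quantifies tuning-curve
sharpening.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "suppression_index",
    "lifetime_sparsity",
    "relative_change",
    "population_tuning_curve",
    "psth",
    "peak_response",
    "responsive_mask",
]

RESPONSIVE_THRESHOLD = 1e-3


def _check_matrix(m, name):
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (neurons x stimuli) array")
    if not np.all(np.isfinite(m)) or np.any(m < 0):
        raise ValueError(f"{name} must be finite and nonnegative")
    return m


def responsive_mask(pre, post, threshold: float = RESPONSIVE_THRESHOLD):
    """Neurons whose stimulus-averaged rate exceeds ``threshold`` in either phase.

    Neurons silent in both phases carry no familiarity signal and are
    excluded from SI and sharpening summaries.
    """
    pre = _check_matrix(pre, "pre")
    post = _check_matrix(post, "post")
    return (pre.mean(axis=1) > threshold) | (post.mean(axis=1) > threshold)


def suppression_index(
    pre,
    post,
    responsive_threshold: float = RESPONSIVE_THRESHOLD,
    per_stimulus: bool = True,
):
    """Per-neuron suppression index over matched pre/post response matrices.

    With ``per_stimulus`` (default) the contrast (post - pre)/(post + pre) is
    computed for every stimulus and then averaged over the stimulus set;
    otherwise the contrast of the stimulus-averaged rates is taken.  Stimuli
    (or neurons) with zero rate in both phases contribute SI = 0.  Returns
    ``(si, retained)`` where ``retained`` is the responsive-neuron mask and
    ``si`` holds values only for retained neurons.
    """
    pre = _check_matrix(pre, "pre")
    post = _check_matrix(post, "post")
    if pre.shape != post.shape:
        raise ValueError("pre and post response matrices must share a shape")
    retained = responsive_mask(pre, post, responsive_threshold)
    if per_stimulus:
        denom = pre + post
        # stimuli with no appreciable response in either phase carry no
        # familiarity signal for this neuron; without the floor the ratio
        # turns numerical dust into hard +-1 contributions
        valid = denom > responsive_threshold
        si_full = np.divide(post - pre, denom, out=np.zeros_like(denom),
                            where=valid)
        n_valid = valid.sum(axis=1)
        si = np.divide(si_full.sum(axis=1), n_valid,
                       out=np.zeros(pre.shape[0]), where=n_valid > 0)
    else:
        mp, mq = pre.mean(axis=1), post.mean(axis=1)
        denom = mp + mq
        si = np.divide(mq - mp, denom, out=np.zeros_like(denom), where=denom > 0)
    return si[retained], retained


def lifetime_sparsity(tuning):
    """Vinje-Gallant lifetime sparsity S in [0, 1].

    ``S = n/(n-1) * (1 - (sum r / n)^2 / (sum r^2 / n))`` over the n stimuli
    of a tuning curve; 0 for a flat curve, 1 for a one-hot curve.  Accepts a
    single tuning vector or a (neurons x stimuli) matrix; all-zero curves give
    NaN.
    """
    t = np.asarray(tuning, dtype=float)
    single = t.ndim == 1
    t = np.atleast_2d(t)
    n = t.shape[1]
    if n < 2:
        raise ValueError("need at least two stimuli")
    if np.any(t < 0):
        raise ValueError("responses must be nonnegative")
    mean_sq = (t.sum(axis=1) / n) ** 2
    sq_mean = (t**2).sum(axis=1) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (n / (n - 1)) * (1.0 - mean_sq / sq_mean)
    s = np.where(sq_mean > 0, s, np.nan)
    return float(s[0]) if single else s


def relative_change(pre, post):
    """(post - pre) / (post + pre); NaN where both are zero."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    denom = pre + post
    out = np.where(
        denom != 0,
        np.divide(post - pre, denom, out=np.zeros_like(denom, dtype=float),
                  where=denom != 0),
        np.nan,
    )
    return float(out) if out.ndim == 0 else out


def population_tuning_curve(responses):
    """Rank-ordered mean population tuning curve.

    For each stimulus, neuron responses are sorted in descending order; the
    sorted vectors are then averaged across stimuli at each rank.
    """
    r = _check_matrix(responses, "responses")
    ranked = np.sort(r, axis=0)[::-1]
    return ranked.mean(axis=1)


def psth(traces, normalize: bool = False):
    """Population peri-stimulus time histogram.

    ``traces`` is (n_stimuli, T, n_neurons) (or (T, n_neurons) for a single
    stimulus); the result is the mean rate per time step over stimuli and
    neurons, optionally normalized by its peak.
    """
    tr = np.asarray(traces, dtype=float)
    if tr.ndim == 2:
        tr = tr[None]
    if tr.ndim != 3:
        raise ValueError("traces must be (n_stimuli, T, n_neurons)")
    curve = tr.mean(axis=(0, 2))
    if normalize:
        peak = curve.max()
        if peak > 0:
            curve = curve / peak
    return curve


def peak_response(tuning):
    """Maximum response over the stimulus set (per neuron for matrices)."""
    t = np.asarray(tuning, dtype=float)
    return t.max(axis=-1)
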