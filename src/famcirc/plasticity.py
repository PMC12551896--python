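"""Plasticity of the E-E recurrent weights: BCM and general Hebbian rules.

Only the excitatory-to-excitatory matrix is plastic, and only on its initial
support mask (no new connections are grown).  Two rules are implemented:

* BCM: dW_kl/dt = r_l r_k (r_k - xi_k) / tau_w, with the sliding threshold
  xi_k tracking an exponential moving average of the squared rate
  (d xi_k/dt = (-xi_k + r_k^2) / tau_xi).  Depression can push entries
  negative; they are clipped at zero (E-E synapses stay excitatory).
* General Hebbian: dW_kl/dt = r_l r_k^2 / tau_w, always potentiating; paired
  with synaptic-resource normalization it behaves like Oja-style learning,
  with depression supplied by the normalization instead of a threshold.

Synaptic resources are conserved by multiplicative row normalization: after
every presentation each row of W_ee is rescaled to sum to w_ee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasticityState",
    "bcm_update",
    "bcm_threshold_update",
    "hebbian_update",
    "normalize_weights",
]


@dataclass
class PlasticityState:
    """Rule selection and constants; holds the BCM thresholds when relevant."""

    rule: str = "hebbian"  # "hebbian" | "bcm"
    tau_w: float = 2e9
    tau_xi: float = 2e7
    xi: np.ndarray | None = None  # per-neuron BCM thresholds (rate^2 units)

    def __post_init__(self):
        if self.rule not in ("hebbian", "bcm"):
            raise ValueError("rule must be 'hebbian' or 'bcm'")
        if self.xi is not None and np.any(np.asarray(self.xi) < 0):
            raise ValueError("BCM thresholds must be nonnegative")

    def apply(self, w_ee: np.ndarray, r_e: np.ndarray, dt: float,
              mask: np.ndarray) -> None:
        """One in-place plasticity step with the configured rule."""
        if self.rule == "bcm":
            bcm_update(w_ee, r_e, self.xi, dt, self.tau_w, mask, out=w_ee)
            bcm_threshold_update(self.xi, r_e, dt, self.tau_xi, out=self.xi)
        else:
            hebbian_update(w_ee, r_e, dt, self.tau_w, mask, out=w_ee)


def _check_rates(r_e):
    if np.any(r_e < 0):
        raise ValueError("rates must be nonnegative")


def bcm_update(w_ee, r_e, xi, dt, tau_w, mask, out=None):
    """BCM step: dW_kl = (dt/tau_w) r_l r_k (r_k - xi_k) on masked entries.

    Entries are clipped at zero from below after the update.
    """
    _check_rates(r_e)
    out = np.array(w_ee, copy=True) if out is None else out
    post = r_e * (r_e - xi)
    delta = (dt / tau_w) * np.outer(post, r_e)
    delta *= mask
    out += delta
    np.maximum(out, 0.0, out=out)
    out[~mask] = 0.0
    return out


def bcm_threshold_update(xi, r_e, dt, tau_xi, out=None):
    """Sliding-threshold step: xi <- xi + (dt/tau_xi)(-xi + r_e^2)."""
    out = np.array(xi, copy=True) if out is None else out
    out += (dt / tau_xi) * (-out + r_e * r_e)
    return out


def hebbian_update(w_ee, r_e, dt, tau_w, mask, out=None):
    """General Hebbian step: dW_kl = (dt/tau_w) r_l r_k^2 on masked entries."""
    _check_rates(r_e)
    out = np.array(w_ee, copy=True) if out is None else out
    delta = (dt / tau_w) * np.outer(r_e * r_e, r_e)
    delta *= mask
    out += delta
    return out


def normalize_weights(w_ee, w_ee_total, mask, ne_sizes=None, out=None):
    """Multiplicatively rescale each row of W_ee to sum to ``w_ee_total``.

    Rows whose mass has vanished are reset to the uniform initial profile
    w_ee_total / |NE(k)| over the mask.
    """
    out = np.array(w_ee, copy=True) if out is None else out
    if np.any(out[mask] < 0):
        raise ValueError("weights must be nonnegative on the support")
    sums = out.sum(axis=1)
    alive = sums > 0
    out[alive] *= (w_ee_total / sums[alive])[:, None]
    dead = np.flatnonzero(~alive)
    if dead.size:
        if ne_sizes is None:
            ne_sizes = mask.sum(axis=1)
        for k in dead:
            out[k, mask[k]] = w_ee_total / ne_sizes[k]
    return out
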