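"""Hypercolumnar E-I rate network: connectivity and fixed-point dynamics.

The network tiles an N_r x N_c retinotopic grid of hypercolumns, each holding
N_d excitatory neurons (one per feature channel) and as many inhibitory
neurons.  Excitatory neuron k receives plastic E-E input from every channel of
the hypercolumns within a square of radius R_e around its own ("mutual
facilitation").  Inhibitory neuron k pools excitatory input from the
same-channel neurons within radius R_i (iso-feature surround suppression) and
from the other channels of its own hypercolumn (divisive normalization), and
projects back uniformly to all excitatory neurons with weight -1/N_i.

Rates evolve under leaky dynamics with a squared-ReLU gain sigma(z) = max(z,0)^2:

    tau_e dr_e/dt = -r_e + sigma(W_ee r_e + W_ei r_i + alpha)
    tau_i dr_i/dt = -r_i + sigma(W_ie r_e)

integrated by forward Euler with dt = 1 time unit.  Stimulus representations
are the converged excitatory steady states (mean over the final 20 time units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

__all__ = [
    "NetworkConfig",
    "Connectivity",
    "NetworkState",
    "FixedPointRecord",
    "InstabilityError",
    "activation",
    "activation_deriv",
    "build_connectivity",
    "step",
    "run_to_fixed_point",
    "simulate_trace",
]


class InstabilityError(RuntimeError):
    """Raised when a population's rate exceeds the divergence bound."""


def activation(z):
    """Squared ReLU: sigma(z) = max(z, 0)^2."""
    zz = np.maximum(z, 0.0)
    return zz * zz


def activation_deriv(z):
    """Derivative of the squared ReLU: sigma'(z) = 2 max(z, 0)."""
    return 2.0 * np.maximum(z, 0.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Geometry, coupling strengths and integration constants of the circuit.

    Defaults are the full-scale configuration: an 8x8 grid of hypercolumns
    with 64 channels (4096 E and 4096 I neurons), facilitation radius R_e = 2,
    surround-suppression radius R_i = 1, per-neuron E-E resource w_ee = 5, and
    excitatory/inhibitory time constants 40 / 20 time units.  The E-I strength
    w_ie is experiment-specific (20 for familiarity, 30 for association).
    """

    n_rows: int = 8
    n_cols: int = 8
    n_channels: int = 64
    radius_e: int = 2
    radius_i: int = 1
    w_ee: float = 5.0
    w_ie: float = 20.0
    tau_e: float = 40.0
    tau_i: float = 20.0
    dt: float = 1.0
    divergence_bound: float = 1e6

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if min(self.n_rows, self.n_cols) < 1:
            raise ValueError("grid must be nonempty")
        if self.radius_e < 0 or self.radius_i < 0:
            raise ValueError("radii must be >= 0")
        if min(self.tau_e, self.tau_i, self.dt) <= 0:
            raise ValueError("tau_e, tau_i, dt must be positive")
        if self.radius_e >= max(self.n_rows, self.n_cols) or self.radius_i >= max(
            self.n_rows, self.n_cols
        ):
            warnings.warn(
                "neighborhood radius spans the whole grid; neighborhoods saturate",
                stacklevel=2,
            )

    @property
    def n_exc(self) -> int:
        return self.n_rows * self.n_cols * self.n_channels

    @property
    def n_inh(self) -> int:
        return self.n_exc

    @property
    def w_ei(self) -> float:
        """Uniform I-to-E weight, -1/N_i."""
        return -1.0 / self.n_inh

    def flat_index(self, r: int, c: int, d: int) -> int:
        return (r * self.n_cols + c) * self.n_channels + d

    def unflatten(self, k: int) -> tuple[int, int, int]:
        d = k % self.n_channels
        rc = k // self.n_channels
        return rc // self.n_cols, rc % self.n_cols, d


@dataclass
class Connectivity:
    """Weight matrices over the flattened neuron index.

    W_ee is dense with a fixed boolean support mask (plastic entries only);
    W_ie is sparse CSR; the I-to-E projection is uniform -1/N_i and stored as
    the scalar ``w_ei``.
    """

    w_ee: np.ndarray
    mask_ee: np.ndarray
    w_ie: sp.csr_matrix
    w_ei: float
    config: NetworkConfig
    ne_sizes: np.ndarray = field(default=None)  # |NE(k)| per row, clipped

    @property
    def plastic_mask(self) -> np.ndarray:
        """E-E support minus the self-connections.

        Autapses exist in the wiring (the excitatory neighborhood contains
        the neuron itself) but are excluded from associative plasticity:
        Hebbian self-association turns single active neurons into
        self-amplifying loops that destabilize the supralinear dynamics, and
        associative rules classically exclude the self term.
        """
        m = self.mask_ee.copy()
        np.fill_diagonal(m, False)
        return m

    def block_matrix(self) -> np.ndarray:
        """Dense stacked connectivity [[W_ee, W_ei], [W_ie, 0]]."""
        n = self.config.n_exc
        W = np.zeros((2 * n, 2 * n))
        W[:n, :n] = self.w_ee
        W[:n, n:] = self.w_ei
        W[n:, :n] = self.w_ie.toarray()
        return W

    def row_sums(self) -> np.ndarray:
        return self.w_ee.sum(axis=1)

    def copy(self) -> "Connectivity":
        return Connectivity(
            w_ee=self.w_ee.copy(),
            mask_ee=self.mask_ee,
            w_ie=self.w_ie,
            w_ei=self.w_ei,
            config=self.config,
            ne_sizes=self.ne_sizes,
        )

    def save(self, path) -> None:
        coo = sp.coo_matrix(self.w_ee * self.mask_ee)
        np.savez(
            path,
            ee_row=coo.row,
            ee_col=coo.col,
            ee_val=coo.data,
            mask_row=np.flatnonzero(self.mask_ee) // self.mask_ee.shape[1],
            mask_col=np.flatnonzero(self.mask_ee) % self.mask_ee.shape[1],
            config=np.array(
                [
                    self.config.n_rows,
                    self.config.n_cols,
                    self.config.n_channels,
                    self.config.radius_e,
                    self.config.radius_i,
                ]
            ),
            config_f=np.array(
                [
                    self.config.w_ee,
                    self.config.w_ie,
                    self.config.tau_e,
                    self.config.tau_i,
                    self.config.dt,
                ]
            ),
        )

    @classmethod
    def load(cls, path) -> "Connectivity":
        with np.load(path) as z:
            ints = z["config"]
            fl = z["config_f"]
            cfg = NetworkConfig(
                n_rows=int(ints[0]),
                n_cols=int(ints[1]),
                n_channels=int(ints[2]),
                radius_e=int(ints[3]),
                radius_i=int(ints[4]),
                w_ee=float(fl[0]),
                w_ie=float(fl[1]),
                tau_e=float(fl[2]),
                tau_i=float(fl[3]),
                dt=float(fl[4]),
            )
            conn = build_connectivity(cfg)
            conn.w_ee[:] = 0.0
            conn.w_ee[z["ee_row"], z["ee_col"]] = z["ee_val"]
        return conn


@dataclass
class NetworkState:
    r_e: np.ndarray
    r_i: np.ndarray
    t: float = 0.0


@dataclass
class FixedPointRecord:
    """Converged steady-state excitatory response for one stimulus."""

    stimulus_id: int
    noise_level: float
    sample_index: int
    r_star: np.ndarray
    residual: float
    converged: bool
    target_id: int = -1


def _square_neighborhood(r, c, radius, n_rows, n_cols):
    rows = range(max(0, r - radius), min(n_rows, r + radius + 1))
    cols = range(max(0, c - radius), min(n_cols, c + radius + 1))
    return [(rr, cc) for rr in rows for cc in cols]


def build_connectivity(config: NetworkConfig) -> Connectivity:
    """Build masks and initial weights from the hypercolumn geometry.

    Neighborhoods are clipped at grid borders (no wraparound); row
    initialization and the per-row W_ie normalization use the actual clipped
    neighborhood sizes so row sums are exact everywhere.  For interior neurons
    |NE(k)| = N_d (2 R_e + 1)^2 and |NI(k)| = (2 R_i + 1)^2 + N_d - 1.
    """
    n_e = config.n_exc
    nd = config.n_channels
    mask = np.zeros((n_e, n_e), dtype=bool)
    ne_sizes = np.zeros(n_e, dtype=int)
    w_ee = np.zeros((n_e, n_e))

    ie_rows, ie_cols, ie_vals = [], [], []
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            hood_e = _square_neighborhood(r, c, config.radius_e, config.n_rows, config.n_cols)
            cols_e = np.array(
                [config.flat_index(rr, cc, d) for rr, cc in hood_e for d in range(nd)]
            )
            hood_i = _square_neighborhood(r, c, config.radius_i, config.n_rows, config.n_cols)
            for d in range(nd):
                k = config.flat_index(r, c, d)
                mask[k, cols_e] = True
                ne_sizes[k] = cols_e.size
                w_ee[k, cols_e] = config.w_ee / cols_e.size
                # inhibitory neuron k: same-channel surround + own hypercolumn
                pre = {config.flat_index(rr, cc, d) for rr, cc in hood_i}
                pre.update(
                    config.flat_index(r, c, dd) for dd in range(nd) if dd != d
                )
                pre = sorted(pre)
                ie_rows.extend([k] * len(pre))
                ie_cols.extend(pre)
                ie_vals.extend([config.w_ie / len(pre)] * len(pre))

    w_ie = sp.csr_matrix(
        (ie_vals, (ie_rows, ie_cols)), shape=(config.n_inh, n_e)
    )
    return Connectivity(
        w_ee=w_ee,
        mask_ee=mask,
        w_ie=w_ie,
        w_ei=config.w_ei,
        config=config,
        ne_sizes=ne_sizes,
    )


def exc_net_input(conn: Connectivity, r_e: np.ndarray, r_i: np.ndarray,
                  alpha: np.ndarray) -> np.ndarray:
    """Total synaptic input to the excitatory population.

    The uniform -1/N_i inhibitory feedback reduces to subtracting the mean
    inhibitory rate.
    """
    return conn.w_ee @ r_e - float(np.mean(r_i)) + alpha


def step(state: NetworkState, conn: Connectivity, alpha: np.ndarray,
         config: NetworkConfig) -> NetworkState:
    """One forward-Euler step; the inhibitory update sees the pre-update r_e."""
    r_e, r_i = state.r_e, state.r_i
    z_e = exc_net_input(conn, r_e, r_i, alpha)
    r_e_new = r_e + (config.dt / config.tau_e) * (-r_e + activation(z_e))
    r_i_new = r_i + (config.dt / config.tau_i) * (-r_i + activation(conn.w_ie @ r_e))
    _check_bounded(r_e_new, r_i_new, config)
    return NetworkState(r_e=r_e_new, r_i=r_i_new, t=state.t + config.dt)


def _check_bounded(r_e, r_i, config):
    if not np.all(np.isfinite(r_e)) or np.max(r_e, initial=0.0) > config.divergence_bound:
        raise InstabilityError("excitatory population rate exceeded the divergence bound")
    if not np.all(np.isfinite(r_i)) or np.max(r_i, initial=0.0) > config.divergence_bound:
        raise InstabilityError("inhibitory population rate exceeded the divergence bound")


def _integrate(conn, alpha, config, max_T, tol, tail_T=20.0, collect_trace=False):
    """Inner Euler loop used by both the fixed-point solver and tracing.

    Runs from the zero state until the max-norm step change stays below
    ``tol`` for ``tail_T`` consecutive time units (or max_T).  Returns the
    final state, the average of r_e over the final ``tail_T`` time units, the
    last step residual, the convergence flag, and optionally the full trace.
    """
    dt = config.dt
    n_steps = int(np.ceil(max_T / dt))
    tail_len = max(1, int(round(tail_T / dt)))
    r_e = np.zeros(conn.config.n_exc)
    r_i = np.zeros(conn.config.n_inh)
    tail = np.zeros((tail_len, r_e.size))
    trace = [] if collect_trace else None
    quiet = 0
    residual = np.inf
    converged = False
    inv_te, inv_ti = dt / config.tau_e, dt / config.tau_i
    w_ee, w_ie = conn.w_ee, conn.w_ie
    for it in range(n_steps):
        z_e = w_ee @ r_e - float(np.mean(r_i)) + alpha
        r_e_new = r_e + inv_te * (-r_e + activation(z_e))
        r_i_new = r_i + inv_ti * (-r_i + activation(w_ie @ r_e))
        _check_bounded(r_e_new, r_i_new, config)
        delta = max(
            float(np.max(np.abs(r_e_new - r_e), initial=0.0)),
            float(np.max(np.abs(r_i_new - r_i), initial=0.0)),
        )
        r_e, r_i = r_e_new, r_i_new
        tail[it % tail_len] = r_e
        if collect_trace:
            trace.append(r_e.copy())
        residual = delta
        quiet = quiet + 1 if delta < tol else 0
        if quiet * dt >= tail_T and (it + 1) >= tail_len:
            converged = True
            break
    filled = min(it + 1, tail_len)
    r_star = tail[:filled].mean(axis=0) if filled else r_e
    state = NetworkState(r_e=r_e, r_i=r_i, t=(it + 1) * dt)
    return state, r_star, residual, converged, trace


def run_to_fixed_point(
    conn: Connectivity,
    alpha: np.ndarray,
    config: NetworkConfig,
    max_T: float = 1000.0,
    tol: float = 1e-6,
    stimulus_id: int = -1,
    noise_level: float = 0.0,
    sample_index: int = 0,
    target_id: int = -1,
) -> FixedPointRecord:
    """Integrate from the zero state to the stimulus-specific attractor.

    Convergence requires the max-norm step change to stay below ``tol`` for
    20 consecutive time units; r_star is the time-average of r_e over the
    final 20 time units.  Non-convergence returns converged=False rather than
    raising.
    """
    _, r_star, residual, converged, _ = _integrate(conn, alpha, config, max_T, tol)
    return FixedPointRecord(
        stimulus_id=stimulus_id,
        noise_level=noise_level,
        sample_index=sample_index,
        r_star=r_star,
        residual=residual,
        converged=converged,
        target_id=target_id,
    )


def simulate_trace(conn: Connectivity, alpha: np.ndarray, config: NetworkConfig,
                   T: float) -> np.ndarray:
    """Excitatory population trace (T/dt steps x N_e) from the zero state."""
    _, _, _, _, trace = _integrate(
        conn, alpha, config, max_T=T, tol=-1.0, collect_trace=True
    )
    return np.asarray(trace)
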