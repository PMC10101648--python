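"""Reservoir model of the cerebellum trained by node-perturbation learning.

The cerebellar cortex is modelled as a single recurrent pool of ``tanh``
units (granule/Golgi recurrence; a fixed subset of units plays the role of
Purkinje output cells).  Dynamics::

    tau dx_i/dt = -x_i + sum_j J_ij r_j + sum_k B_ik u_k,     r_i = tanh(x_i)

where ``u`` is a one-hot goal input, ``B`` are fixed input weights drawn from
U(-0.2, 0.2) and ``J`` are the plastic recurrent weights, initialised from
N(0, 0.05).

Exploration comes from random perturbations: at every 1-ms step each unit is
kicked with probability ``f / 1000`` (``f`` in events per second) by a draw
from U(-A, A).  Each synapse accumulates a cubic eligibility trace

    e_ij(t) = e_ij(t-1) + (r_j(t-1) (x_i(t) - xbar_i))^3

whose supralinearity makes perturbation events dominate the trace.  After a
trial with scalar aiming error ``E`` the weights move against the trace when
the error exceeded its running per-goal mean ``Ebar``::

    dJ_ij = -eta e_ij Ebar (E - Ebar)

so perturbations that reduced the error are reinforced.  ``Ebar`` is an
exponential moving average kept independently for every goal.

Because the kicks enter the trace cubed, the raw trace is unbounded; the
implemented update uses the trace *pattern* (normalised by its largest
element) with the error factors setting a step size that anneals as the
per-goal error stabilises.  Three calibrated guards shape the update: a
per-trial per-synapse cap (``max_dw``), an eligibility gate (only synapses
with ``|e|`` above ``e_gate`` of the maximum are plastic, confining the
random-walk load to perturbation-tagged synapses), and a weight cap
(``|J| <= j_cap``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .cpg import PARAM_NAMES, PARAM_BOUNDS

__all__ = [
    "ReservoirParams",
    "Reservoir",
    "trace_increment",
    "outputs_to_params",
    "outputs_to_correction",
    "outputs_to_angles",
    "param_grid_bounds",
]


@dataclass(frozen=True)
class ReservoirParams:
    """Reservoir size, noise, and learning constants.

    ``f`` is the perturbation frequency in events per second per neuron,
    ``A`` the perturbation amplitude, ``eta`` the learning rate; the trio
    controls the exploration noise.  ``tau`` (ms) is the unit time constant,
    ``xbar_tau`` the averaging window for the activation mean used in the
    eligibility trace, and ``ebar_alpha`` the update coefficient of the
    per-goal error mean.  ``max_dw`` and ``j_cap`` are numerical guards
    (calibrated; see the methods note).
    """

    n_units: int = 400
    n_outputs: int = 24
    tau: float = 10.0
    f: float = 9.0
    A: float = 20.0
    eta: float = 0.8
    input_weight_range: float = 0.2
    init_weight_sd: float = 0.05
    x_init_range: float = 0.01
    xbar_tau: float = 5.0
    ebar_alpha: float = 0.2
    max_dw: float = 1e-2
    e_gate: float = 1e-3
    j_cap: float = 1.0
    dt: float = 1.0
    input_ms: float = 200.0
    free_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.f < 0 or self.A < 0 or self.eta < 0:
            raise ValueError("f, A and eta must be non-negative")
        if self.n_outputs > self.n_units:
            raise ValueError("n_outputs cannot exceed n_units")


def trace_increment(r_prev: np.ndarray, x: np.ndarray, x_bar: np.ndarray) -> np.ndarray:
    """Single-step eligibility increment ``(r_j(t-1) (x_i(t) - xbar_i))^3``.

    Returns the full (post, pre) matrix.  The cube is separable, so the
    increment factorises as ``outer((x - xbar)^3, r_prev^3)``; the trial loop
    exploits this to accumulate the trace as one matrix product.
    """
    return np.multiply.outer((x - x_bar) ** 3, r_prev**3)


@njit(cache=True, fastmath=True)
def _trial_kernel(J, drive, x0, mask_rand, kicks, p_perturb, leak, bar_coef,
                  n_in, n_free, n_out, collect):  # pragma: no cover - numba
    T = n_in + n_free
    n = J.shape[0]
    x = x0.copy()
    x_bar = x0.copy()
    r = np.tanh(x)
    rows = T if collect else 1
    post3 = np.zeros((rows, n), dtype=np.float32)
    pre3 = np.zeros((rows, n), dtype=np.float32)
    out_sum = np.zeros(n_out, dtype=np.float32)
    for t in range(T):
        xin = np.dot(J, r)
        for i in range(n):
            inp = xin[i] + drive[i] if t < n_in else xin[i]
            xi = x[i] + leak * (inp - x[i])
            if mask_rand[t, i] < p_perturb:
                xi += kicks[t, i]
            dev = xi - x_bar[i]
            x_bar[i] += bar_coef * dev
            if collect:
                post3[t, i] = dev * dev * dev
                pre3[t, i] = r[i] * r[i] * r[i]  # r still holds r(t-1) here
            x[i] = xi
        for i in range(n):
            r[i] = np.tanh(x[i])
        if t >= n_in:
            for o in range(n_out):
                out_sum[o] += r[o]
    return out_sum, post3, pre3


class Reservoir:
    """A perturbation-learning reservoir with per-goal error baselines.

    Parameters
    ----------
    params
        Network constants.
    n_goals
        Number of goal-identity input cells (one-hot input).
    rng
        Generator for weight initialisation and perturbation noise.
    """

    def __init__(self, params: ReservoirParams, n_goals: int, rng: np.random.Generator):
        self.params = params
        self.n_goals = int(n_goals)
        self.rng = rng
        n = params.n_units
        # float32 state: the dynamics are noise-driven and the weight updates
        # are orders of magnitude above float32 resolution at these scales.
        self.J = rng.normal(0.0, params.init_weight_sd, (n, n)).astype(np.float32)
        self.B = rng.uniform(-params.input_weight_range, params.input_weight_range,
                             (n, self.n_goals)).astype(np.float32)
        self.E_bar: dict = {}
        self.e = np.zeros((n, n), dtype=np.float32)

    def run_trial(self, goal_id, learn: bool = True) -> np.ndarray:
        """Simulate one trial and return the 24 output values.

        The state is reset to U(-x_init_range, x_init_range); the goal input
        is on for ``input_ms`` and off for ``free_ms``; the output is the mean
        rate of the output units over the free phase.  The eligibility trace
        is reset at trial start and accumulated throughout; ``learn=False``
        skips trace collection only (perturbations depend solely on ``f``
        and ``A``).
        """
        p = self.params
        n = p.n_units
        rng = self.rng
        u_vec = np.zeros(self.n_goals, dtype=np.float32)
        u_vec[self._goal_index(goal_id)] = 1.0
        input_drive = self.B @ u_vec

        x0 = rng.uniform(-p.x_init_range, p.x_init_range, n).astype(np.float32)
        n_in = int(round(p.input_ms / p.dt))
        n_free = int(round(p.free_ms / p.dt))
        T = n_in + n_free
        # Perturbation draws are made up front so the whole trial is a pure
        # function of the generator state (one Bernoulli and one amplitude
        # draw per unit per step).
        if p.f > 0.0 and p.A > 0.0:
            mask_rand = rng.random((T, n), dtype=np.float32)
            kicks = ((rng.random((T, n), dtype=np.float32) * 2.0 - 1.0)
                     * np.float32(p.A))
            p_perturb = np.float32(p.f * p.dt / 1000.0)
        else:
            mask_rand = np.ones((T, n), dtype=np.float32)
            kicks = np.zeros((T, n), dtype=np.float32)
            p_perturb = np.float32(-1.0)

        out_sum, post3, pre3 = _trial_kernel(
            self.J, input_drive, x0, mask_rand, kicks, p_perturb,
            np.float32(p.dt / p.tau), np.float32(p.dt / p.xbar_tau),
            n_in, n_free, p.n_outputs, bool(learn))
        if learn:
            self.e = post3.T @ pre3
        return (out_sum / np.float32(n_free)).astype(float)

    def apply_learning(self, goal_id, error: float) -> None:
        """Update ``J`` from the last trial's trace and the goal's error history."""
        if error < 0 or not np.isfinite(error):
            raise ValueError(f"error must be finite and non-negative, got {error}")
        p = self.params
        key = self._key(goal_id)
        e_bar = self.E_bar.get(key)
        if e_bar is not None:
            # The cubic trace is unbounded (perturbation kicks enter cubed),
            # so its *pattern*, normalised by its largest element, is used;
            # the error factors of the learning rule set the step magnitude,
            # which therefore anneals as the per-goal error stabilises.
            # max_dw caps the per-trial per-synapse step.  Synapses whose
            # trace is below e_gate of the maximum are left untouched:
            # plasticity is confined to the perturbation-tagged synapses
            # that carry the exploration signal.
            e_max = float(np.abs(self.e).max())
            if e_max > 0.0:
                dj = self.e * np.float32(-p.eta * e_bar * (error - e_bar) / e_max)
                np.clip(dj, np.float32(-p.max_dw), np.float32(p.max_dw), out=dj)
                if p.e_gate > 0.0:
                    dj[np.abs(self.e) < np.float32(p.e_gate * e_max)] = 0.0
                self.J += dj
                np.clip(self.J, np.float32(-p.j_cap), np.float32(p.j_cap), out=self.J)
            self.E_bar[key] = (1.0 - p.ebar_alpha) * e_bar + p.ebar_alpha * error
        else:
            # First observation of this goal seeds the baseline; no update.
            self.E_bar[key] = float(error)

    def _goal_index(self, goal_id) -> int:
        idx = goal_id[0] if isinstance(goal_id, tuple) else goal_id
        idx = int(idx)
        if not 0 <= idx < self.n_goals:
            raise IndexError(f"goal index {idx} out of range [0, {self.n_goals})")
        return idx

    @staticmethod
    def _key(goal_id):
        return goal_id if isinstance(goal_id, tuple) else int(goal_id)


# -- Output mappings ---------------------------------------------------------

def param_grid_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper clamp bounds for the 24-vector (joint-major, 6 per joint)."""
    lo = np.array([PARAM_BOUNDS[n][0] for n in PARAM_NAMES])
    hi = np.array([PARAM_BOUNDS[n][1] for n in PARAM_NAMES])
    return np.tile(lo, 4), np.tile(hi, 4)


def outputs_to_params(outputs: np.ndarray) -> np.ndarray:
    """Cerebellum-alone readout: map [-1, 1] outputs affinely onto each
    parameter's clamp interval (24 values -> (4, 6) parameter array)."""
    lo, hi = param_grid_bounds()
    vals = (np.asarray(outputs) + 1.0) / 2.0 * (hi - lo) + lo
    return vals.reshape(4, 6)


def outputs_to_correction(outputs: np.ndarray, scale: float = 0.25) -> np.ndarray:
    """Full-model readout: scale outputs by ``scale`` of each parameter's
    interval width.  The default lets a saturated output cell move a
    parameter across a quarter of its interval - enough authority to
    displace the endpoint across the workspace when several outputs
    cooperate, small enough that the reservoir's exploration noise stays a
    fine-tuning signal rather than motor chaos."""
    lo, hi = param_grid_bounds()
    return (np.asarray(outputs) * (hi - lo) * scale).reshape(4, 6)


def outputs_to_angles(outputs: np.ndarray, scale: float = 5.0) -> np.ndarray:
    """Direct joint-angle readout (control variant without CPGs): the first
    four outputs are scaled to angles, matching the CPG excursion ``Amp``."""
    return scale * np.asarray(outputs)[:4]
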