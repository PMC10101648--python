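"""Central pattern generators driving the four arm joints.

Each joint is controlled by an independent three-layer CPG network:

* a *rhythm-generation* (RG) layer of two conditional oscillator cells
  (extensor ``e`` and flexor ``f``), each governed by a fast membrane
  potential ``V`` with an N-shaped fast current and a lumped slow current
  ``q``::

      tau_m dV/dt = -(V - A_f tanh((sigma_f/A_f) V) + q - i_inj)
      tau_s dq/dt = -q + sigma_s (V - E_s),          tau_s = 20 tau_m

* a *pattern-formation* (PF) layer applying a parameterised logistic to the
  RG output, and
* a *motor-neuron* (MN) layer with a fixed-slope logistic.

The final joint angle combines the two mirrored chains,
``U = Amp (MN_E - MN_F) + U_ref``, so ``|U - U_ref| <= Amp`` always.

Six parameters per joint (``tau_m``, ``sigma_f``, ``sigma_s``, ``i_inj``,
``alpha_0``, ``theta_0``) are the quantities set by the upstream action
selection and cerebellar correction; everything else is fixed.  A "movement"
is the deterministic map from a full 24-value parameter set to the joint
angles read out at the end of a fixed integration window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "CPGFixedParams",
    "CPGParams",
    "CPGState",
    "clamp_params",
    "clamp_param_array",
    "pf_activation",
    "mn_activation",
    "joint_angle",
    "rg_step",
    "execute_movement",
    "IntegrationError",
]

#: Order of the six tunable parameters per joint.
PARAM_NAMES = ("tau_m", "sigma_f", "sigma_s", "i_inj", "alpha_0", "theta_0")

#: Clamp interval for each tunable parameter.
PARAM_BOUNDS = {
    "tau_m": (5.0, 15.0),
    "sigma_f": (5.0, 10.0),
    "sigma_s": (5.0, 10.0),
    "i_inj": (-4.0, 4.0),
    "alpha_0": (0.001, 2.0),
    "theta_0": (0.001, 2.0),
}

_LO = np.array([PARAM_BOUNDS[n][0] for n in PARAM_NAMES])
_HI = np.array([PARAM_BOUNDS[n][1] for n in PARAM_NAMES])


class IntegrationError(RuntimeError):
    """Raised when the CPG integration diverges past the guard value."""


@dataclass(frozen=True)
class CPGFixedParams:
    """Fixed CPG constants shared by all joints.

    ``E_s`` (slow-current reversal) and the symmetry-breaking RG initial
    conditions are not part of the printed constant set; their defaults are
    calibrated choices (see the methods note) and are configurable here.
    """

    A_f: float = 5.0
    tau_s_factor: float = 20.0
    alpha_PF: float = 1.0
    theta_PF: float = 0.0
    W_rg: float = 1.0
    W_pf: float = 1.0
    Amp: float = 5.0
    E_s: float = 0.0
    U_ref: float = 0.0
    v_init_e: float = 0.1
    v_init_f: float = -0.1
    v_guard: float = 1e6
    readout_ms: float = 3000.0


@dataclass(frozen=True)
class CPGParams:
    """The six tunable parameters of one joint's CPG."""

    tau_m: float
    sigma_f: float
    sigma_s: float
    i_inj: float
    alpha_0: float
    theta_0: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not np.isfinite(v) or v < lo or v > hi:
                raise ValueError(f"{name}={v} outside clamp range [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])


@dataclass
class CPGState:
    """Instantaneous state of one joint's CPG (both half-center chains)."""

    V_e: float = 0.1
    V_f: float = -0.1
    q_e: float = 0.0
    q_f: float = 0.0
    PF_e: float = 0.5
    PF_f: float = 0.5
    MN_e: float = 0.5
    MN_f: float = 0.5
    U: float = 0.0


def clamp_params(raw) -> CPGParams:
    """Project six raw values onto the per-parameter clamp intervals."""
    arr = np.asarray(raw, dtype=float)
    if arr.shape != (6,):
        raise ValueError(f"expected 6 parameter values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"parameter values must be finite, got {arr}")
    clipped = np.clip(arr, _LO, _HI)
    return CPGParams(*clipped)


def clamp_param_array(raw: np.ndarray) -> np.ndarray:
    """Vectorised clamp for arrays of shape (..., 6) in :data:`PARAM_NAMES` order."""
    arr = np.asarray(raw, dtype=float)
    if arr.shape[-1] != 6:
        raise ValueError("last axis must hold the 6 CPG parameters")
    return np.clip(arr, _LO, _HI)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def pf_activation(rg_input, sensory=(), params: CPGParams | None = None,
                  fixed: CPGFixedParams | None = None, sensory_weights=()) -> float:
    """Pattern-formation activation: normalised drive through a tunable logistic.

    The drive is ``(W_rg * RG + sum_j W_j S_j) / (n + 1)`` for ``n`` sensory
    inputs; the model runs open loop so sensory weights default to zero.
    """
    fixed = fixed or CPGFixedParams()
    if params is None:
        raise ValueError("pf_activation requires the tunable CPG parameters")
    s = np.asarray(sensory, dtype=float)
    w = np.asarray(sensory_weights, dtype=float) if len(np.atleast_1d(sensory_weights)) else np.zeros_like(s)
    drive = (fixed.W_rg * rg_input + float(np.sum(w * s))) / (s.size + 1)
    return float(_logistic(params.alpha_0 * fixed.alpha_PF * (drive - (params.theta_0 + fixed.theta_PF))))


def mn_activation(pf, sensory=(), fixed: CPGFixedParams | None = None,
                  sensory_weights=()) -> float:
    """Motor-neuron activation: fixed-slope logistic centred at drive 0.5."""
    fixed = fixed or CPGFixedParams()
    s = np.asarray(sensory, dtype=float)
    w = np.asarray(sensory_weights, dtype=float) if len(np.atleast_1d(sensory_weights)) else np.zeros_like(s)
    drive = (fixed.W_pf * pf + float(np.sum(w * s))) / (s.size + 1)
    return float(_logistic(5.0 * (drive - 0.5)))


def joint_angle(mn_e: float, mn_f: float, fixed: CPGFixedParams | None = None) -> float:
    """Joint angle from the extensor/flexor motor-neuron pair."""
    fixed = fixed or CPGFixedParams()
    return fixed.Amp * (mn_e - mn_f) + fixed.U_ref


def _rg_derivs(v, q, params: CPGParams, fixed: CPGFixedParams):
    dv = -(v - fixed.A_f * np.tanh((params.sigma_f / fixed.A_f) * v) + q - params.i_inj) / params.tau_m
    dq = (-q + params.sigma_s * (v - fixed.E_s)) / (fixed.tau_s_factor * params.tau_m)
    return dv, dq


def rg_step(state: CPGState, params: CPGParams, fixed: CPGFixedParams | None = None,
            dt: float = 1.0) -> CPGState:
    """One explicit-Euler step of both RG cells; refreshes PF/MN/U readouts.

    The two chains are antagonists: the extensor pattern-formation cell is
    driven by its rhythm cell, the flexor one by the *inhibitory mirror* of
    its rhythm cell, so the joint command reflects the balance between them.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    fixed = fixed or CPGFixedParams()
    dve, dqe = _rg_derivs(state.V_e, state.q_e, params, fixed)
    dvf, dqf = _rg_derivs(state.V_f, state.q_f, params, fixed)
    v_e = state.V_e + dt * dve
    v_f = state.V_f + dt * dvf
    q_e = state.q_e + dt * dqe
    q_f = state.q_f + dt * dqf
    pf_e = pf_activation(v_e, params=params, fixed=fixed)
    pf_f = pf_activation(-v_f, params=params, fixed=fixed)
    mn_e = mn_activation(pf_e, fixed=fixed)
    mn_f = mn_activation(pf_f, fixed=fixed)
    return CPGState(v_e, v_f, q_e, q_f, pf_e, pf_f, mn_e, mn_f,
                    joint_angle(mn_e, mn_f, fixed))


@njit(cache=True)
def _integrate_kernel(params, a_f, tau_s_factor, e_s, alpha_pf, theta_pf,
                      w_rg, w_pf, dt, n_steps, readout_steps,
                      v_init_e, v_init_f, v_guard):  # pragma: no cover - numba
    n_joints = params.shape[0]
    v_e = np.full(n_joints, v_init_e)
    v_f = np.full(n_joints, v_init_f)
    q_e = np.zeros(n_joints)
    q_f = np.zeros(n_joints)
    mn_diff = np.zeros(n_joints)
    count = 0
    for step in range(n_steps):
        for j in range(n_joints):
            tau_m = params[j, 0]
            sigma_f = params[j, 1]
            sigma_s = params[j, 2]
            i_inj = params[j, 3]
            tau_s = tau_s_factor * tau_m
            dve = -(v_e[j] - a_f * np.tanh((sigma_f / a_f) * v_e[j]) + q_e[j] - i_inj) / tau_m
            dqe = (-q_e[j] + sigma_s * (v_e[j] - e_s)) / tau_s
            dvf = -(v_f[j] - a_f * np.tanh((sigma_f / a_f) * v_f[j]) + q_f[j] - i_inj) / tau_m
            dqf = (-q_f[j] + sigma_s * (v_f[j] - e_s)) / tau_s
            v_e[j] += dt * dve
            q_e[j] += dt * dqe
            v_f[j] += dt * dvf
            q_f[j] += dt * dqf
            if abs(v_e[j]) > v_guard or abs(v_f[j]) > v_guard:
                return v_e, v_f, q_e, q_f, mn_diff, False
        if step >= n_steps - readout_steps:
            for j in range(n_joints):
                alpha_0 = params[j, 4]
                theta_0 = params[j, 5]
                # antagonist wiring: the flexor pattern-formation cell
                # receives the inhibitory mirror of its rhythm cell
                pf_e = 1.0 / (1.0 + np.exp(-alpha_0 * alpha_pf
                                           * (w_rg * v_e[j] - theta_0 - theta_pf)))
                pf_f = 1.0 / (1.0 + np.exp(-alpha_0 * alpha_pf
                                           * (-w_rg * v_f[j] - theta_0 - theta_pf)))
                mn_e = 1.0 / (1.0 + np.exp(-5.0 * (w_pf * pf_e - 0.5)))
                mn_f = 1.0 / (1.0 + np.exp(-5.0 * (w_pf * pf_f - 0.5)))
                mn_diff[j] += mn_e - mn_f
            count += 1
    return v_e, v_f, q_e, q_f, mn_diff / count, True


def execute_movement(params_per_joint, fixed: CPGFixedParams | None = None,
                     duration: float = 4000.0, dt: float = 1.0,
                     u_ref=None) -> np.ndarray:
    """Integrate all four CPGs and return the final joint angles.

    Parameters
    ----------
    params_per_joint
        Sequence of four :class:`CPGParams`, or an array of shape (4, 6) in
        :data:`PARAM_NAMES` order (values must already be clamped).
    fixed
        Shared fixed constants.
    duration, dt
        Integration window and Euler step, both in ms.
    u_ref
        Optional per-joint reference angles (defaults to ``fixed.U_ref``).

    Returns
    -------
    ndarray of shape (4,)
        Final joint angles (pitch, yaw, roll, elbow) in radians: the mean
        motor command over the last ``readout_ms`` of the movement (the
        posture the oscillating command settles around), not a single-step
        phase snapshot.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    fixed = fixed or CPGFixedParams()
    if isinstance(params_per_joint, np.ndarray):
        p = clamp_param_array(params_per_joint)
    else:
        p = np.stack([q.as_array() if isinstance(q, CPGParams) else np.asarray(q, float)
                      for q in params_per_joint])
        p = clamp_param_array(p)
    if p.shape != (4, 6):
        raise ValueError(f"expected parameters for 4 joints, got shape {p.shape}")
    n_steps = int(round(duration / dt))
    readout_steps = max(1, min(n_steps, int(round(fixed.readout_ms / dt))))
    _, _, _, _, mn_diff, ok = _integrate_kernel(
        np.ascontiguousarray(p), fixed.A_f, fixed.tau_s_factor, fixed.E_s,
        fixed.alpha_PF, fixed.theta_PF, fixed.W_rg, fixed.W_pf,
        dt, n_steps, readout_steps,
        fixed.v_init_e, fixed.v_init_f, fixed.v_guard,
    )
    if not ok:
        raise IntegrationError("CPG membrane potential exceeded the guard value")
    refs = np.full(4, fixed.U_ref) if u_ref is None else np.asarray(u_ref, float)
    return fixed.Amp * mn_diff + refs
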