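"""Rate-coded motor cortex-basal ganglia loop with novelty-gated plasticity.

The loop holds one discrete channel per *concrete action* (a full 24-value
CPG parameter set): premotor input cells with Gaussian spatial tuning project
through plastic weights to striatum D1; each striatal channel inhibits its
SNr channel, which tonically inhibits its thalamic channel, which excites its
motor-cortex channel; the cortex feeds back onto its striatal channel.  All
populations follow the linear-rectified rate dynamics::

    tau dmp_j/dt + mp_j = sum_exc w r - sum_inh w r + B + eps_j,   r_j = mp_j^+

Action selection: a goal position sets the premotor baselines through a
Gaussian tuning curve; after 200 ms the most active cortex channel is clamped
to 1 if it exceeds a threshold, otherwise a uniformly random channel is
clamped (exploration).  Fixed random weights from the cortex channels fan out
to value-tuned parameter populations whose population-vector readout yields
the action's 24 CPG parameters.

Learning is an act-and-sense scheme: after the movement, the *achieved*
outcome is encoded in the premotor input and a dopamine cell gates Hebbian
plasticity.  The dopamine burst is the difference between a movement-gated
drive and a learned striatal prediction, so it signals outcome *novelty* and
shrinks as an outcome becomes familiar:

    tau_DA dDA/dt + DA = P (1 - sum_i wDA_i r_i) + B_DA
    tau_w  dw_ij/dt    = f_DA(DA - B_DA) C_ij - alpha (r_j - rbar_post)^2
    C_ij = ((r_i - rbar_pre - gamma_pre)(r_j - rbar_post - gamma_post))^+
    tau_w dwDA_i/dt    = 3 (DA - B_DA) (r_i - rbar_pre)^+

``f_DA`` has slope ``K_b`` for positive phasic dopamine and ``K_d`` for
negative.  All rates and plastic weights are floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinematics
from .cpg import clamp_param_array
from .cerebellum import param_grid_bounds

__all__ = ["BGParams", "ActionLibrary", "BGNetwork"]


@dataclass(frozen=True)
class BGParams:
    """Fixed constants of the loop.

    The time constant, fixed weights, baselines and plasticity thresholds
    carry their printed values.  ``K_b``, ``K_d``, ``alpha_norm``, ``tau_w``,
    ``tau_DA``, ``noise_amplitude``, ``B_cortex``, the premotor population
    geometry and the parameter-population size are calibrated constants
    (see the methods note).  ``B_cortex`` in particular is chosen so the
    resting cortex activity is zero, giving the 0.05 selection threshold the
    sub-threshold random-exploration branch its semantics.
    """

    tau: float = 10.0
    w_str_snr: float = 0.8
    w_snr_thal: float = 0.6
    w_thal_ctx: float = 1.0
    w_ctx_str: float = 0.5
    B_striatum: float = 0.0
    B_snr: float = 1.1
    B_thalamus: float = 0.9
    B_DA: float = 0.1
    gamma_pre: float = 0.0
    gamma_post: float = 0.1
    n_actions: int = 120
    # calibrated constants
    K_b: float = 5.0
    K_d: float = 2.5
    alpha_norm: float = 0.01
    tau_w: float = 100.0
    tau_DA: float = 10.0
    noise_amplitude: float = 0.01
    B_cortex: float = -0.3
    n_premotor: int = 200
    sigma_goal: float = 0.15
    n_param_cells: int = 21
    dt: float = 1.0
    settle_ms: float = 200.0
    goal_ms: float = 200.0
    select_ms: float = 150.0
    sense_ms: float = 100.0
    learn_ms: float = 100.0
    selection_threshold: float = 0.05


class ActionLibrary:
    """Fixed random fan-out from action channels to parameter populations.

    Each of the 24 CPG parameters is represented by ``n_cells`` value-tuned
    cells whose preferred values tile the parameter's clamp interval.  Each
    action channel excites every population through a fixed random weight
    vector, drawn once per run and then frozen: a Gaussian bump of width
    ``bump_sd`` cells around a uniformly random centre cell, on a small
    uniform background, normalised to unit sum.  The bump centre is what
    makes each concrete action a *random point* in parameter space (the
    population-vector decode of a bump is its centre's preferred value);
    a structureless uniform draw would decode every action to near the
    interval midpoint and collapse the movement repertoire.
    """

    def __init__(self, n_actions: int, n_cells: int, rng: np.random.Generator,
                 bump_sd: float = 1.5, background: float = 0.05):
        self.n_actions = n_actions
        self.n_cells = n_cells
        lo, hi = param_grid_bounds()
        #: (24, n_cells) preferred values tiling each clamp interval
        self.preferred = np.linspace(lo, hi, n_cells).T.copy()
        # Bump centres: uniform over each interval, except the
        # posture-setting injected current (drawn U-shaped, favouring strong
        # extensor or flexor drive) and the slow-current conductance (biased
        # low).  Without this bias most random actions produce weak,
        # near-resting postures and the action repertoire does not span the
        # reaching space.
        centres = rng.uniform(0.0, n_cells - 1.0, (n_actions, 24))
        scale = n_cells - 1.0
        i_inj_cols = np.arange(3, 24, 6)
        sigma_s_cols = np.arange(2, 24, 6)
        centres[:, i_inj_cols] = scale * rng.beta(0.4, 0.4, (n_actions, 4))
        centres[:, sigma_s_cols] = scale * rng.beta(1.0, 2.0, (n_actions, 4))
        cells = np.arange(n_cells, dtype=float)
        w = (np.exp(-(cells - centres[..., None]) ** 2 / (2.0 * bump_sd**2))
             + background * rng.uniform(0.0, 1.0, (n_actions, 24, n_cells)))
        self.weights = w / w.sum(axis=2, keepdims=True)

    def screen_stability(self, execute, rng: np.random.Generator,
                         probes=((0.05, 0.05), (0.05, 0.05), (0.10, 0.10)),
                         min_sensitivity: float = 0.01,
                         max_rounds: int = 25) -> int:
        """Redraw actions whose movement endpoint is not well-behaved.

        A concrete action is a stereotyped but *tunable* motor program.  Each
        action is probed with random parameter displacements, one per
        ``(jitter, tol)`` pair: under a ``jitter``-of-range displacement the
        endpoint must move less than ``tol`` workspace units (otherwise the
        action sits in a chaotic zone of the oscillator map, and cerebellar
        corrections of that size scramble the movement).  The first probe must
        also move the endpoint by at least ``min_sensitivity`` (otherwise the
        movement is parameter-dead and the cerebellum has no authority over
        it).  The probe scales cover both the exploration noise (~5% of each
        interval) and trained corrections (~10%).  Failing actions get their
        weight-bump centres redrawn.

        ``execute`` maps a (4, 6) parameter array to a hand position.
        Returns the number of actions that were redrawn at least once.
        """
        lo, hi = param_grid_bounds()
        span = (hi - lo).reshape(4, 6)
        cells = np.arange(self.n_cells, dtype=float)
        scale = self.n_cells - 1.0
        redrawn = 0
        for a in range(self.n_actions):
            for round_ in range(max_rounds):
                base = self.exact_params(a)
                p0 = np.asarray(execute(base))
                ok = True
                for k, (jitter, tol) in enumerate(probes):
                    delta = jitter * span * rng.choice([-1.0, 1.0], size=(4, 6))
                    p1 = np.asarray(execute(clamp_param_array(base + delta)))
                    disp = np.linalg.norm(p1 - p0)
                    if disp > tol or (k == 0 and disp < min_sensitivity):
                        ok = False
                        break
                if ok:
                    break
                if round_ == 0:
                    redrawn += 1
                centre = rng.uniform(0.0, scale, 24)
                centre[3::6] = scale * rng.beta(0.4, 0.4, 4)
                centre[2::6] = scale * rng.beta(1.0, 2.0, 4)
                w = (np.exp(-(cells - centre[:, None]) ** 2 / (2.0 * 1.5**2))
                     + 0.05 * rng.uniform(0.0, 1.0, (24, self.n_cells)))
                self.weights[a] = w / w.sum(axis=1, keepdims=True)
        return redrawn

    def decode(self, rates: np.ndarray) -> np.ndarray:
        """Population-vector readout of (24, n_cells) rates -> clamped (4, 6)."""
        total = rates.sum(axis=1)
        lo, hi = param_grid_bounds()
        mid = (lo + hi) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (rates * self.preferred).sum(axis=1) / total
        vals = np.where(total > 0.0, vals, mid)
        return clamp_param_array(vals.reshape(4, 6))

    def exact_params(self, action: int) -> np.ndarray:
        """Noise-free readout of one action (the decode of its weight row)."""
        return self.decode(self.weights[action])


class BGNetwork:
    """State and dynamics of the motor loop.

    Parameters
    ----------
    params
        Fixed constants.
    rng
        Generator used for the premotor tuning positions, the per-step noise
        terms and random exploration.
    premotor_positions
        Optional (n_premotor, 3) array of preferred positions.  By default
        they are forward-kinematics images of random joint configurations, so
        the population covers exactly the reachable workspace.
    """

    def __init__(self, params: BGParams, rng: np.random.Generator,
                 premotor_positions: np.ndarray | None = None):
        self.p = params
        self.rng = rng
        if premotor_positions is None:
            angles = rng.uniform(-np.pi, np.pi, (params.n_premotor, 4))
            premotor_positions = np.array(
                [kinematics.forward_kinematics(a) for a in angles])
        self.premotor_positions = np.asarray(premotor_positions, float)
        self.library = ActionLibrary(params.n_actions, params.n_param_cells, rng)
        self._w_flat = self.library.weights.reshape(params.n_actions, -1)

        n_a = params.n_actions
        self.b_pre = np.zeros(params.n_premotor)
        self.mp_pre = np.zeros(params.n_premotor)
        self.r_pre = np.zeros(params.n_premotor)
        self.mp_str = np.zeros(n_a)
        self.r_str = np.zeros(n_a)
        self.mp_snr = np.zeros(n_a)
        self.r_snr = np.zeros(n_a)
        self.mp_thal = np.zeros(n_a)
        self.r_thal = np.zeros(n_a)
        self.mp_ctx = np.zeros(n_a)
        self.r_ctx = np.zeros(n_a)
        self.mp_par = np.zeros((24, params.n_param_cells))
        self.r_par = np.zeros((24, params.n_param_cells))
        #: plastic premotor -> striatum weights
        self.W_pre_str = np.zeros((params.n_premotor, n_a))
        #: plastic striatum -> dopamine (prediction) weights
        self.W_str_da = np.zeros(n_a)
        self.DA = params.B_DA
        self.P = 0.0
        self.clamp: int | None = None

    # -- dynamics ----------------------------------------------------------

    def encode_goal(self, goal: np.ndarray | None) -> None:
        """Set premotor baselines from a Gaussian tuning to ``goal``
        (or clear them when ``goal`` is None)."""
        if goal is None:
            self.b_pre = np.zeros(self.p.n_premotor)
            return
        goal = np.asarray(goal, float)
        if not np.all(np.isfinite(goal)):
            raise ValueError("goal position must be finite")
        d2 = np.sum((self.premotor_positions - goal) ** 2, axis=1)
        self.b_pre = np.exp(-d2 / (2.0 * self.p.sigma_goal**2))

    def rate_step(self, learning: bool = False, integrate_params: bool = False,
                  noise: np.ndarray | None = None) -> None:
        """One Euler step of every population (and plasticity if enabled).

        ``noise`` may carry pre-drawn U(-eps, eps) terms for all populations
        (concatenated premotor | striatum | snr | thalamus | cortex | params);
        by default fresh draws are made.
        """
        p = self.p
        k = p.dt / p.tau
        if noise is None:
            total = (p.n_premotor + 4 * p.n_actions
                     + (24 * p.n_param_cells if integrate_params else 0))
            noise = (self.rng.uniform(-p.noise_amplitude, p.noise_amplitude, total)
                     if p.noise_amplitude > 0 else np.zeros(total))
        n_pre, n_a = p.n_premotor, p.n_actions
        off = (0, n_pre, n_pre + n_a, n_pre + 2 * n_a, n_pre + 3 * n_a,
               n_pre + 4 * n_a)

        in_pre = self.b_pre + noise[off[0]:off[1]]
        in_str = (self.W_pre_str.T @ self.r_pre + p.w_ctx_str * self.r_ctx
                  + p.B_striatum + noise[off[1]:off[2]])
        in_snr = p.B_snr - p.w_str_snr * self.r_str + noise[off[2]:off[3]]
        in_thal = p.B_thalamus - p.w_snr_thal * self.r_snr + noise[off[3]:off[4]]
        in_ctx = p.B_cortex + p.w_thal_ctx * self.r_thal + noise[off[4]:off[5]]

        self.mp_pre += k * (in_pre - self.mp_pre)
        self.mp_str += k * (in_str - self.mp_str)
        self.mp_snr += k * (in_snr - self.mp_snr)
        self.mp_thal += k * (in_thal - self.mp_thal)
        self.mp_ctx += k * (in_ctx - self.mp_ctx)

        self.r_pre = np.maximum(self.mp_pre, 0.0)
        self.r_str = np.maximum(self.mp_str, 0.0)
        self.r_snr = np.maximum(self.mp_snr, 0.0)
        self.r_thal = np.maximum(self.mp_thal, 0.0)
        self.r_ctx = np.maximum(self.mp_ctx, 0.0)
        if self.clamp is not None:
            self.mp_ctx[self.clamp] = 1.0
            self.r_ctx[self.clamp] = 1.0

        if integrate_params:
            # Feedforward readout populations: only integrated when their
            # activity is consumed (no feedback into the loop, no plasticity).
            in_par = ((self.r_ctx @ self._w_flat).reshape(self.mp_par.shape)
                      + noise[off[5]:].reshape(self.mp_par.shape))
            self.mp_par += k * (in_par - self.mp_par)
            self.r_par = np.maximum(self.mp_par, 0.0)

        self.dopamine_step()
        if learning:
            self.plasticity_step()

    def dopamine_step(self) -> None:
        """Euler step of the dopamine cell toward its gated, predicted drive."""
        p = self.p
        # The gated drive is rectified: a fully predicted outcome silences
        # the burst rather than inverting it, so familiarity stops learning
        # instead of eroding established associations.
        target = self.P * max(0.0, 1.0 - self.W_str_da @ self.r_str) + p.B_DA
        self.DA += (p.dt / p.tau_DA) * (target - self.DA)
        self.DA = max(self.DA, 0.0)

    def plasticity_step(self) -> None:
        """Apply the three-factor corticostriatal and prediction updates."""
        p = self.p
        phasic = self.DA - p.B_DA
        f_da = p.K_b * phasic if phasic >= 0 else p.K_d * phasic
        # Correlation term: joint above-mean activity.  Each factor is
        # rectified separately so anti-correlated pairs clip to zero and
        # jointly *silent* pairs (both below mean) cannot potentiate.
        pre_dev = np.maximum(self.r_pre - self.r_pre.mean() - p.gamma_pre, 0.0)
        post_dev = np.maximum(self.r_str - self.r_str.mean() - p.gamma_post, 0.0)
        corr = np.multiply.outer(pre_dev, post_dev)
        norm = p.alpha_norm * (self.r_str - self.r_str.mean()) ** 2
        self.W_pre_str += (p.dt / p.tau_w) * (f_da * corr - norm[None, :])
        np.maximum(self.W_pre_str, 0.0, out=self.W_pre_str)

        str_dev = np.maximum(self.r_str - self.r_str.mean(), 0.0)
        self.W_str_da += (p.dt / p.tau_w) * 3.0 * phasic * str_dev
        np.maximum(self.W_str_da, 0.0, out=self.W_str_da)

    def simulate(self, ms: float, learning: bool = False,
                 integrate_params: bool = False, track_da: bool = False):
        """Run the loop for ``ms`` milliseconds; optionally return peak DA."""
        p = self.p
        n = int(round(ms / p.dt))
        total = (p.n_premotor + 4 * p.n_actions
                 + (24 * p.n_param_cells if integrate_params else 0))
        if p.noise_amplitude > 0:
            block = self.rng.uniform(-p.noise_amplitude, p.noise_amplitude, (n, total))
        else:
            block = np.zeros((n, total))
        peak = self.DA
        for t in range(n):
            self.rate_step(learning=learning, integrate_params=integrate_params,
                           noise=block[t])
            if track_da:
                peak = max(peak, self.DA)
        return peak if track_da else None

    # -- trial-level operations -------------------------------------------

    def settle(self, simulate_ms: float | None = None) -> None:
        """Release any clamp, clear the goal and return to baseline activity.

        With no premotor input the loop's resting state has a closed form
        (striatum and cortex silent, SNr at its baseline, the thalamus under
        tonic SNr inhibition), so by default the state is reset to that fixed
        point directly; pass ``simulate_ms`` to relax there dynamically
        instead.
        """
        p = self.p
        self.clamp = None
        self.P = 0.0
        self.encode_goal(None)
        if simulate_ms is not None:
            self.simulate(simulate_ms)
            return
        self.mp_pre[:] = 0.0
        self.mp_str[:] = 0.0
        self.mp_snr[:] = p.B_snr
        self.mp_thal[:] = p.B_thalamus - p.w_snr_thal * max(p.B_snr, 0.0)
        self.mp_ctx[:] = p.B_cortex + p.w_thal_ctx * max(self.mp_thal[0], 0.0)
        self.mp_par[:] = 0.0
        for mp, r in ((self.mp_pre, "r_pre"), (self.mp_str, "r_str"),
                      (self.mp_snr, "r_snr"), (self.mp_thal, "r_thal"),
                      (self.mp_ctx, "r_ctx"), (self.mp_par, "r_par")):
            setattr(self, r, np.maximum(mp, 0.0))
        self.DA = p.B_DA

    def select_action(self, goal: np.ndarray, force_random: bool = False,
                      stabilise: bool = True,
                      greedy_fallback: bool = False) -> int:
        """Select (and clamp) an action channel for ``goal``.

        Presents the goal for 200 ms; if the maximum cortex rate stays below
        the selection threshold (or ``force_random``), a uniformly random
        channel is clamped to 1, otherwise the most active channel is.  A
        further 150 ms stabilises the parameter populations (skipped for
        probe selections that never decode, ``stabilise=False``).  Whether
        the sub-threshold random branch fired is left in
        ``last_selection_random``.
        """
        self.encode_goal(goal)
        self.simulate(self.p.goal_ms)
        self.last_selection_random = bool(
            force_random or self.r_ctx.max() < self.p.selection_threshold)
        drive = self.W_pre_str.T @ self.r_pre
        if not self.last_selection_random:
            action = int(np.argmax(self.r_ctx))
        elif greedy_fallback and not force_random and drive.max() > 1e-3:
            # Caching-time fallback: below the cortical threshold the loop has
            # not committed, but the learned striatal drive still ranks the
            # channels; exploiting it beats a blind random pick when no
            # further act-and-sense learning will correct a bad cache entry.
            action = int(np.argmax(drive))
            self.last_selection_random = False
        else:
            action = int(self.rng.integers(self.p.n_actions))
        self.clamp = action
        self.mp_ctx[action] = 1.0
        self.r_ctx[action] = 1.0
        if stabilise:
            self.simulate(self.p.select_ms, integrate_params=True)
        return action

    def decode_parameters(self) -> np.ndarray:
        """Clamped (4, 6) CPG parameters from the parameter populations."""
        return self.library.decode(self.r_par)

    def learn_trial(self, outcome: np.ndarray) -> float:
        """Act-and-sense learning after a movement.

        The achieved ``outcome`` is encoded in the premotor input (100 ms),
        then the dopamine gate opens (``P = 1``) and plasticity runs for
        100 ms.  Returns the peak phasic dopamine level of the learning
        window (novelty burst).
        """
        self.encode_goal(outcome)
        self.simulate(self.p.sense_ms)
        self.P = 1.0
        peak = self.simulate(self.p.learn_ms, learning=True, track_da=True)
        self.P = 0.0
        return float(peak)
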