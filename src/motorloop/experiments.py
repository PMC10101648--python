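"""Task protocols: goal generation, pretraining, reaching and adaptation.

The experiments mirror a standard motor-learning battery:

* **Act-and-sense pretraining** of the basal ganglia: random goals are
  presented, actions executed (randomly when nothing is recognised), and the
  achieved outcome is bound to the executed action by novelty-gated
  plasticity, until the loop reliably recognises goals (three consecutive
  cortex-driven selections).
* **Reaching**: 2 or 8 fixed goals; the basal ganglia provide a concrete
  action (optionally cached per goal), the cerebellum adds a 24-value
  correction, the CPGs execute, and the cerebellum learns from the Euclidean
  aiming error.
* **Visuomotor adaptation**: after baseline training on 2 goals, the
  *displayed* endpoint is rotated about the axis formed by the cross product
  of the two goal vectors.  Three conditions replicate the classic
  instruction experiment: rotation only, rotation + explicit strategy (the
  motor goal is replaced by the counter-rotated goal a few trials after
  perturbation onset), and strategy only (instruction without perturbation).
  Cerebellar learning always uses the aiming error against the current
  (possibly instructed) motor goal; the rotation never changes the physical
  arm state.
* **Variability sweep**: adaptation speed as a function of the reservoir's
  perturbation amplitude and frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import kinematics
from .basal_ganglia import BGNetwork
from .cerebellum import (Reservoir, outputs_to_angles, outputs_to_correction,
                         outputs_to_params)
from .cpg import CPGFixedParams, clamp_param_array, execute_movement

__all__ = [
    "Goal",
    "AdaptationSchedule",
    "TrialRecord",
    "MotorModel",
    "initial_hand_position",
    "generate_goals",
    "sample_goal_position",
    "pretrain_bg",
    "PretrainResult",
    "cache_actions",
    "run_reaching",
    "run_adaptation",
    "run_variability_sweep",
    "trials_to_half_error",
]


@dataclass(frozen=True)
class Goal:
    """A reachable target: constructed from joint angles, so attainable."""

    id: int
    position: np.ndarray
    source_angles: np.ndarray


@dataclass(frozen=True)
class AdaptationSchedule:
    """Trial-indexed plan of the visuomotor-rotation experiment.

    Perturbation onset is after ``baseline_trials``; the instruction (in
    strategy-bearing conditions) arrives ``instruction_delay`` trials later
    and is withdrawn at the end of the perturbed block; in the
    rotation+strategy condition the rotation is withdrawn
    ``strategy_off_to_rotation_off`` trials after the instruction, otherwise
    together with the end of the perturbed block; ``washout_trials`` follow.
    """

    condition: str = "rotation"
    baseline_trials: int = 100
    instruction_delay: int = 2
    perturbed_trials: int = 200
    strategy_off_to_rotation_off: int = 10
    rotation_deg: float = 45.0
    washout_trials: int = 100

    def __post_init__(self) -> None:
        if self.condition not in ("rotation", "strategy", "rotation_plus_strategy"):
            raise ValueError(f"unknown condition {self.condition!r}")
        for name in ("baseline_trials", "instruction_delay", "perturbed_trials",
                     "strategy_off_to_rotation_off", "washout_trials"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def has_rotation(self) -> bool:
        return self.condition in ("rotation", "rotation_plus_strategy")

    @property
    def has_instruction(self) -> bool:
        return self.condition in ("strategy", "rotation_plus_strategy")

    @property
    def instruction_start(self) -> int:
        return self.baseline_trials + self.instruction_delay

    @property
    def instruction_end(self) -> int:
        return self.baseline_trials + self.perturbed_trials

    @property
    def rotation_end(self) -> int:
        end = self.baseline_trials + self.perturbed_trials
        if self.condition == "rotation_plus_strategy":
            end += self.strategy_off_to_rotation_off
        return end

    @property
    def n_trials(self) -> int:
        return self.rotation_end + self.washout_trials

    def rotation_active(self, trial: int) -> bool:
        return (self.has_rotation
                and self.baseline_trials <= trial < self.rotation_end)

    def instruction_active(self, trial: int) -> bool:
        return (self.has_instruction
                and self.instruction_start <= trial < self.instruction_end)


@dataclass
class TrialRecord:
    """Everything logged about one movement."""

    trial: int
    goal_id: int
    motor_goal_id: int
    action: int
    params: np.ndarray
    cerebellar_output: np.ndarray
    joint_angles: np.ndarray
    hand_position: np.ndarray
    displayed_position: np.ndarray
    error: float            # Euclidean aiming error (to the motor goal)
    task_error: float       # Euclidean error to the task goal
    angular_error: float    # signed, degrees, displayed vs task goal
    da_peak: float = np.nan


def initial_hand_position(fixed: CPGFixedParams | None = None) -> np.ndarray:
    """Hand position of the resting arm (all joints at their reference angle)."""
    fixed = fixed or CPGFixedParams()
    return kinematics.forward_kinematics(np.full(4, fixed.U_ref))


def sample_goal_position(rng: np.random.Generator,
                         fixed: CPGFixedParams | None = None,
                         min_distance: float = 0.5,
                         max_tries: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """One reachable goal: random joint offsets added to the rest posture,
    rejected until the hand lands at least ``min_distance`` away."""
    fixed = fixed or CPGFixedParams()
    start = initial_hand_position(fixed)
    for _ in range(max_tries):
        angles = fixed.U_ref + rng.uniform(-np.pi, np.pi, 4)
        pos = kinematics.forward_kinematics(angles)
        if np.linalg.norm(pos - start) >= min_distance:
            return pos, angles
    raise RuntimeError("goal sampling budget exhausted")


def generate_goals(n: int, rng: np.random.Generator,
                   fixed: CPGFixedParams | None = None,
                   min_distance: float = 0.5) -> list[Goal]:
    """Sample ``n`` reachable goals at ``min_distance`` from the start hand."""
    if n < 1:
        raise ValueError("need at least one goal")
    goals = []
    for i in range(n):
        pos, angles = sample_goal_position(rng, fixed, min_distance)
        goals.append(Goal(i, pos, angles))
    return goals


class MotorModel:
    """The composed system: BG action selection + cerebellar correction + CPGs.

    Either component may be absent: ``bg=None`` gives the cerebellum-alone
    configuration (outputs mapped affinely onto the parameter intervals, or
    directly onto joint angles with ``readout='direct'``); ``cerebellum=None``
    gives the ablated model in which the concrete action is executed as is.
    """

    def __init__(self, bg: BGNetwork | None = None,
                 cerebellum: Reservoir | None = None,
                 fixed: CPGFixedParams | None = None,
                 duration: float = 4000.0, dt: float = 1.0,
                 readout: str = "cpg"):
        if readout not in ("cpg", "direct"):
            raise ValueError(f"unknown readout {readout!r}")
        self.bg = bg
        self.cerebellum = cerebellum
        self.fixed = fixed or CPGFixedParams()
        self.duration = duration
        self.dt = dt
        self.readout = readout
        self.cached_params: dict = {}
        self.cached_actions: dict = {}

    def execute(self, params: np.ndarray) -> np.ndarray:
        """Run the CPGs on a (4, 6) parameter array and return joint angles."""
        return execute_movement(params, self.fixed, self.duration, self.dt)

    def movement_from_action(self, params: np.ndarray,
                             outputs: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """Combine action parameters with a cerebellar correction and move."""
        if outputs is not None:
            params = clamp_param_array(params + outputs_to_correction(outputs))
        angles = self.execute(params)
        return params, angles

    def movement_cerebellum_alone(self, outputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.readout == "direct":
            angles = self.fixed.U_ref + outputs_to_angles(outputs, self.fixed.Amp)
            return np.full((4, 6), np.nan), angles
        params = clamp_param_array(outputs_to_params(outputs))
        angles = self.execute(params)
        return params, angles


# -- Pretraining -------------------------------------------------------------

@dataclass
class PretrainResult:
    converged: bool
    n_trials: int
    distances: np.ndarray
    records: list[TrialRecord] = field(default_factory=list)


def pretrain_bg(model: MotorModel, rng: np.random.Generator,
                max_trials: int = 1500, required_streak: int = 3,
                min_distance: float = 0.5,
                min_trials: int | None = None) -> PretrainResult:
    """Act-and-sense pretraining of the basal ganglia.

    Each trial: relax to baseline, present a random reachable goal, select an
    action (random while nothing is recognised), execute it, and let the
    novelty-gated plasticity bind the achieved outcome to the executed
    action.  Stops once the loop recognises goals in ``required_streak``
    consecutive trials (cortex-driven selections), i.e. once random outcomes
    are being replicated; returns the goal-to-outcome distance trace.

    ``min_trials`` (default: two trials per action) keeps the stop rule from
    firing while the observed-outcome pool is still tiny.
    """
    bg = model.bg
    if bg is None:
        raise ValueError("pretraining requires a basal-ganglia component")
    if min_trials is None:
        min_trials = 2 * bg.p.n_actions
    distances = []
    records = []
    outcomes: list[tuple[np.ndarray, int]] = []
    streak = 0
    converged = False
    n_trials = 0
    for trial in range(max_trials):
        n_trials = trial + 1
        goal, _ = sample_goal_position(rng, model.fixed, min_distance)
        bg.settle()
        action = bg.select_action(goal)
        params = bg.decode_parameters()
        angles = model.execute(params)
        outcome = kinematics.forward_kinematics(angles)
        da_peak = bg.learn_trial(outcome)
        outcomes.append((outcome, action))
        dist = float(np.linalg.norm(goal - outcome))
        distances.append(dist)
        records.append(TrialRecord(trial, -1, -1, action, params, np.zeros(24),
                                   angles, outcome, outcome,
                                   dist, dist, np.nan, da_peak))
        # Probe: present a randomly chosen past outcome as the goal and ask
        # whether the loop re-selects the action that produced it.
        probe_outcome, producer = outcomes[int(rng.integers(len(outcomes)))]
        bg.settle()
        probed = bg.select_action(probe_outcome, stabilise=False)
        streak = streak + 1 if (probed == producer and not bg.last_selection_random) else 0
        if streak >= required_streak and n_trials >= min_trials:
            converged = True
            break
    bg.settle()
    return PretrainResult(converged, n_trials, np.asarray(distances), records)


def cache_actions(model: MotorModel, goals: dict | list) -> None:
    """Select and store the concrete action for each goal once.

    Mirrors the speed-up used for larger goal sets: one extra selection trial
    per goal after pretraining; during the task the stored parameters are
    reused and only the cerebellum keeps adapting.
    """
    bg = model.bg
    items = goals.items() if isinstance(goals, dict) else [(g.id, g) for g in goals]
    for key, goal in items:
        bg.settle()
        action = bg.select_action(np.asarray(goal.position, float),
                                  greedy_fallback=True)
        model.cached_actions[key] = action
        model.cached_params[key] = bg.library.exact_params(action)


# -- Reaching ----------------------------------------------------------------

def run_reaching(model: MotorModel, goals: list[Goal], n_trials: int,
                 cached_actions: bool = True,
                 bg_learning: bool = False) -> list[TrialRecord]:
    """Reaching task on a fixed goal set, cycling through the goals.

    With ``cached_actions`` the concrete action per goal is selected once and
    frozen; otherwise the basal ganglia run a full selection every trial
    (with optional continued novelty learning on the achieved outcome).
    The cerebellum, when present, adds its correction and learns from the
    Euclidean distance between its motor goal and the achieved hand position.
    """
    start = initial_hand_position(model.fixed)
    if model.bg is not None and cached_actions:
        missing = [g for g in goals if g.id not in model.cached_params]
        if missing:
            cache_actions(model, missing)
    records = []
    for trial in range(n_trials):
        goal = goals[trial % len(goals)]
        outputs = model.cerebellum.run_trial(goal.id) if model.cerebellum is not None else None
        if model.bg is None:
            params, angles = model.movement_cerebellum_alone(outputs)
            action = -1
        else:
            if cached_actions:
                action = model.cached_actions[goal.id]
                base = model.cached_params[goal.id]
            else:
                model.bg.settle()
                action = model.bg.select_action(goal.position)
                base = model.bg.decode_parameters()
            params, angles = model.movement_from_action(base, outputs)
        pos = kinematics.forward_kinematics(angles)
        err = float(np.linalg.norm(goal.position - pos))
        if model.cerebellum is not None:
            model.cerebellum.apply_learning(goal.id, err)
        da_peak = np.nan
        if model.bg is not None and bg_learning and not cached_actions:
            da_peak = model.bg.learn_trial(pos)
        try:
            ang = kinematics.angular_error(start, pos, goal.position,
                                           np.cross(goals[0].position,
                                                    goals[min(1, len(goals) - 1)].position)
                                           if len(goals) > 1 else np.array([0.0, 0.0, 1.0]))
        except ValueError:
            ang = np.nan
        records.append(TrialRecord(trial, goal.id, goal.id, action, params,
                                   np.zeros(24) if outputs is None else outputs,
                                   angles, pos, pos, err, err, ang, da_peak))
    return records


# -- Visuomotor adaptation ---------------------------------------------------

def run_adaptation(model: MotorModel, schedule: AdaptationSchedule,
                   goals: list[Goal], cached: bool = True,
                   bg_learning: bool = False) -> list[TrialRecord]:
    """The three-condition visuomotor-rotation protocol on two goals.

    The cursor rotation acts on the *displayed* endpoint only, about the
    normalised cross product of the two goal position vectors.  The
    instruction replaces the motor goal by the goal counter-rotated about the
    same axis.  Cerebellar learning always uses the aiming error: the
    distance between the displayed endpoint and the current motor goal.  The
    signed angular error is logged against the task goal.

    Goal-identity inputs to the cerebellum: ``0, 1`` for the two task goals
    and ``2, 3`` for their instructed counterparts, so an instruction starts
    a fresh per-goal error baseline.
    """
    if len(goals) != 2:
        raise ValueError("the adaptation task uses exactly 2 training goals")
    start = initial_hand_position(model.fixed)
    # Rotation plane: spanned by the two goal directions as seen from the
    # movement start; the cursor rotation is centred on the start position,
    # as in the experimental paradigm being modelled.
    axis = np.cross(goals[0].position - start, goals[1].position - start)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("degenerate goal pair: parallel goal directions")
    axis = axis / nrm

    instructed = {
        g.id: Goal(g.id + 2,
                   kinematics.rotate_endpoint(g.position, axis,
                                              -schedule.rotation_deg, center=start),
                   g.source_angles)
        for g in goals
    }
    if model.bg is not None and cached:
        todo = {g.id: g for g in goals}
        todo.update({ig.id: ig for ig in instructed.values()})
        todo = {k: v for k, v in todo.items() if k not in model.cached_params}
        if todo:
            cache_actions(model, todo)

    records = []
    for trial in range(schedule.n_trials):
        task_goal = goals[trial % 2]
        instructed_now = schedule.instruction_active(trial)
        motor_goal = instructed[task_goal.id] if instructed_now else task_goal
        outputs = (model.cerebellum.run_trial(motor_goal.id)
                   if model.cerebellum is not None else None)
        if model.bg is None:
            params, angles = model.movement_cerebellum_alone(outputs)
            action = -1
        else:
            if cached:
                action = model.cached_actions[motor_goal.id]
                base = model.cached_params[motor_goal.id]
            else:
                model.bg.settle()
                action = model.bg.select_action(motor_goal.position)
                base = model.bg.decode_parameters()
            params, angles = model.movement_from_action(base, outputs)
        hand = kinematics.forward_kinematics(angles)
        displayed = (kinematics.rotate_endpoint(hand, axis, schedule.rotation_deg,
                                                center=start)
                     if schedule.rotation_active(trial) else hand)
        aim_err = float(np.linalg.norm(displayed - motor_goal.position))
        if model.cerebellum is not None:
            model.cerebellum.apply_learning(motor_goal.id, aim_err)
        da_peak = np.nan
        if model.bg is not None and bg_learning and not cached:
            # act-and-sense on the *sensed* endpoint (the cursor): novelty
            # gates how much, if anything, is learned.
            da_peak = model.bg.learn_trial(displayed)
        task_err = float(np.linalg.norm(displayed - task_goal.position))
        try:
            ang = kinematics.angular_error(start, displayed, task_goal.position, axis)
        except ValueError:
            ang = np.nan
        records.append(TrialRecord(trial, task_goal.id, motor_goal.id, action,
                                   params,
                                   np.zeros(24) if outputs is None else outputs,
                                   angles, hand, displayed,
                                   aim_err, task_err, ang, da_peak))
    return records


# -- Variability sweep -------------------------------------------------------

def trials_to_half_error(angular_errors: np.ndarray, onset: int,
                         window: int = 10) -> float:
    """Adaptation-speed statistic: trials after ``onset`` until the moving
    average (width ``window``) of |angular error| first falls below half its
    initial post-onset value.  Returns ``inf`` if it never does."""
    err = np.abs(np.asarray(angular_errors, float)[onset:])
    if err.size < window:
        return float("inf")
    kernel = np.ones(window) / window
    smooth = np.convolve(err, kernel, mode="valid")
    target = smooth[0] / 2.0
    below = np.nonzero(smooth < target)[0]
    return float(below[0]) if below.size else float("inf")


def run_variability_sweep(model_factory, amplitudes, frequencies, seeds,
                          schedule: AdaptationSchedule | None = None) -> list[dict]:
    """Adaptation speed across reservoir noise settings.

    ``model_factory(seed, A, f)`` must return a ``(model, goals)`` pair ready
    for :func:`run_adaptation` (pretrained, rotation condition).  Amplitude
    and frequency are varied one at a time around the first entry of the
    other list.  Returns one summary row per (parameter, value, seed).
    """
    schedule = schedule or AdaptationSchedule(condition="rotation")
    rows = []
    combos = [("A", a, a, frequencies[0]) for a in amplitudes]
    combos += [("f", f, amplitudes[0], f) for f in frequencies]
    for which, value, amp, freq in combos:
        for seed in seeds:
            model, goals = model_factory(seed, amp, freq)
            recs = run_adaptation(model, schedule, goals)
            errs = np.array([r.angular_error for r in recs])
            speed = trials_to_half_error(errs, schedule.baseline_trials)
            rows.append({
                "param": which, "value": value, "A": amp, "f": freq,
                "seed": seed, "trials_to_half": speed,
                "final_abs_error": float(np.nanmean(
                    np.abs(errs[schedule.rotation_end - 10:schedule.rotation_end]))),
            })
    return rows
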