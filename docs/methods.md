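# Methods

`motorloop` simulates a systems-level division of labour in motor learning:
a cortex–basal-ganglia loop *selects* discrete motor programs ("concrete
actions"), a reservoir cerebellum *fine-tunes* them, and brainstem central
pattern generators (CPGs) *execute* them on a 4-degree-of-freedom arm.  This
note documents the model equations as implemented, every constant that had to
be calibrated, the numerical choices, and what the package's synthetic
experiments do and do not show.

## Arm and kinematics

The arm is a serial chain (shoulder pitch → yaw → roll → elbow) described by
four homogeneous transforms with link translations 0.05, 0.22 and 0.16
(dimensionless link units); the wrist position is the image of the origin
under their product.  The workspace is a ball of radius 0.43 around the
shoulder; the resting posture (all joints at the reference angle 0) puts the
hand at (−0.38, 0.00, −0.05).

The *projected angular error* of a movement projects the displayed endpoint
and the goal into the plane orthogonal to a given normal and measures the
signed angle at the start position between movement direction and goal
direction (positive = counterclockwise about the normal, right-hand rule).
The sign convention is ours; it is needed to render aftereffects as sign
flips.

In the visuomotor-rotation experiments the cursor rotation is **centred on
the start position** of the movement, about the axis spanned by the two goal
directions as seen from the start (normalised cross product).  An
origin-centred rotation would change the projected error at the start vertex
by an arbitrary amount rather than by the imposed rotation; centring on the
movement origin is what the experimental paradigm implements.

## Central pattern generators

Each joint has an independent three-layer CPG.  The rhythm-generation layer
holds two conditional-oscillator cells (extensor `e`, flexor `f`):

    tau_m dV/dt = -(V - A_f tanh((sigma_f/A_f) V) + q - i_inj)
    tau_s dq/dt = -q + sigma_s (V - E_s),        tau_s = 20 tau_m

with fixed `A_f = 5`.  The pattern-formation layer applies the logistic
`PF = 1/(1 + exp(alpha_0 alpha_PF ((theta_0 + theta_PF) - I_PF)))` to its
drive, and motor neurons apply a fixed-slope logistic
`MN = 1/(1 + exp(5 (0.5 - I_MN)))`.  The joint angle is
`U = Amp (MN_E - MN_F) + U_ref` with `Amp = 5`, so `|U - U_ref| ≤ 5` rad
always.  Six parameters per joint are set by the upstream loop: `tau_m` ∈
[5, 15] ms, `sigma_f`, `sigma_s` ∈ [5, 10], `i_inj` ∈ [−4, 4], `alpha_0`,
`theta_0` ∈ [0.001, 2]; values outside the interval are clamped.

Choices the equations do not pin down (all config-exposed):

* **Antagonist wiring.** The extensor pattern-formation cell is driven by its
  rhythm cell, the flexor one by the inhibitory mirror of its rhythm cell
  (`-V_f`).  With two uncoupled, identically driven chains the time-averaged
  extensor/flexor commands would cancel and the arm would barely move; the
  mirrored drive makes `theta_0` a genuine extensor/flexor balance control
  and gives the parameter → posture map its range.
* **Slow-current reversal** `E_s = 0` and symmetry-broken initial conditions
  `V_e(0) = 0.1`, `V_f(0) = −0.1`, `q(0) = 0`.
* **Integrator**: explicit Euler, `dt = 1` ms, guarded by a convergence test
  against a high-accuracy adaptive solver (the relaxation-oscillation jumps
  make pointwise late-time comparison meaningless; amplitude and mean are
  compared over a full second, the smooth initial rise pointwise).
* **Movement duration and readout.** A movement integrates the CPGs for
  4000 ms and reads the joint angle as the **mean motor command over the last
  3000 ms** — the settled posture around which the command oscillates.  A
  single-step snapshot readout samples an arbitrary oscillation phase, which
  makes the parameter → endpoint map nearly sign-inconsistent at the scale of
  cerebellar exploration (67% sign agreement between full- and quarter-size
  parameter steps, vs 88% for the averaged readout) and defeats perturbation
  learning; the averaged readout spans several oscillation cycles.  These
  problem sizes are the package's default operating point, not a constraint
  of the equations.

## Basal ganglia: selection by disinhibition

One rate-coded channel per concrete action runs premotor input → striatum D1
→ SNr → thalamus → motor cortex → (feedback) striatum, all populations
following `tau dmp/dt + mp = input + B + eps`, `r = mp⁺`, with `tau = 10` ms,
noise `eps ~ U(−0.01, 0.01)` per step, fixed weights (striatum→SNr 0.8,
SNr→thalamus 0.6, thalamus→cortex 1.0, cortex→striatum 0.5) and baselines
(striatum 0, SNr 1.1, thalamus 0.9).  At rest the SNr tonically fires at 1.1,
the thalamus sits at 0.24, and a calibrated cortex baseline `B_ctx = −0.3`
keeps the resting cortex silent — without it the resting loop fixed point
(cortex ≈ 0.32) would sit above the 0.05 selection threshold and the
random-exploration branch of selection could never fire.

**Selection.** A goal sets the premotor baselines through Gaussian spatial
tuning (width `sigma_g = 0.15` workspace units, calibrated; 200 premotor
cells with preferred positions drawn as forward-kinematics images of random
joint configurations).  After 200 ms, the most active cortex channel is
clamped to 1 if it exceeds 0.05; otherwise a uniformly random channel is
clamped (exploration).  150 ms more lets the parameter populations settle.
During the one-off caching of actions for a goal set, a sub-threshold
selection falls back on the argmax of the *striatal* drive instead of a
random pick (the striatum ranks the channels even below the cortical
commitment threshold, and no later act-and-sense trial would correct a
randomly mis-cached action).

**Parameter readout.** Each of the 24 CPG parameters has a 21-cell
value-tuned population tiling its clamp interval; the decoded value is the
population-vector average, clamped.  Action→parameter weights are fixed and
random: a Gaussian bump (sd 1.5 cells) at a uniformly random centre cell on a
5% uniform background, normalised.  The bump centre makes each action a
random point in parameter space; a structureless uniform draw would decode
every action to near the interval midpoints and collapse the movement
repertoire.  Centres for the injected current are drawn U-shaped
(beta(0.4, 0.4), favouring strong extensor or flexor drive) and for the
slow-current conductance biased low (beta(1, 2)); with uniform centres only
~7% of actions reach the goal shell (≥ 0.5 from rest) versus ~16% with the
bias.  Finally, libraries are **stability-screened** at construction: an
action must keep its endpoint within 0.05 workspace units under two
independent 5%-of-range parameter jitters and within 0.1 under a 10% jitter,
while moving at least 0.01 (a concrete action is a stereotyped but tunable
motor program; endpoints in chaotic zones of the oscillator map are
scrambled by any cerebellar correction, and parameter-dead endpoints give
the cerebellum no authority).  Failing actions are redrawn; the probe scales
bracket the exploration noise and the trained corrections an action will
actually receive.

**Novelty-gated plasticity.** After a movement the achieved endpoint is
encoded in the premotor input (act-and-sense) and a dopamine cell opens the
plasticity gate for 100 ms:

    tau_DA dDA/dt + DA = P (1 - sum_i wDA_i r_i)^+ + B_DA
    tau_w  dw_ij/dt    = f_DA(DA - B_DA) C_ij - alpha (r_j - rbar_post)^2
    C_ij = (r_i - rbar_pre - gamma_pre)^+ (r_j - rbar_post - gamma_post)^+
    tau_w dwDA_i/dt    = 3 (DA - B_DA) (r_i - rbar_pre)^+

with `B_DA = 0.1`, `gamma_pre = 0`, `gamma_post = 0.1`, and population means
taken instantaneously.  Two readings differ deliberately from the literal
update forms: the correlation term rectifies each factor separately (the
positive part of the *product* would potentiate jointly-silent premotor ×
striatal pairs — negative × negative — flooding all channels with diffuse
weight growth and erasing goal→action specificity), and the gated dopamine
drive is rectified (otherwise the learned prediction overshoots 1, phasic
dopamine inverts on every familiar outcome, and the associations being
reused are actively unlearned).  Calibrated constants: `K_b = 5`,
`K_d = 2.5` (one novelty burst must bind an outcome strongly enough to cross
the selection threshold), `alpha = 0.01`, `tau_w = 100` ms, `tau_DA = 10` ms.
All plastic weights are floored at 0.

**Pretraining** loops act-and-sense trials on random reachable goals (random
joint offsets from rest, hand at least 0.5 from the resting hand) and stops
when a probe — a randomly chosen *previously achieved outcome* presented as
the goal — re-selects the action that produced it three times in a row, with
a minimum of one trial per action so the stop rule cannot fire while the
outcome pool is tiny.

## Cerebellum: reservoir with node-perturbation learning

400 `tanh` units, `tau dx/dt = −x + J r + B u`, goal-identity one-hot input
`u` (weights U(−0.2, 0.2)), recurrent weights `J ~ N(0, 0.05)`.  Per trial:
state reset to U(−0.01, 0.01), 200 ms with input, 200 ms free; the output is
the mean rate of the 24 output units over the free phase.  Every unit is
kicked with per-ms probability `f/1000` by U(−A, A); the featured fast
configuration is `eta = 0.8`, `f = 9` /s, `A = 20`.  Each synapse accumulates
the cubic eligibility trace `e += (r_pre(t−1) (x(t) − xbar))³` (`xbar`: 5-ms
moving average), and after the trial the weights update against the
per-goal error baseline `Ebar` (exponential moving average, coefficient
0.2): improvements (`E < Ebar`) reinforce the trace.

Because the kicks enter the trace cubed, the raw trace is numerically
unbounded; the implemented update uses the trace *pattern*:

    dJ = -eta (e / max|e|) Ebar (E - Ebar),   per-element cap max_dw = 0.01,
    applied only where |e| >= 1e-3 max|e|,    |J| <= 1

The eligibility gate confines plasticity to the perturbation-tagged synapses
that actually carry the exploration signal; without it the other ~159k
synapses random-walk `J` into saturation faster than the learning signal
accumulates, and with a cap small enough to prevent that, learning stalls.
The step magnitude anneals naturally as the per-goal error stabilises
(`E − Ebar` shrinks).  All three guards are calibrated and config-exposed.

**Output mappings.** Cerebellum-alone: outputs map affinely from [−1, 1]
onto each parameter's clamp interval; a control variant maps the first four
outputs directly to joint angles (scaled by `Amp`).  Full model: outputs are
*corrections*, scaled to a quarter of each parameter's interval per
saturated output and added to the selected action's parameters before
clamping.  The scale balances authority (a trained output pattern can still
displace the endpoint by ~0.5 workspace units) against motor noise (the
exploration kicks contribute only a few degrees of trial-to-trial direction
noise); because both scale together, the ratio is fixed by the output
fluctuation level and the gain chooses the operating point.

## Experiments

* **Reaching**: 2 or 8 fixed goals, cycled; with a pretrained BG the concrete
  action per goal is selected once and cached (a standard speed-up for larger
  goal sets, since a fixed goal keeps re-selecting the same action), and only
  the cerebellum keeps adapting on the Euclidean aiming error.  BG novelty learning during the task is off by default — an
  outcome revisited under a cached action is familiar and would not learn
  anyway.
* **Visuomotor rotation**: after baseline training on 2 goals, the displayed
  endpoint is rotated 45° about the axis above.  Three conditions: rotation
  only; rotation + strategy (after 2 perturbed trials the motor goal is
  replaced by the counter-rotated goal, withdrawn at the end of the perturbed
  block, rotation withdrawn 10 trials later); strategy only (instruction
  without rotation).  Cerebellar learning always uses the *aiming* error —
  displayed endpoint versus current motor goal — and instructed goals are
  distinct goal-identity inputs with fresh error baselines.  The rotation
  never touches the physical arm state.
* **Variability sweep**: rotation condition across perturbation amplitudes
  and frequencies; adaptation speed is the number of trials until the
  10-trial moving average of |angular error| first falls below half its
  post-onset value (censored at the phase length when it never does).

Analysis convention: angular-error traces are reported baseline-corrected —
each goal's mean error over its last eight baseline movements subtracted —
the standard de-biasing in rotation paradigms (a late-baseline block, so
slow drift during baseline training does not leak into the estimate).  With
a 120-action library the per-goal aiming bias is tens of degrees at the
desk scales used here and would otherwise mask perturbation effects.
Condition-level traces are pooled across seeds with medians where single
basin-hopping trials would otherwise dominate.

## Scales, seeds, reproducibility

One global seed fans out into named, mutually independent streams (`goals`,
`bg`, `cerebellum`), so ablating one component never shifts another's
randomness — ablation comparisons differ only in the ablated part.  Three
presets: `unit` (5 actions, 50 units — fast tests), `reduced` (30 actions,
400 units, 30/60/10-trial adaptation schedule — desk-scale experiments),
`full` (120 actions, 400 units, 100/200/10 schedule).  The adaptation
experiments use the full 120-action library with the reduced schedule: the
instruction effect is a question of directional resolution of the action
repertoire, which is not what the schedule reduction is meant to scale down.

## Known limitations

* Node-perturbation learning assigns credit by correlating a scalar error
  with hundreds of simultaneous kicks; its convergence horizon is hundreds
  to thousands of trials.  At the desk scales used here the *selection*
  phenomenology (first-trial perturbation error, instruction effects,
  stability of the full model, ablation) is robust, while the *slow
  implicit* components (gradual error decay within a 60-trial perturbed
  block, amplitude/frequency speed ordering) sit at or below the noise floor
  of 5-seed comparisons and may not replicate reliably at this scale.
* The model is open loop: no trajectory feedback, no muscle model, no
  execution noise.  The only stochasticity in a movement is planning noise
  (reservoir kicks) and the per-step rate noise in the loop.
* The CPG parameter → endpoint map is piecewise smooth with chaotic zones;
  the stability screen excludes those zones from the action repertoire but
  the cerebellum can still steer into them.
* Synthetic experiments only: goals, actions and schedules are generated;
  nothing here fits human kinematic data, and passing tests demonstrate
  internal phenomenology, not quantitative agreement with behaviour.
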