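# Methods

`contextmaze` implements a family of context-inferring reinforcement
learning agents on discrete cued maze tasks, together with the training
protocols and analyses needed to study how feature-based and outcome-based
context inference interact during learning. This note documents the model,
its parameters, the numerical choices made where the design was genuinely
open, and what the synthetic tasks do and do not capture.

## The problem

A cued T-maze trial hides its state: a cue early on the stem announces
which arm will pay off, but the cue is gone by the time the agent stands at
the junction. Formally the task is a POMDP whose hidden state factorises
into a fully observable location and a partially observable context (the
trial type); each context is an ordinary MDP differing only in where the
reward sits. An agent that can infer the context from its observations can
act predictively within the trial; an agent that cannot must react to
outcomes across trials.

## Environments

Tasks are discrete T-shaped graphs (`maze.py`). Observations are feature
vectors: a one-hot over locations followed by cue features, with predictive
cues scaled (4x on the cued T-maze and structural discrimination, 2x on
non-match-to-sample) relative to location entries. Moving into a wall
leaves the agent in place. Reaching either arm end terminates the attempt;
a wrong end teleports the agent back to the start for another attempt, and
nothing is learnt across the teleport. Contextual signal-to-noise is
manipulated by adding distractor cue features (shared across trial types,
co-located with the predictive cue, same scale) or by lengthening the stem.
The sequence tasks present two cues on successive stem locations and force
`up` along the stem; matching pairs reward right in the non-match task,
and the six ordered pairs of three cues split 3/3 in the structural task
(the cyclic pairs A-B, B-C, C-A reward right — the pairing is a
convention and is exposed in the builder).

## Per-context maps

Each context z owns three aligned maps, spawned together:

- **Successor map M^z** (`features.py`): ψ(s) = Mφ(s) predicts the
  discounted future occupancy of every feature. The delta rule
  M ← M + δ ⊗ (k ⊙ g) with δ = φ_t + γψ(s_{t+1}) − ψ(s_t) drives the
  one-step consistency to zero. g = φ_t/‖φ_t‖² is the minimum-norm
  least-squares allocation over observed columns: it normalises for cue
  overrepresentation and guarantees the per-step contraction never exceeds
  the largest gain. Gains are per-column scalar Kalman filters with
  count-based annealing, k_j = σ_j²/(σ_j² + σn²), σ_j² shrinking only when
  feature j is observed: confidence grows with how often a feature has
  been seen, not with its magnitude, so scaled cue columns anneal at the
  same pace as location columns. A joint-Σ gain was tried first and
  rejected: the scaled cue features dominate the shared denominator, the
  start state's column learns an order of magnitude slower than the cue
  columns, and the persistent mid-learning residual at the cue transition
  makes fresh maps chronically outscore the correct one. Entering an arm
  end triggers an absorption update (zero continuation) so terminal
  columns converge to their one-hots, matching the analytic SR
  (I − γT)⁻¹ with empty terminal columns.
- **Convolved-reward map C^z** (`outcomes.py`): a per-location diffuse
  reward estimate. A symmetric kernel γ^|i|, i ∈ [−len, len] (len = 2) is
  dotted with the window of the last 2·len+1 per-visit rewards; the result
  cr is credited to the location at the window centre, i.e. the state
  visited len moves earlier. The map moves toward cr with rate
  α = min(1, α_o·k(s)) (α_o = 23: near-one-shot early). The variance used
  for inference is the estimated innovation variance — a running average
  of the squared post-update residual — because cr at a location
  genuinely scatters with the path taken, and the annealing parameter
  variance alone would make the likelihood arbitrarily over-confident.
- **TD value map** (`policy.py`): linear state values V(φ) = TD·φ counting
  the occupied state's own reward (a rewarded terminal has value equal to
  its reward; a 3-state corridor converges to [γ², γ, 1]). The Kalman
  regressor is φ_t, with small diagonal process noise (0.005 per update)
  so the filter keeps a steady-state gain: learnt values can also be
  unlearnt after a contingency change, which the pure annealing filter
  cannot do. Action selection is ε-greedy (ε = 0.2) over one-step
  lookahead values Q(a) = TD·φ(step(s, a)), querying the environment's
  transition dynamics for the lookahead observation; a location-only
  lookahead is available as a configuration switch.

## Context inference

Evidence is compared against each context's map under a Gaussian
likelihood: the feature stream scores the transition residual
φ_t − (ψ(s_t) − γψ(s_{t+1})) with fixed per-dimension variance σr² = 1.6;
the outcome stream scores cr − C(s) under the map's estimated variance
(floored at 0.03, the scale of within-context convolved-reward scatter
under ε-greedy dithering). The "new context" slot is scored with a fresh
zero map. The prior is a sticky Chinese restaurant process estimated by a
particle filter: 100 particles each hold the last y = 10 inferred labels;
each particle's sCRP weights (counts + stickiness β on its last label +
concentration α on "new") are averaged and renormalised. Particles are
refreshed by direct sampling from the current posterior (a weighted
variant can be slotted in through `ParticleSet.advance`).

Per step the cycle is **infer → absorb → act**: inference consumes the
evidence completed on the previous step, the same evidence is then
absorbed as map updates, and the agent acts with the selected context's TD
map. Credit assignment differs by stream, and this asymmetry is essential:

- Feature and value learning follow the context that was *acting* when the
  transition happened. Its map made the prediction the transition tests;
  experiments with post-inference assignment let a transient misfit
  redirect exactly the update that would have fixed it, starving the
  acting map of cue-prediction learning and spawning junk contexts until
  the capacity was exhausted.
- Outcome learning follows the context selected *in light of* the window:
  a reward window trains the map of the context it confirmed, and a
  window that conflicts with every map acts purely as selection evidence —
  the map that expected the reward keeps its expectation as context
  memory. Zero windows sharpen a map only when they agree with it and the
  map already contains reward knowledge; otherwise a blank context would
  accumulate a spurious confidence edge over a genuinely fresh one.

Three further rules govern the belief dynamics:

- **Outcome-signal gating.** A convolved-reward window contributes
  evidence only when it contained reward or some context predicts reward
  (> 0.05) at its centre. Outcome inference reacts to unexpected reward
  or omission of expected reward; windows that every map explains carry no
  information, and scoring them hands the incumbent map a small
  log-density bonus every step that freezes the belief.
- **Self-transitions are not evidence.** A rejected move emits no new
  observation: wall bumps update neither maps nor beliefs and do not
  advance the outcome window (the TD self-transition delta −(1−γ)V(s) is
  the one exception — it discounts time spent against a wall and steers
  the greedy policy off it).
- **New-slot folding.** The y-step window forgets contexts unused for y
  inferences, driving their prior — hence posterior — to exactly zero. A
  winning "new" verdict is therefore read as *"none of the recently used
  contexts"*: if an existing map explains the evidence strictly better
  than a fresh map would, the new-slot mass is folded onto it (the
  returning context); otherwise a fresh context is spawned, up to the
  capacity z_max = 10, beyond which folding is unconditional. The feature
  stream folds only at capacity (its high-dimensional evidence separates
  fresh from returning maps on its own); the scalar outcome stream folds
  always.

## Joint inference

During the fusion window the two streams share one particle set and one
context bank. Both likelihoods combine with the joint prior (the mean of
the sCRP estimates under the feature and outcome hyperparameters, from the
shared windows), the acting posterior is the renormalised average of the
stream posteriors, and the prior advances once per stream. The outcome
stream's belief persists between outcome events and keeps contributing its
standing verdict to the joint prior on outcome-silent steps — without
this, the roughly six-fold more frequent feature advances wash the outcome
stamps out of the windows, and at low contextual signal-to-noise the
feature stream (whose likelihood favours any trained map over a fresh one
on the shared structure) drags the joint belief back into the old context.
Outcome maps absorb windows under the outcome stream's own verdict, so
stream disagreement cannot mix reward knowledge across contexts. Outside
the window the agent is trace-identical to a pure feature-inference agent
given the same seed.

## Hyperparameters

All agents: ε = 0.2, γ = 0.9, σn² = 1, 100 particles, y = 10, z_max = 10,
initial context probabilities ∝ [1, 0.4, 0.1, 0, …]. Feature stream:
concentration 0.5, stickiness 5 (8 on the structural task), σ0² = σr² =
1.6. Outcome stream: concentration 0.1 (0.8 structural), stickiness 0.7,
σ0² = 1.6, α_o = 23, len = 2. Baselines: reward learning rate α_r = 0.7
(SR), 1.0 (SR1). Numerical constants chosen here: outcome signal threshold
0.05 and variance floor 0.03 (both on the scale of the smallest kernel
weights and of within-context cr scatter), TD process noise 0.005
(unlearning over ~15 visits).

## Protocols and metrics

The cued T-maze trains on 20 alternating 50-trial blocks then 500 random
trials (joint fusion over the first 200 trials); the sequence tasks
pretrain on blocked rewarded types, train on blocked all-types, then run
500 random trials with fusion during training blocks. A step cap of 1,000
per trial replaces wall-clock limits; capped trials are recorded as
failures and reported as a completion fraction. Reversal speed is the mean
attempts on the first trial after each of the last k switches;
within-trial prediction is the first-attempt percent correct over the last
n random trials. Replicates use consecutive seeds.

## Analyses

Simulated splitter cells read the predicted future occupancy of a chosen
target location out of each context's successor map at every state,
weighted by the mean acting posterior recorded at that state on
first-attempt-correct random trials; the preferred context/trial type is
the larger stem firing, and the splitter probability difference is the
posterior separation of the preferred context between preferred and
non-preferred trials. Both raw and posterior-weighted fields are emitted;
raw is primary where normalisation matters. Incorrect updates count map
updates applied, within a trial window, to a context whose pre-window
majority trial type mismatches the current one. The confidence gate
compares mean max-posterior per stream per phase against a threshold.

## What the synthetic tasks do not capture

All inputs are generated; there is no sensory noise, no continuous
kinematics, and rewards are binary and deterministic given the trial type.
Passing behavioural tests therefore show that the inference machinery
reproduces the qualitative phenomena — predictive versus reactive
switching, SNR-dependent degradation and its rescue, splitter-like
selectivity — under idealised observations, not that the model fits any
particular animal's data. Deep successor-map entries converge slowly under
annealed gains (far columns of long corridors approach the analytic SR
polylogarithmically), so map-level oracle checks use short chains;
behaviour depends on the cue-adjacent structure, which converges within a
few trials. Rescue of feature inference at high distractor counts is
bimodal across seeds — a fraction of joint agents still lose the critical
first reversal — so condition means carry substantial seed variance at
desk scale. The behavioural test conditions use 10 replicate seeds for the
baseline agents and 6 for the slower 20-distractor conditions; the
headline-number script uses 10.
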