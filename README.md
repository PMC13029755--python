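# contextmaze

Contextual-inference reinforcement learning agents on cued maze tasks.

## The problem

In a cued T-maze, a cue early on the central stem announces which arm will
pay off — but the cue is gone by the time the animal (or agent) stands at
the junction. The task is a POMDP whose hidden state factorises into an
observable location s and a latent context z (the trial type); each
context is an ordinary MDP G_z = (S, A, p, R_z, γ) differing only in where
the reward sits. Solving it means inferring z while still learning what
each context looks like.

`contextmaze` implements two Bayesian strategies for that inference and
their combination:

- **Feature inference (FI)** — hippocampus-style. Each context owns a
  successor map M^z with ψ(s) = M^z φ(s), learnt by the delta rule
  δ = φ_t + γψ(s_{t+1}) − ψ(s_t) with Kalman-gain learning rates. Contexts
  are scored by how well each map reconstructs the observed feature
  transition, p(φ_t | z) = N(φ_t; ψ(s_t) − γψ(s_{t+1}), σr²I), so the cue
  itself shifts the belief within the trial — predictive inference.
- **Outcome inference (OI)** — prefrontal-style. Each context owns a
  diffuse reward map C^z over locations, compared against a convolved
  reward cr_t = F_γ · r (a γ-kernel over the recent reward window,
  credited to the state visited len steps ago): p(cr_t | z) =
  N(cr_t; C^z(s), σ²(s)). OI never sees cues; it reacts to unexpected
  reward or the omission of an expected one.
- **Joint inference** — during early learning the two posteriors are
  averaged, p(z | o_t) = (p(z | φ_t) + p(z | cr_t))/2, over a shared
  sticky-CRP particle prior. The outcome stream's stable context signal
  supervises the formation of distinct feature maps when the cue evidence
  is weak, and the benefit persists after the fusion window closes.

Both strategies share per-context TD value maps for ε-greedy choice, a
sticky Chinese-restaurant-process prior over an open-ended context set
(approximated by a particle filter), and single-map baselines (SR, one-shot
SR, TD) for comparison. The analysis layer turns trained agents into
simulated hippocampal "splitter cells" — context-selective activity at
identical locations — plus map-quality metrics.

## A worked example

```
$ python examples/cued_tmaze_feature_inference.py
s6 - s5 - s4 - s3 - s7 - s8 - s9
               s2 *cue*
               s1

contexts in use: 10
block-switch attempts (mean over last 10 switches): 2.30
first-attempt percent correct, last 100 random trials: 80.0%

context 9: predicted occupancy from s1 of cue L = 0.77, cue R = 3.20
context 1: predicted occupancy from s1 of cue L = 3.18, cue R = 0.74
(one map expects cue L ahead, the other cue R — the basis of within-trial inference)
```

The agent was trained on 20 alternating 50-trial blocks and then 500
random trials. 80% first-attempt accuracy on random trials means the agent
predicts the rewarded arm from the cue within the trial; ~2 attempts at
block switches means the cue — not the missing reward — drives its
reversals. The two dominant context maps have specialised: each predicts
high future occupancy of its own trial type's cue from the start state
(≈ γ·4 = 3.6) and little of the other's.

Other examples: `outcome_inference_reversal.py` (reactive switching,
chance on random trials), `joint_rescue_with_distractors.py` (fusion
rescues feature inference at low cue signal-to-noise),
`splitter_cells.py` (context-selective simulated activity on the stem),
`sequence_tasks.py` (delayed non-match to sample),
`baseline_comparison.py` (why single-map learners must relearn at every
switch).

A thin CLI covers batch use: `contextmaze run`, `contextmaze sweep`
(distractor count or stem length), `contextmaze analyze`, `contextmaze
demo`. See `contextmaze --help`.

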