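# Methods

This note documents the model, the numerical choices, the calibration of
parameters the published tables leave free, and what the simulation does
and does not establish.

## Model structure

**State.** Nine discrete variables: three graded cultural-norm beliefs
(`OLD/MID/YOUNG_LIKES_FORMAL ∈ {-2..2}`), conversation status
(`IN_CONVERSATION`, `NPC_AGE ∈ {NONE, YOUNG, MID, OLD}`, `GREETED`,
`ASKED`, `NPC_HAPPY`), and `GOT_WATER`. The full product space has
5·5·5·2·4·2·2·2·2 = 16 000 states; states violating the consistency
invariants (e.g. an NPC age outside a conversation) are retained in the
table but unreachable. A single absorbing terminal state is appended; STOP
transitions into it and the transition carries the end-of-game reward.

**Actions and availability.** Outside a conversation: select one of the
three NPC age classes, or STOP. Inside: one greet (formal/informal), then
asks (formal/informal, repeatable), or LEAVE at any point. Once the water
location is known, a conversation allows only LEAVE — a revealed quest
ends all further dialog. Dialog *turns* are greets and asks only;
select/leave are navigation.

**Real-world dynamics.** An NPC is pleased iff the formality of the
greet/ask matches the true culture (old and young formal, middle-aged
informal); the mood is recomputed at every greet/ask. An ask reveals the
water with probability `p_reveal_happy` if the NPC is pleased after the
ask, else `p_reveal_unhappy`. Every greet/ask reaction, positive or
negative, gives the concerned belief one chance to move one step toward
its true value, with the mindset-specific probabilities of the update
table (confirmation-biased for fixed, uncertainty-peaked for malleable);
beliefs never move away from the truth and never move by more than one
step per feedback.

**Subjective (planning) model.** The player expects an NPC to be pleased
with probability `(b+2)/4` for a formal act (complement for informal),
where `b` is their own belief about that age class. Pleasure counts as
evidence for the used formality, displeasure against it; the expected
belief movement follows the mindset rule (fixed: move only from `b = 0`;
malleable: move whenever `|b| < 2`), one step in the evidence direction.
At `b = 0` this yields the symmetric 50/50 split of ±1. Water-reveal
expectations reuse the real-world probabilities (shared basic reasoning).
An alternative subjective-update mode that reuses the real-world update
table is available per profile (`subjective_update="real_world_table"`); it weakens
the learning contrast between the mindsets and is not the default.

**Rewards.** All rewards except the per-move time cost are granted at game
end: 5 for having the water plus a belief-strength band reward on
`s = Σ|b|` (`0<s<3`, `3≤s<6`, `s=6`; 0.5/1.5/3.5 fixed, 1/3/6 malleable).
The time cost (−0.75 fixed, −0.5 malleable) applies to every move
including select, leave, and STOP.

## Solving and simulating

Q values are solved by fixed-point iteration of the softmax-consistent
recursion (the future value uses the Boltzmann policy of the Q being
solved; `backup="greedy"` switches to standard value iteration). Softmax
and log-likelihoods use max-shift stabilization. Convergence is a sup-norm
residual below `tol = 1e-6` (default; residual history is recorded and is
empirically monotone after the first sweep on the water-task models,
converging in ~30 sweeps). Non-convergence raises with the last residual.

Q is solved once per mindset with a planning noise `planning_beta = 10`
(near-optimal but smooth); the per-player β enters only the action
sampling and likelihood evaluation. This treats planning competence as a
property of the mindset and β as execution noise, and it keeps one Q table
per mindset valid for the whole cohort.

Each record derives two independent RNG streams (action sampling,
environment) from a per-record seed built deterministically from
(master seed, mindset, player index, run index), so any single record is
re-simulable and a recorded action sequence can be replayed through the
environment stream alone. Episodes are capped at `max_steps = 50`
(`end_reason="cap"`, distinct from a drawn STOP); the cap binds rarely
(high-β malleable games run ~10–20 moves).

**Cohort design.** β ~ lognormal(0, 1) (median 1), one draw per player
pair, shared by a fixed and a malleable player; default full scale is 500
pairs × 100 runs. Tests and the worked example use the desk-scale cohort
(50 pairs × 20 runs, master seed 20260101), which keeps the full pipeline
— two 16 000-state solves, 2 000 games, metrics, and classification —
under ~15 s on one CPU.

## Classification

A record's log likelihood under a mindset is the sum over steps of the log
softmax probability of the taken action (restricted to the actions
available in the recorded state); state transitions do not enter. β is a
nuisance parameter maximized over a log-spaced grid
(log β ∈ [−2.5, 2.5], step 0.125) per model per record; the larger
maximized likelihood wins, exact ties going to fixed (deterministic, and
ties are vanishingly rare). An oracle mode evaluates at the generating β
instead, for sensitivity analysis.

## Calibrated parameters

Two environment parameters the published description leaves unquantified
were calibrated once, against the *printed fixed-player statistics* (which
are insensitive to the contested parts of the malleable policy), and then
frozen:

- `p_reveal_happy = 0.4`, `p_reveal_unhappy = 0.05`. A near-optimal fixed
  player's conversation is one greet plus Geometric(p) asks, so the
  reported ≈3.07 dialog turns per conversation implies p ≈ 0.4–0.5. The
  8:1 ratio keeps culturally appropriate behavior strongly (not perfectly)
  instrumental.
- `γ = 0.98`. The discount must keep end-of-game rewards salient over a
  realistic game (≈5–20 moves). At γ ≤ 0.93 with the calibrated reveal
  probability, the fixed model's optimal policy degenerates to stopping
  on move 1 (the ~4-move water plan discounts below its time cost), which
  contradicts the intended fixed phenotype. At 0.98 the simulated fixed
  players closely match the reported statistics (turns/conversation 3.05,
  conversations/game 1.72, game-quit 24%).

## What the simulation shows — and does not

The desk-scale cohort reproduces: higher cultural learning for malleable
players (Welch p < 10⁻⁴⁰), more conversations and more actions per game
for malleable players, far more game-quitting for fixed players, a fixed
preference for high-status (old/young) NPCs vs. near-uniform malleable
selection, and above-chance mindset recovery whose per-player accuracy
rises with log β for malleable players while fixed players stay
recognizable even at low β.

Three behavioral contrasts come out *opposite* to the behavioral-theory
prediction under this implementation, at every parameterization we
explored: dialog turns per conversation (fixed higher), conversational
quitting (malleable higher), and responsiveness to feedback (fixed
higher). The cause is structural. Because a revealed water location
freezes all further dialog, asks are risky for a learner; the malleable
planner therefore farms safe one-greet conversations across age classes
(many short conversations — which the <4-turns rule counts as quits — and
few post-error correct acts), while the fixed planner exploits one NPC
with a long greet-and-ask run (and, after an occasional noise-driven
wrong-formality act, goes on to produce the ≥2 correct acts that the
responsiveness rule rewards). These three metrics are reported exactly as
defined and their acceptance checks are left failing rather than
redefined; an implementation without the dialog freeze, or with dialog
permitted after the reveal, would likely reverse them.

## Synthetic data, scope, limitations

All data are generated by the package itself; nothing is fitted to human
logs. The generator emulates the decision structure of the original game,
not its surface: NPC personalities, utterance generation, multi-utterance
dialog trees, and the "correction" reaction are out of scope (the six-NPC
roster is kept for annotation only; the state abstracts NPCs to age
classes). Group tests are exactly the planned comparisons with no
multiple-testing correction. Passing tests show internal consistency of
the models and pipeline — not that human players with these mindsets would
behave this way. The reported Cohen's d uses the pooled-SD form
`(m_a − m_b)/√((s_a² + s_b²)/2)` on per-player means.
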