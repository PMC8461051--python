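# mindsim

Generative Markov-decision-process models of **cultural mindset** — how
readily a person updates cultural beliefs — exercised in a small
dialog-based cross-cultural game, with behavioral-criteria analyses and
maximum-likelihood mindset classification of the simulated play logs.

The package is aimed at computational cognitive modelers and assessment
researchers who want to (a) simulate how a *fixed* vs. a *malleable*
cultural mindset should behave in a norm-learning task, (b) test whether
the simulated behavior matches theory-driven behavioral criteria, and
(c) measure how recoverable the generating mindset is from a play log.

## The task

A newcomer to a village must find water by talking to villagers (NPCs) of
three age classes. The village culture ties formality to status: **old and
young villagers prefer formal address, middle-aged villagers informal**.
Players select an NPC, greet them, and ask for the water; each greet/ask
with the wrong formality draws a subtle frown (negative feedback), the
right formality a nice reply. A pleased NPC is more likely to reveal the
water location when asked. The player's knowledge of the culture is a
graded belief per age class, `X_LIKES_FORMAL ∈ {-2..2}` (−2 = certain they
dislike formality, 0 = no idea, +2 = certain they like it); every piece of
feedback is a chance for the concerned belief to move one step toward the
truth.

## The model

Each mindset is a belief-augmented MDP over the full discrete state space
(three beliefs × conversation/quest status; 16 000 states). Action values
solve

    Q(s,a) = Σ_s' p(s'|s,a) [ r(s,a,s') + γ Σ_a' π(a'|s') Q(s',a') ]

with a softmax (Boltzmann) policy

    π(a|s) ∝ exp(β Q(s,a)),   β ∈ [0, ∞)

where β is the decision-noise ("strategic ability") parameter: β = 0 acts
uniformly at random, β → ∞ acts optimally. The transition model used for
planning is *subjective* — what the player expects to happen, driven by
their own beliefs — while an independent *real-world* model generates the
actual outcomes and the actual belief updates.

The two mindsets differ in three mechanisms:

| mechanism | fixed | malleable |
| --- | --- | --- |
| initial beliefs (old, mid, young) | (2, 1, −2) — confident, partly wrong | (0, 0, 0) — agnostic |
| end-of-game rewards (water; belief bands 0<s<3, 3≤s<6, s=6) | 5; 0.5 / 1.5 / 3.5 | 5; 1 / 3 / 6 |
| time cost per move | −0.75 | −0.5 |
| expects own belief to change | only if completely uncertain (b = 0) | whenever not maxed (&#124;b&#124; < 2) |
| real-world update probability after feedback (current value −2…1, correct-value frame) | 0.20 / 0.40 / 0.60 / 0.80 | 0.30 / 0.60 / 0.95 / 0.60 |

(`s` is the belief strength Σ|b|; the update row for an age class whose
correct value is −2 is mirrored.) The fixed column's update probabilities
rise toward the held belief — confirmation bias — while the malleable
column peaks at complete uncertainty.

A simulated cohort draws β ~ lognormal(0, 1) per *player pair* (one fixed
and one malleable player share each β), plays many independent seeded games
per player, and analyzes the records: cultural learning, conversation
counts and dialog turns, conversational/game quitting, responsiveness to
negative feedback, NPC-age preferences (Welch t and Pearson χ² group
comparisons), plus profile-likelihood classification of every record back
to a mindset.

## Worked example

Run the full pipeline on the desk-scale cohort (50 player pairs × 20 games,
default environment, fixed seed):

```bash
mindsim report --scaled --seed 20260101 --out-dir results/example
```

This solves both mindsets' Q tables (16 000 states each), simulates 2 000
games, and writes records, summary CSVs, and `report.txt`, which contains
(abridged):

```
                      metric      mean_a(malleable)  mean_b(fixed)   p_value
               mean_learning              2.810          0.888       1.9e-43
 mean_conversations_per_game              3.241          1.717       6.8e-15
 mean_turns_per_conversation              1.754          3.051       5.5e-07
       mean_actions_per_game             12.829          8.851       1.2e-14
               game_quitting              0.087          0.240       2.2e-20

fixed:     YOUNG 0.377, MID 0.242, OLD 0.381
malleable: YOUNG 0.332, MID 0.328, OLD 0.340

overall classification accuracy: 0.725
confusion matrix (rows: generating model):
           fixed  malleable
fixed      0.823      0.177
malleable  0.373      0.627
```

Reading this: malleable players learn about three times as much of the
culture per game (2.81 vs 0.89 belief steps), hold almost twice as many
conversations, take more actions overall, and almost never abandon the
game early (8.7% vs 24.0%), while fixed players concentrate on the NPCs
they already feel certain about (old and young) and exploit a single
conversation with a long greet-and-ask run. Classification recovers the
generating mindset well above chance, recognizes fixed records more
reliably than malleable ones, and (see `accuracy_by_beta.csv`) becomes
near-perfect for malleable players as β grows.

The same pipeline is available as library calls (`mindsim.simulation`,
`mindsim.metrics`, `mindsim.classification`) and stage-by-stage
subcommands (`solve`, `simulate`, `metrics`, `classify`).

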