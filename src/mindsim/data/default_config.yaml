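# mindsim default run configuration (config-schema v1).
#
# The profile tables (initial beliefs, reward bands, time costs, and the
# real-world belief-update probabilities) are the published model
# parameters; the environment block holds the task parameters the published
# description leaves free, at this package's calibrated defaults.
version: 1
master_seed: 20260101
output_dir: results

environment:
  # Probability an NPC reveals the water when asked, by mood after the ask.
  p_reveal_happy: 0.4
  p_reveal_unhappy: 0.05
  max_steps: 50

profiles:
  fixed:
    # (old, mid, young): confident that old likes / young dislikes formality,
    # weakly suspects mid likes it.
    initial_beliefs: [2, 1, -2]
    # belief-strength bands: 0<s<3, 3<=s<6, s==6
    belief_reward_bands: [0.5, 1.5, 3.5]
    time_cost: -0.75
    water_reward: 5.0
    subjective_update: mindset_rule
  malleable:
    initial_beliefs: [0, 0, 0]
    belief_reward_bands: [1.0, 3.0, 6.0]
    time_cost: -0.5
    water_reward: 5.0
    subjective_update: mindset_rule

# Real-world probability that one piece of feedback moves a belief one step
# toward its true value, keyed on the current value in the frame where the
# correct value is +2 (mirrored for age classes whose correct value is -2).
belief_update_table:
  "-2": {fixed: 0.20, malleable: 0.30}
  "-1": {fixed: 0.40, malleable: 0.60}
  "0": {fixed: 0.60, malleable: 0.95}
  "1": {fixed: 0.80, malleable: 0.60}
  "2": {fixed: 0.0, malleable: 0.0}

simulation:
  # Full study conditions: 500 paired players, 100 games each.
  n_players_per_mindset: 500
  runs_per_player: 100
  # Planner settings: discount, backup policy and its noise level.
  gamma: 0.98
  planning_beta: 10.0
  backup: softmax
  tol: 1.0e-6
  max_iter: 10000

classification:
  # Profile-likelihood beta grid: log beta from -2.5 to 2.5, step 0.125.
  log_beta_min: -2.5
  log_beta_max: 2.5
  log_beta_step: 0.125
  oracle_beta: false
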