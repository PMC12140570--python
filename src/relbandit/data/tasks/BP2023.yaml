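# Ten-option bandit with two binary and two ternary Gaussian contexts crossing
# outcome range (wide/narrow) with context size.  This editable reconstruction
# uses means 14/50/86 (wide) and 41/50/59 (narrow) with sd $2, matching the
# published structural facts: 10 options, 2 binary + 2 ternary contexts,
# Gaussian dollars, reward range ~[8, 92], 45 transfer trials, and no
# incongruent transfer pairs.  The published ideal-agent rate (0.969) depends
# on supplementary details and is not reproduced by this reconstruction
# (which yields 1.0); see docs/methods.md.
name: BP2023
currency: dollars
transfer_reps: 1
contexts:
  - id: wide_binary
    n_learning_trials: 15
    options:
      - id: wb_lo
        reward: {kind: gaussian, mean: 14.0, sd: 2.0}
      - id: wb_hi
        reward: {kind: gaussian, mean: 86.0, sd: 2.0}
  - id: narrow_binary
    n_learning_trials: 15
    options:
      - id: nb_lo
        reward: {kind: gaussian, mean: 41.0, sd: 2.0}
      - id: nb_hi
        reward: {kind: gaussian, mean: 59.0, sd: 2.0}
  - id: wide_ternary
    n_learning_trials: 15
    options:
      - id: wt_lo
        reward: {kind: gaussian, mean: 14.0, sd: 2.0}
      - id: wt_mid
        reward: {kind: gaussian, mean: 50.0, sd: 2.0}
      - id: wt_hi
        reward: {kind: gaussian, mean: 86.0, sd: 2.0}
  - id: narrow_ternary
    n_learning_trials: 15
    options:
      - id: nt_lo
        reward: {kind: gaussian, mean: 41.0, sd: 2.0}
      - id: nt_mid
        reward: {kind: gaussian, mean: 50.0, sd: 2.0}
      - id: nt_hi
        reward: {kind: gaussian, mean: 59.0, sd: 2.0}
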