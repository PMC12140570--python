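# Eight-option bandit with four binary learning contexts and Gaussian rewards
# (sd $1).  Context means form a uniform ladder 15..36 in steps of 3, so the
# high option of one context can be worth less than the low option of a later
# context (6 incongruent transfer pairs; ideal-agent rate 0.625).
name: HW2023a
currency: dollars
transfer_reps: 1
contexts:
  - id: ctx1
    n_learning_trials: 15
    options:
      - id: opt1L
        reward: {kind: gaussian, mean: 15.0, sd: 1.0}
      - id: opt1H
        reward: {kind: gaussian, mean: 18.0, sd: 1.0}
  - id: ctx2
    n_learning_trials: 15
    options:
      - id: opt2L
        reward: {kind: gaussian, mean: 21.0, sd: 1.0}
      - id: opt2H
        reward: {kind: gaussian, mean: 24.0, sd: 1.0}
  - id: ctx3
    n_learning_trials: 15
    options:
      - id: opt3L
        reward: {kind: gaussian, mean: 27.0, sd: 1.0}
      - id: opt3H
        reward: {kind: gaussian, mean: 30.0, sd: 1.0}
  - id: ctx4
    n_learning_trials: 15
    options:
      - id: opt4L
        reward: {kind: gaussian, mean: 33.0, sd: 1.0}
      - id: opt4H
        reward: {kind: gaussian, mean: 36.0, sd: 1.0}
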