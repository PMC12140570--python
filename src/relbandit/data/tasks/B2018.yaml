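# Eight-option bandit crossing outcome valence (gain/loss) with outcome
# magnitude (1 euro / 0.1 euro).  Each binary context pairs a p=.75 frequent
# winner with a p=.25 partner; losses are framed as avoiding the negative
# outcome (the better loss option pays 0 most of the time).  This editable
# reconstruction reproduces the published structural facts: 8 options, 4
# binary Bernoulli contexts, reward range [-1, 1] euros, 48 learning trials,
# 6 incongruent transfer pairs, ideal-agent rate 0.625.
name: B2018
currency: euros
transfer_reps: 1
contexts:
  - id: gain_big
    n_learning_trials: 12
    options:
      - id: gain_big_lo
        reward: {kind: bernoulli, win_prob: 0.25, hi_value: 1.0, lo_value: 0.0}
      - id: gain_big_hi
        reward: {kind: bernoulli, win_prob: 0.75, hi_value: 1.0, lo_value: 0.0}
  - id: gain_small
    n_learning_trials: 12
    options:
      - id: gain_small_lo
        reward: {kind: bernoulli, win_prob: 0.25, hi_value: 0.1, lo_value: 0.0}
      - id: gain_small_hi
        reward: {kind: bernoulli, win_prob: 0.75, hi_value: 0.1, lo_value: 0.0}
  - id: loss_small
    n_learning_trials: 12
    options:
      - id: loss_small_lo
        reward: {kind: bernoulli, win_prob: 0.25, hi_value: 0.0, lo_value: -0.1}
      - id: loss_small_hi
        reward: {kind: bernoulli, win_prob: 0.75, hi_value: 0.0, lo_value: -0.1}
  - id: loss_big
    n_learning_trials: 12
    options:
      - id: loss_big_lo
        reward: {kind: bernoulli, win_prob: 0.25, hi_value: 0.0, lo_value: -1.0}
      - id: loss_big_hi
        reward: {kind: bernoulli, win_prob: 0.75, hi_value: 0.0, lo_value: -1.0}
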