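# Four-option bandit with two binary learning contexts and binary (0/1 point)
# outcomes.  Win probabilities are {0.1, 0.4} in context 1 and {0.6, 0.9} in
# context 2; 60 learning trials split evenly; every transfer pair is presented
# twice (12 transfer trials).
name: V2023
currency: points
transfer_reps: 2
contexts:
  - id: ctx1
    n_learning_trials: 30
    options:
      - id: ctx1_lo
        reward: {kind: bernoulli, win_prob: 0.1, hi_value: 1.0, lo_value: 0.0}
      - id: ctx1_hi
        reward: {kind: bernoulli, win_prob: 0.4, hi_value: 1.0, lo_value: 0.0}
  - id: ctx2
    n_learning_trials: 30
    options:
      - id: ctx2_lo
        reward: {kind: bernoulli, win_prob: 0.6, hi_value: 1.0, lo_value: 0.0}
      - id: ctx2_hi
        reward: {kind: bernoulli, win_prob: 0.9, hi_value: 1.0, lo_value: 0.0}
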