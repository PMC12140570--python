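# Eight-option Bernoulli bandit (dollars, outcomes within [10, 44]) built to
# dissociate the frequent winner from the expected-value maximizer.  Contexts
# safe_low/safe_low2 pair a p=.8 frequent winner that is ALSO EV-best with a
# lower partner (congruent); contexts tradeoff1/tradeoff2 pair a p=.8 frequent
# winner holding LOWER EV against a rare-big-win partner (incongruent).  This
# editable reconstruction reproduces the published structural facts: Bernoulli
# rewards in [10, 44], 4 binary contexts, 60 learning trials, and an
# ideal-agent rate of exactly 0.500 (8 congruent and 8 incongruent of the 16
# rank-discordant transfer pairs).
name: HW2023b
currency: dollars
transfer_reps: 1
contexts:
  - id: safe_high1
    n_learning_trials: 15
    options:
      - id: sh1_lo
        reward: {kind: bernoulli, win_prob: 0.6, hi_value: 38.0, lo_value: 18.0}  # EV 30
      - id: sh1_hi
        reward: {kind: bernoulli, win_prob: 0.8, hi_value: 44.0, lo_value: 24.0}  # EV 40
  - id: safe_high2
    n_learning_trials: 15
    options:
      - id: sh2_lo
        reward: {kind: bernoulli, win_prob: 0.6, hi_value: 36.0, lo_value: 16.0}  # EV 28
      - id: sh2_hi
        reward: {kind: bernoulli, win_prob: 0.8, hi_value: 42.0, lo_value: 22.0}  # EV 38
  - id: tradeoff1
    n_learning_trials: 15
    options:
      - id: to1_risky
        reward: {kind: bernoulli, win_prob: 0.2, hi_value: 44.0, lo_value: 19.0}  # EV 24
      - id: to1_freq
        reward: {kind: bernoulli, win_prob: 0.8, hi_value: 21.0, lo_value: 11.0}  # EV 19
  - id: tradeoff2
    n_learning_trials: 15
    options:
      - id: to2_risky
        reward: {kind: bernoulli, win_prob: 0.2, hi_value: 43.0, lo_value: 18.0}  # EV 23
      - id: to2_freq
        reward: {kind: bernoulli, win_prob: 0.8, hi_value: 20.0, lo_value: 10.0}  # EV 18
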