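# Methods

## Task structures

A task is a set of options partitioned into learning contexts of 2–3 options;
each context is presented `n_learning_trials` times (equal across contexts),
randomly interleaved, with complete feedback; the transfer test covers all
unordered option pairs `transfer_reps` times without feedback.  Rewards are
two-point Bernoulli distributions (`hi_value` with probability `win_prob`,
else `lo_value`) or Gaussians.

**Exact-frequency sampling.**  Bernoulli outcome sequences are generated so the
realized count of high outcomes equals `round(win_prob × n)` exactly, with the
positions shuffled per run — sample means equal expected values to machine
precision, which removes sampling noise from the congruency structure.  If
`win_prob × n` is not an integer the count rounds half up with a warning; all
built-in tasks were parameterized so this never triggers at their shipped
trial counts.

**Frequent winner and relative rank.**  Option *i* outranks *j* within a
context when `P(draw_i > draw_j) > P(draw_j > draw_i)` (draw ties are
ignored — with binary 0/1 outcomes most trials tie, yet one option still wins
the decided trials more often).  Win probabilities are computed in closed form
(Bernoulli × Bernoulli enumeration; Gaussian × Gaussian via
`Φ((μ_i − μ_j)/√(σ_i² + σ_j²))`; mixed pairs by conditioning on the discrete
support).  Ranks are win counts scaled to [0, 1], i.e. {0, 1} in binary and
{0, 0.5, 1} in ternary contexts; a cyclic (intransitive) relation raises an
error, and no built-in task produces one.

**Congruency and the ideal rate.**  For each transfer pair the EV winner and
the relative-rank winner are compared: equal ranks → `rel_tied`; agreement →
`congruent`; disagreement → `incongruent`; the degenerate equal-EV,
unequal-rank case is labeled `ev_tied` and excluded, like `rel_tied` pairs,
from the ideal-rate denominator (no built-in task contains one).  The ideal
rate is the congruent fraction of the remaining pairs — it is analytic,
per-pair, and therefore invariant to `transfer_reps`.

**Built-in fixtures.**  Five task configs ship as editable YAML.  V2023
(binary 0/1 outcomes, win probabilities {.1,.4}/{.6,.9}) and HW2023a (Gaussian
means 15–36 in steps of 3, sd 1) are fully determined by their published
design parameters; the HW2023a means are the unique uniform ladder consistent
with the published per-option EVs, range, ideal rate (0.625) and incongruent
count (6).  B2018, BP2023, and HW2023b are *reconstructions* from structural
facts (option/context counts, distribution family, reward range, ideal rate,
presence/absence of incongruent pairs) rather than verbatim source parameters:
B2018 crosses valence with outcome magnitude (±1 € and ±0.1 €, p = .75/.25),
which reproduces its 0.625 ideal rate; HW2023b pairs two congruent contexts
with two frequent-winner/EV trade-off contexts, giving ideal rate exactly
0.500; BP2023 uses wide/narrow binary and ternary Gaussian contexts (means
14/41/50/59/86, sd 2) and, having no incongruent pairs, yields an ideal rate
of 1.0 — the published 0.969 depends on supplementary details that are not
recoverable from the main design facts, so it is documented as a known
deviation of the reconstruction.  All analysis code is config-driven, so
corrected parameters drop in without code changes.

## Cognitive model family

Encoding, updating and choice are as summarized in the README.  Numerical and
structural choices that the equations leave open:

- **Running-range update order.**  The running min/max absorbs the current
  trial's outcomes *before* `x_ABS` is computed, so the first trial's extremes
  map to 0 and 1 and the normalizer is always defined.  This is pinned by a
  test.
- **Degenerate ranges.**  When a trial's outcomes are all equal, or the
  running range is a point, the corresponding normalized value is 0.5
  (symmetric, keeps v defined and in [0, 1]).
- **Confirmation classification.**  Chosen option with `v > Q`, or unchosen
  with `v < Q`, updates with α_CON; the reverse cases with α_DIS; at `v = Q`
  the update is zero either way.
- **Position bias in all models.**  The factorial varies encoding, learning
  rates and inverse temperatures only; `b` appears in all eight models because
  the response stage includes it unconditionally.
- **Q reset.**  Expectancies reset to 0.5 and the running range resets at the
  start of every run; pooled likelihoods sum per-run likelihoods each with its
  own reset state.
- **Invalid trials** are removed before packing: they contribute neither
  likelihood nor expectancy updates (their outcomes leave the data).
- **Softmax stability.**  Choice probabilities are computed in the log domain
  (max-shifted), exact to ~1e-12 for utilities up to ±700.
- **Loss-domain rewards** (B2018, range [−1, 1]) enter the encoding stage
  unchanged; range normalization maps them into [0, 1] automatically.

The likelihood kernel is numba-jitted (with a transparent pure-Python
fallback) and is verified against an independent straight-line trace oracle in
the test suite to 1e-10, plus an exact ω = 0 nesting identity against the
absolute model.

## Estimation, comparison, recovery, cross-validation

Pooled maximum likelihood uses bounded L-BFGS-B from seeded Latin-hypercube
multi-starts (default 20; tolerance 1e-8).  Bounds: ω, α ∈ [0, 1],
β ∈ [0, 100], b ∈ [−10, 10].  These are the package's own defaults — the
estimation procedure is not prescribed by the model equations.  BIC is
`k·ln(n) − 2·LL` with `n` the number of valid pooled choice trials and `k`
= 3 + one per optional component; BIC ties break toward fewer parameters.

Model recovery simulates from each of the eight models (generating parameters
drawn from a pluggable sampler; the default draws magnitudes typical of fitted
in-context learners: α_CON ∈ [.4,.8] vs α_DIS ∈ [.05,.25], β ∈ [5,20],
b ∈ [−1.5,1.5], ω ∈ [.3,.9]), fits all eight, and selects by BIC.  The shipped
check runs 5 simulations per generating model per task on two tasks with 4
sessions each and 4 optimization starts — sized to finish in well under a
minute per model family on one core while still separating recovery from the
12.5% chance level by a large margin (observed ≈ 40–50%; misselections
concentrate on simpler models with the same encoding stage, so absolute vs
relative valuation stays distinguishable).

Leave-one-run-out CV refits on all runs but one and scores the held-out run;
pseudo-R² = `1 − LL_M/LL_0` with the chance log-likelihood accumulated trial
by trial (probability 1/2 binary, 1/3 ternary) in the same order as the
kernel, so a degenerate fitted model (β = 0, b = 0) yields exactly zero.

## Synthetic agents and grids

`simulate_session` runs any parameter vector generatively through a task:
seeded schedule, per-trial randomized presentation order (the first-listed
option receives the position bias), softmax sampling, updates during learning
only.  `simulate_ideal` always takes the max-EV presented option with a seeded
coin flip on exact ties, and `uniform_random_params` gives the β = 0 chance
agent.  Grids spawn one `SeedSequence` child per session from the base seed,
so any cell reproduces in isolation and manifests are byte-identical across
calls.  Each session draws its own outcome schedule; schedules are not shared
across prompt conditions within a repetition.

Synthetic agents emit no text.  The prompt condition is a metadata tag, and
the behavioral effect of explicit outcome comparisons is emulated by raising
ω (the `emulated_llm_params` helper defaults to ω = 0.11 standard / 0.26
comparison, with α_CON = .5, α_DIS = .16, β_learn = 18, β_transfer = 11,
b = 1.2 — magnitudes in the range typically estimated for instruction-tuned
in-context learners on these tasks).  What passing tests on these agents show
is that the *pipeline* — schedules, likelihoods, selection, bias statistics —
behaves correctly under known ground truth; they do not show anything about
any particular live model's behavior, which requires ingesting real session
logs through the same JSONL reader.

## Prompt harness

Prompt templates are plain config dataclasses; every rendered prompt ends with
the fixed response-format sentence, and the comparison clause defaults to
"…, which is more/less than the [amount] delivered by slot machine [Z]"
(semantics preserved; exact wording replaceable).  Responses parse
case-insensitively from the canonical sentence, tolerate trailing punctuation,
and anything else — including a label that was not offered — is invalid.
Invalid trials are dropped (the trial is skipped, not re-prompted), and a
dropped learning trial's outcomes are also excluded from expectancy updates.

## Hidden-unit value probe

For each transfer trial the two regressors are the unsigned difference in
absolute value (min-max-normalized EV across options) and in relative value
(within-context rank in {0, 0.5, 1}), each min-max normalized to [0, 1] across
trials.  EV-based absolute values are the default construction; a learned-Q
construction can be substituted by passing a custom design.  Every unit is an
independent OLS with intercept (vectorized across units); designs with
condition number above 1e8 are rejected.  Correction defaults to Bonferroni at
family-wise 0.05 over units × regressors (family size configurable; other
methods delegate to statsmodels `multipletests`).  The planted-signal
generator adds seeded Gaussian noise to a linear readout of the two
regressors — it emulates the readout structure of a final hidden layer, not
the representational geometry of any actual network, so probe tests establish
the statistical machinery (exact recovery at zero noise, pattern recovery at
effect/noise = 10, null false-positive control), not claims about real
activations.

## Known limitations

- B2018, BP2023 and HW2023b are structural reconstructions (above); BP2023's
  ideal rate deviates from the published 0.969.
- No hierarchical or per-run estimation (fits pool runs by design); no
  omnibus ANOVA machinery — bias flags use run-level t CIs against the ideal
  rate, which implements the same decision rule self-containedly.
- The frequent-winner classification uses the design distributions, not the
  realized outcome sequences; with exact-frequency Bernoulli sampling the two
  coincide.
- Partial-feedback variants are not modeled; all built-ins use complete
  feedback.
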