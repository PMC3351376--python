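# Methods

## Model and assumptions

The package analyzes discrete FACS time series from evolving, multi-labeled
microbial populations. Three layers sit on top of each other:

1. a **normalization** layer turning counts into inoculum-normalized
   proportion trajectories and per-generation slopes;
2. a **statistical classifier** turning each slope into one of three
   emission symbols (`P`/`N`/`Z`) by comparison with a neutral reference
   distribution; and
3. a **two-state hidden Markov model** (`A` adaptive expansion / `N` not)
   with history-penalized transitions, decoded to mark adaptive events and
   drive sampling suggestions.

Assumptions worth spelling out: samples are sparse (roughly one per ten
generations here), so inference is per-interval; label fitness effects are
neutral (any residual effect shows up as a non-zero `μ_r`); the neutral slope
pool is representative of the noise in the experiment being analyzed; and an
adaptive event manifests as a *sustained* run of significantly positive
slopes, which is exactly what the penalized HMM rewards.

## The slope classifier

`T = (r − μ_r) / (σ_r / √n)` with `n − 1` degrees of freedom, where
`(μ_r, σ_r, n)` come from pooled neutrality-experiment slopes. The test is
single-tailed by default at `α = 0.10` (a `tails=2` option halves the
per-direction level; a Gaussian reference is available via
`distribution="normal"` for large calibration pools). Slopes exactly at the
critical value are not rejected — a conservative, deterministic tie rule.
Significant slopes emit `P` or `N` by the sign of `r − μ_r`; the rest emit
`Z`. Calibration is pooled across fluorophores by default;
`calibrate_neutral_per_label` provides the per-label variant for dyes with
known fitness effects.

Note the statistic scales the deviation by the standard error of the
*calibration mean*, not by the slope standard deviation. It therefore asks
"could this slope be the mean of the neutral pool?", and a single neutral
slope (spread `σ_r`) is rejected whenever `|r − μ_r| > t_crit·σ_r/√n` —
about 87% of the time at `n = 64`, `α = 0.10`. The classifier is thus
deliberately liberal: it maximizes sensitivity to real expansions and leaves
the suppression of isolated false `P`/`N` symbols to the HMM layer, whose
non-adaptive emission distribution (`e_N` puts only a third of its mass on
`Z`) absorbs exactly this behaviour. The consequence is that the per-slope
type-I rate is *not* `α`; the acceptance suite records this honestly (see
"Known limitations").

## The penalized HMM and its decoder

Nominal transitions `p_AN°`, `p_NA°` are damped by `exp(−C_P)` and
`exp(−C_!P)`, where `C_P` counts the current contiguous run of `P` symbols
and `C_!P` the current run of `N`/`Z` symbols; each counter resets when the
other kind of symbol appears. This encodes the biology that an expansion,
once underway, does not stop at random. Because both counters are functions
of the *observed* symbols alone, the transition matrix at every step is
known before decoding; the model is a time-inhomogeneous two-state HMM and
the most likely path is computed exactly by a forward Viterbi pass (path
scores renormalized by the running maximum each step, which preserves the
argmax). A brute-force path enumerator (`decode_brute_force`, capped at 16
symbols) ships as a study utility and independent cross-check.

Numerical choices:

- counters are capped at 50 before exponentiation (`exp(−50) ≈ 2·10⁻²²` is
  zero for any decision);
- two path scores within a relative `1e−12` count as tied; ties prefer
  staying in the current state, and prefer `N` at the end of the sequence —
  deterministic and inertia-consistent;
- the penalty at step `k` uses the run length accumulated strictly before
  `k`; the symbol at `k` then updates the counters (a run must already exist
  to justify staying in `A`).

All populations start in state `N` before the first interval. After
decoding, states are translated back one position (the last repeats): slot
`k` of the result, nominally describing the interval `(t_k, t_{k+1})`,
becomes the state call for the measurement at `t_{k+1}` taken from the
*following* interval. Equivalently, a measurement is called `A` when the
population is still expanding *leaving* that point — which is also how the
synthetic ground truth is defined, keeping the two aligned by construction.
Events are extracted from the shifted sequence; an event's generation span
maps interval `k` to `generations[k+1]`.

### Training

Supervised training counts state transitions and per-state emission symbols
across annotated histories, with annotation row `k+1` supplying the state
for interval `k`. A Laplace-style pseudocount (default 0.5) keeps estimates
defined on small annotated sets; with pseudocount 0, an unvisited state
raises a training error rather than producing a degenerate model. Because
subpopulation proportions sum to one, one subpopulation's significant rise
forces significant falls elsewhere; pooled training data therefore always
contain "passive mirror" points, which is why the non-adaptive emission
distribution has substantial `P` and `N` mass. For parameter-recovery
studies against *known generating* parameters, the optional
`subpopulations` filter restricts training to the driven subpopulation.

## Sampling suggestions

For each event, emissions are scanned from the event's end forward to the
first `N` at position `i`; the suggestion is `i − 1` (the last sample before
the mutant's decline), clamped to the event's end if that would precede the
event, and the final sample if no `N` follows (the mutant overran the
vessel). Each event yields exactly one suggestion; a suggestion landing
inside a later event is reported as a warning, not an error.

## Summary statistics

`compare_annotations` pools all subpopulations and scored measurements into
TP/TN/FP/FN fractions (model `A`/`N` versus annotated `A`/`N`); the
inoculation sample is fixed at `N` and not scored. `summarize_dynamics`
reports events per generation per label (event count divided by elapsed
generations times `J`), the mean/sd of expansion rates over event-internal
intervals, and event lengths in measurement points (a per-generation variant
is an option — point counts match the natural scale of daily sampling).
`event_distribution` reports the length-weighted share of adaptive-event
mass per subpopulation, normalized per experiment, for jackpot-bias
inspection.

## The synthetic generator

`simulate_experiment` emulates the observable of a chemostat VERT run, not
its mechanism: lineages carry exponential fitness weights (wild-type 1,
mutant `1+s` per generation, seeded at a configurable within-host frequency,
default 10⁻³), so a mutant's within-host frequency follows a logistic sweep
and subpopulation shares follow from normalization. Observation draws a
multinomial of the configured FACS total (default 10⁵ cells) over the true
shares, adds optional Gaussian jitter on the proportion scale (default sd
0.005), and renormalizes so each sample sums to the configured total.
Defaults — three labels, 25 samples, 10 generations per sample — mirror a
typical multi-week chemostat experiment. Ground truth marks a measurement
`A` while a mutant lineage is detectable (within-host frequency ≥ 5%, below
95% saturation) and its host's true share is still rising.

What the generator does *not* emulate: drift and clonal interference among
spontaneous mutants (events are planned, not stochastic), instrument-level
FACS artifacts (spillover, gating error), day-to-day volume/media
fluctuations, and annotator disagreement. Passing tests therefore show the
*method* behaves as specified on data matching its own model of the world;
they do not certify error rates on real chemostat data.

`simulate_annotated_history` is a different tool: it samples a
(state, symbol) chain directly from given HMM parameters and realizes it as
a two-subpopulation history whose classified slopes reproduce the sampled
symbols exactly (significant slopes are placed at 2–6× the critical slope,
`Z` slopes exactly at `μ_r`; a constant-total buffer subpopulation absorbs
the complement). It exists so supervised training can be validated against
known generating parameters through the full file-level pipeline.

## Design choices where the design was open

- **Exact Viterbi rather than a per-step greedy argmax.** A greedy local
  rule can never leave state `N` under the default parameters
  (`p_NA°·max e_A = 0.059` is always beaten by staying), so the iterative
  decision rule is implemented as a proper maximum-likelihood path search,
  which the observable counters make exact.
- **`n` in the T statistic is the calibration pool size**, not the length of
  the experiment being analyzed — `μ_r`, `σ_r` are properties of the neutral
  pool.
- **Back-shift boundary:** the final position repeats the last pre-shift
  state, avoiding truncation.
- **Event lengths in points** by default (see above); **rate of expansion**
  is the mean slope over event-internal intervals — the only defined rate
  quantity at this sampling resolution.
- **Missing count cells are errors**; no imputation rule is defensible for
  FACS tables.

## Known limitations

- The classifier's per-slope type-I rate under matched calibration is ≈ 0.87
  by construction of the published statistic (see above), not `α`. The
  acceptance suite contains a test asserting the `rate ≈ α` property; it
  fails, and `scripts/acceptance.py` reports the measured rate
  (`classifier_type1_rate`) without adjustment. Treat `Z`-rate expectations
  with this in mind when calibrating on data whose noise scale matches the
  experiment; with a calibration pool noisier than the analyzed experiment
  (the published `σ_r = 0.018` against clean data) the classifier behaves
  conservatively instead.
- Unsupervised (Baum–Welch) training, more than two hidden states, and
  continuous-time observation models are out of scope.
- Slow expansions whose slopes stay below the significance threshold
  (roughly `< t_crit·σ_r/√n` per generation) are invisible to the classifier
  and hence to the decoder.

## Problem sizes used by tests and the acceptance script

Type-I measurement: 64 calibration slopes and 10,000 evaluation intervals.
Decoder cross-check: 1,000 random sequences of length ≤ 50 (plus three-way
brute-force checks at length ≤ 9). Parameter recovery: 100 chains × 100
intervals (10,000 annotated points). Sweep recovery: 20 replicate
experiments of 25 samples, 3 labels. These sizes give binomial standard
errors comfortably inside the asserted tolerances while keeping the whole
suite in the seconds range.
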