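# Methods

## Model and procedure

The selector treats the `n` candidate features as players of a simple
(0/1-valued) cooperative game and scores each by its Banzhaf power. All
information quantities are computed on discretized features, in bits.

For a focal feature `F_i` and a coalition `S ⊆ N \ {F_i}`:

- relevance of a coalition to the class:
  `R(S;C) ≈ (1/|S|) Σ_{j∈S} I(F_j;C)` (implemented as `relevance`; it is
  exposed but does not enter the swinger rule, mirroring the selection
  criterion, which depends only on the two conditions below);
- relevance change due to knowing `F_i`:
  `ΔR_i(S) = (1/|S|) Σ_{j∈S} [I(F_j;C|F_i) − I(F_j;C)]`;
- interdependent count: `γ_i(S) = #{j∈S : I(F_j;C|F_i) > I(F_j;C)}`
  (strict inequality).

`F_i` swings `S` iff `S` is nonempty, `ΔR_i(S) ≥ 0`, and
`γ_i(S) ≥ |S|/2` (real-valued half: a coalition of 5 needs 3). The
Banzhaf power is `β_i = η_i / 2^(n−1)` with `η_i` the number of swung
coalitions. The characteristic function is never materialized; the
swinger predicate realizes it implicitly. Note the induced game is not
guaranteed monotone for arbitrary interdependency matrices; this is a
property of the criterion, recorded rather than "fixed".

Everything the game needs is the relevance profile `r_j = I(F_j;C)` and
the interdependency matrix `D[i,j] = I(F_j;C|F_i) − I(F_j;C)` (diagonal
fixed at 0, never read). `D[i,j] > 0` flags synergy, `D[i,j] < 0`
redundancy.

### Conventions the criterion leaves open

- **Empty coalition.** The mean in `ΔR_i` is undefined at `S = ∅`; the
  empty coalition is never a swinger, while the denominator stays
  `2^(n−1)`. Hence `max β = 1 − 2^−(n−1)`, which is what the all-positive
  row limit returns.
- **Inequalities.** Relevance change uses `≥ 0`; interdependence uses
  strict `>`; the half-count threshold is evaluated in real arithmetic.
- **Normalization.** `β_i` is reported as a fraction in `[0,1]` (the
  swinger count divided by `2^(n−1)`), never as a raw count.

### Computing β

Exact enumeration of all `2^(n−1)` coalitions is the default up to
`n = 22` features, implemented as a subset-sum dynamic program over
bitmasks (three arrays of length `2^(n−1)` accumulate coalition size,
the row-sum of `D[i,·]`, and the positive count; `sum ≥ 0` is equivalent
to `mean ≥ 0`). Beyond that, coalitions are sampled uniformly — each
other feature joins independently with probability 1/2 — giving an
unbiased estimate with binomial standard error
`√(β̂(1−β̂)/n_samples)`; default 20,000 samples per feature, per-feature
RNG streams spawned from one shared seed, fully reproducible. Ranking
sorts by descending β with ties broken by ascending feature index
(stable), so rankings are deterministic.

## Feature extraction

Each channel is decomposed by a multi-level DWT using the standard named
Daubechies filter banks (`db8` for ECG II, `db4` for ABP/PLETH, 6
levels) rather than constructing the scaling/wavelet functions from the
two-scale recursion — numerically identical and standard practice.
Whole 5-minute records are transformed; no windowing. Boundary handling
is symmetric extension by default and configurable; periodization makes
the transform orthogonal, which the energy-conservation test uses.

A 6-level cascade yields 7 outputs per channel (`d1..d6, a6`) but the
record is summarized by 6 vectors per channel. Which 6 is configurable
(`grouping_mode`): the default keeps `d1..d5, a6`; the alternatives are
`d1..d6` and `a1..a5, d6`. All three give 18 vectors for 3 channels.

Per vector, 20 order-invariant features: mean, mode, median, max, min,
range, variance, σ, 3rd and 4th central moments (`Σ(X−X̄)^k/N`), σ/mean,
kurtosis `μ4/σ⁴`, skewness `μ3/σ³`, harmonic mean `N/Σ(1/X_i)`,
interquartile range, Shannon entropy of energy `−Σ X_i² log2 X_i²`
(the unnormalized wavelet-entropy convention; a normalized variant that
first scales energies to sum to one is available behind a flag, default
off), log energy `Σ ln X_i²`, and three exceedance counts
`n_T(α) = #{|X_i| > α}` at `α = max|X_i|/2`, `ΣX_i²`, and `5ΣX_i²`
(each computed per coefficient vector; the magnitude reading of
`max{X_i}` keeps the threshold consistent with the counts' use of
`|X_i|`). Degenerate inputs stay finite by convention: zero variance
forces kurtosis, skewness and the coefficient of variation to 0 (a zero
mean likewise zeroes the coefficient of variation); any zero coefficient
sends the harmonic mean to 0 (its limit as one reciprocal diverges); log
energy floors `X_i²` at the smallest positive float. The "mode" of
continuous coefficients is the midpoint of the fullest bin of a 100-bin
equal-width histogram over `[min, max]` — a convention, since the mode of
continuous data is otherwise ill-defined. Log energy uses the natural
log; the Shannon energy entropy uses log2.

## Quantization and estimation

Features are discretized column-wise with a Lloyd-Max scalar quantizer,
5 levels by default. Initialization is at the `(2k−1)/(2q)` sample
quantiles; iterations alternate midpoint boundaries and centroid levels
until the relative MSE improvement falls below `1e−6` or 500 iterations;
empty cells are re-seeded at the midpoint of the most populated cell.
All deterministic — no RNG. Boundary ties encode to the lower level
(left-closed cells). Constant columns collapse to a single level, get
`r_j = 0` and zero `D` entries, and can never be swingers.

Entropies are raw plug-in (empirical) estimates in bits; Miller–Madow
bias correction exists behind a flag, default off. MI and CMI are
computed from joint entropies (`I(X;C|Z) = H(X,Z)+H(C,Z)−H(X,C,Z)−H(Z)`)
and clipped at 0 against float rounding. Probabilities are summed in
sorted order so entropy depends only on the count multiset, which makes
MI symmetry exact. The log base is a convention: only signs and
orderings of `D` enter the game, and those are base-invariant.

Plug-in estimation has a known consequence for the game: conditioning
inflates the estimated CMI by a finite-sample bias that grows with the
conditioning alphabet, so small `D` entries between genuinely
independent features drift slightly positive. Features with no signal at
all can therefore reach high β alongside truly synergistic ones (their
rows are uniformly "weakly positive"), while informative-but-redundant
features are pushed down hard by their negative entries. The selector's
strength is hence recovering synergy and demoting redundancy, not
filtering pure noise — visible in the worked example, where the noise
columns tie near the top. Miller–Madow correction reduces but does not
remove this.

## Synthetic data

`synth_feature_table` builds tables with known column roles: marginal
features are class-conditional Gaussians with a fixed effect size of
d = 1; redundant features are copies of marginal ones plus N(0, 0.15)
jitter; each XOR pair renders two independent balanced sign variables as
±1 Gaussian mixtures (component SD 0.4) whose XOR equals the balanced
binary label except on a 5% flipped fraction; noise features are
independent standard normals. Defaults (n = 3000; 2 marginal + 10
redundant + 1 XOR pair + 2 noise = 16 features) define the synergy
benchmark: exactly the four features without univariate signal (XOR pair
+ noise) occupy the bottom MI quartile, and the twelve informative
columns descend from only two independent sources, so a univariate top-5
is heavily redundant and the benchmark's AUC margin is predictable.
Effect sizes are fixed so the power of the recovery tests is predictable.

`synth_vital_records` emits 3-channel quasi-periodic records (Gaussian-
bump ECG complexes; smoothed pulse waves for ABP/PLETH; ~75 bpm with a
slow respiratory phase wobble) plus Gaussian noise, 5 minutes at 250 Hz
by default, with the target cohort's true-alarm fraction (170/220).
True-alarm records get an event in the final 10 s (beat rate ×1.8,
amplitude ×0.6), mimicking an arrhythmia onset just before the alarm.
The waveforms are deliberately minimal — they exercise the pipeline's
shape and determinism, not physiological fidelity, and specific
arrhythmia morphologies are not simulated. Passing tests on them shows
the machinery is correct, not that the features are clinically
discriminative; real-data artifacts (dropout, pacing interference,
movement) are absent.

## Evaluation

`run_evaluate` does stratified k-fold cross-validation (10 folds, fixed
fold seed) and reports accuracy, sensitivity (recognized true alarms
over all true alarms; the true alarm is the positive class), specificity
(recognized false alarms over all false alarms), and AUC over pooled
out-of-fold probabilities. Folds whose training split degenerates to a
single class are skipped and counted. The default classifier is Gaussian
naive Bayes; any sklearn-style estimator can be plugged in. The synergy
benchmark uses a random forest, because a naive-Bayes model is additive
per feature and cannot represent an XOR decision boundary at all — the
method's payoff is only visible with classifiers that model
inter-feature dependencies.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
inputs: benchmark tables of 3000 × 16, waveform cohorts of 4–8 records
(full 5-minute length where the structural counts are measured, 6–8 s
elsewhere), exact-vs-Monte-Carlo comparisons at 12 features with 50,000
coalition samples, and 40 / 20 benchmark replicates. These sizes keep
every Banzhaf computation on the exact path except where the Monte-Carlo
path is itself under test.

## Known limitations

- Exact enumeration is exponential; at the 360-feature scale of a full
  3-channel extraction only the Monte-Carlo path is feasible.
- Plug-in MI at 5 quantization levels is biased upward in small samples
  (see above); rankings at small n should be read with that in mind.
- The quantizer is univariate; joint structure is only seen through the
  pairwise conditional terms of `D`, and the relevance-change
  approximation is itself a first-order (pairwise) surrogate for
  `I(S;C|F_i)`.
- Record I/O is delimited text only.
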