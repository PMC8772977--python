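# Methods

## Model and procedure

The package targets sparse linear-model feature selection: a response
`Y ∈ ℝⁿ` assumed to depend on a small subset of the `p` columns of
`X ∈ ℝⁿˣᵖ`, evaluated through the least-squares loss
`L(A) = (1/2n)‖Y − X_A β_A‖²` for an active set `A`. Two components are
original to this package and documented in detail here; everything
standard around them (regression fits, cross-validation, rank statistics
distributions, delimited IO) is delegated to scikit-learn, scipy and
pandas.

### Capped splicing local search (`splicing`)

Given a binary individual, the search

1. partitions features into active `A` / inactive `I`;
2. if `|A| > Smax`, demotes the `|A| − Smax` lowest backward-sacrifice
   members of `A` (del/add step), so the subset size budget always holds
   on output;
3. repeats swap sweeps until a full sweep improves the loss by less than
   the threshold `τ = tau_const·|A|·log(p)·log(log n)/n`, then merges
   `A`/`I` back into a bit vector.

One sweep computes both sacrifice score vectors once from the entering
state and holds them fixed. For each exchange size `k` in ascending
order, a candidate is built *from the sweep's entering partition*: drop
the `k` lowest-ξ members of the entering `A`, add the `k` highest-ζ
members of the entering `I`, refit, and replace the current best state
iff the candidate loss is strictly lower. This resolution keeps the
candidate sets well defined after an acceptance (scores computed for the
entering members cannot be attached to swapped-in members) and makes the
accepted-loss sequence strictly decreasing by construction. Ties in
either score are broken toward the lowest feature index, and a rank set
never exceeds `k` under ties.

Numerical choices:

- **Fits.** Active-set coefficients come from the normal equations; when
  the Gram matrix is singular or `|A| ≥ n`, a ridge-stabilized solve with
  relative penalty `ridge_eps` (default 1e-8, scaled by the mean Gram
  diagonal) stands in. The condition-number guard is 1e12.
- **Del-step scoring at very large `|A|`.** Random initial individuals
  can carry more active bits than samples, where a joint fit is
  underdetermined. When `|A| ≥ 0.9·n` the del step ranks features by
  marginal coefficients `β_j = X_jᵀY / X_jᵀX_j` instead; the swap phase
  always uses joint fits because the cap has already reduced `|A| ≤ Smax`.
- **`d` normalization.** The residual correlation `d_j` is always divided
  by `n`, consistently in the state and in the forward sacrifice.
- **Standardization.** Columns are internally centered and unit-scaled
  (and `Y` centered) by default before scores and losses are computed,
  so sacrifices compare correlation-like quantities rather than raw
  scales; `standardize=False` disables this for analyses that need raw
  losses (for example comparisons against exhaustive enumeration on
  already-centered data). Selection is always reported on the original
  column indices.
- **Degenerate inputs.** An empty active set uses `L = (1/2n)‖Y‖²` with
  forward sacrifices against `Y` itself; since swaps preserve `|A|`, an
  empty individual passes through unchanged. Zero-norm columns receive
  forward score 0 inside sweeps (never attractive); the scalar
  `forward_sacrifice` raises on them because such columns should have
  been filtered. `max_outer_iters` (default 100) caps the outer loop
  against floating-point τ-cycling.
- **τ logs.** Natural logarithms; `τ` requires `n ≥ 3` so that
  `log(log n) > 0`, and `τ(|A|=0) = 0`.

### Memetic evolution loop (`ga`)

Individuals initialize with i.i.d. Bernoulli(`s/q`) bits (`s` the
expected starting subset size). Each generation copies the best
individual unchanged (elitism — the best-fitness trace is therefore
non-increasing), then fills the population with offspring: two parents
drawn by roulette on inverse fitness, uniform crossover with disruption
probability `P0` (common bits always preserved; per differing position
the offspring keep their own parent's bit with probability `P0`,
otherwise exchange), and splicing improvement of both offspring.
Offspring pairs can overshoot the population size by one; the overflow
individual is discarded to keep the size constant at `N`. The loop stops
at `T` generations or after `stall_limit` (default 5) consecutive
generations without improvement of the best fitness. Exact-zero fitness
is floored at 1e-12 before the inverse-fitness wheel. Fitness values are
cached on the bit vector, and all randomness flows from one seeded
generator recorded in the run report.

Mutation is absent by design — splicing replaces it. The ablation mode
(`ablation_ga=True`) restores bit-flip mutation at rate `1/q` (no
splicing, including at initialization) so the memetic design can be
compared with the plain GA under identical budgets.

Defaults mirror the sheep body-weight study configuration: `N = 20`,
`T = 30`, `s = 2000`, `tau_const = 0.01`, per-trait SVR presets
(`C`, `ε`, `σ`) in `fitness.TRAIT_PRESETS`, and a 170/70 train/test
split protocol in `data_model` (seeded shuffle by default, ordered split
available — whether the original split was randomized is not stated, so
both are exposed).

### Fitness (`fitness`)

Fitness is the MSE of a regressor on the selected columns. The SVR uses
the Gaussian kernel `k(x,x') = exp(−σ‖x−x'‖²)` — a precision-style
parameterization chosen because published values like `σ = 10⁻⁵` are
implausible as bandwidths — with fixed solver tolerance (1e-4) and
iteration cap for determinism. What data the fitness is computed on
during evolution is genuinely open; the default is 5-fold CV MSE on the
training set, because training MSE with a near-zero ε-insensitive loss
overfits trivially; `eval_scheme="train"` selects the literal reading.
An empty subset scores the variance of `Y` (mean-only model).

### Method comparison (`stats_eval`)

Within-dataset mid-ranks (ties averaged, no tie-correction factor in the
chi-square), Friedman `χ²_F = 12N/(k(k+1))·(ΣR̄_j² − k(k+1)²/4)`,
Iman–Davenport `F_F = (N−1)χ²_F/(N(k−1) − χ²_F)` against
`F(k−1, (k−1)(N−1))`, and Holm step-down on pairwise normal statistics
`z_j = (R̄_j − R̄_c)/√(k(k+1)/6N)` against a control. The benchmark grid
shipped in `datasets` reports average ranks at two-decimal precision;
`F_F` is sensitive to that rounding (5.579 from two-decimal ranks versus
5.522 from exact fractions), so `compare_methods(rank_precision=2)` and
the acceptance script compute the omnibus statistics from the
display-precision ranks, matching the published pipeline. Post hoc
conventions vary between published sources; this package implements
standard Holm step-down and makes no attempt to match any specific
published post hoc p-value table.

## Synthetic data generator (`synthetic`)

Rows of `X` are i.i.d. zero-mean Gaussian with AR(1) column correlation
`ρ` (generated by the recursion `x_j = ρx_{j−1} + √(1−ρ²)z_j`, so the
population lag-`h` correlation is `ρ^h`). The true support is a uniform
draw of `s*` columns; coefficients have Rademacher signs and magnitudes
uniform in `[beta_low, beta_high]` (defaults 1–2); noise is i.i.d.
`N(0, noise_sd²)`, or derived from a requested signal-to-noise ratio via
the population signal variance `βᵀΣβ`. This emulates the statistical
structure the splicing search assumes — linear signal, sparse support,
homoscedastic noise. It does **not** emulate real expression/genotype
data: no discrete genotype coding, allele-frequency spectra, LD-block
correlation, batch effects, heavy tails, or missingness. Passing tests
therefore certify algorithmic correctness and recovery behaviour under
the assumed model, not performance on any real dataset.

Benchmark protocol: support-recovery and optimality studies start the
local search from a random individual with expected size
`min(p, 4·Smax)/p · p` active bits (i.e. `p_initial = min(1, 4·Smax/p)`),
a moderate oversizing that exercises both the del cap and the swap
phase; the evolution benchmarks use expected initial size 20 at
`p = 500`, since an expected size above `p` would make every initial
individual the full model.

## Problem sizes used in the shipped studies

Chosen as the package's standard desk-scale benchmarks: splicing
optimality versus exhaustive enumeration at `n=50, p=10, s*=3` (30
replicates), support recovery at `n=200, p=500, s*=5, noise sd 0.5` (50
replicates), and the memetic-versus-GA ablation on the same design (25
paired runs, linear CV fitness). Larger designs behave the same but add
nothing to the checks.

## Known limitations

- The swap sweep refits every candidate subset from scratch rather than
  using rank-one updates; fine for `Smax` up to a few hundred, wasteful
  beyond.
- The splicing search is greedy per sweep and offers no global optimality
  guarantee; the GA layer supplies the exploration.
- `Smax` is a hard user-set budget, not searched adaptively with an
  information criterion; a grid over `Smax` (and `P0`) is the intended
  tuning protocol.
- The generator's SNR handling assumes the AR(1) covariance; with custom
  covariance structures supply `noise_sd` directly.
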