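# Methods

## Model and estimation

`repmod` analyzes two-instance repeated measures designs by difference-score
regression. Each participant i contributes two outcome measurements and a
vector of between-participant moderators W_i. The working model allows the
intercept and every moderator coefficient to differ by condition j:

    Y_ij = b_0j + Σ_k b_kj w_k(W_i) + e_ij,

where the design terms w_k are the moderators themselves (additive model)
or all products of nonempty moderator subsets (multiplicative model).
Errors are assumed mean zero with condition-specific SDs σ1, σ2,
correlation ρ within a participant, independent across participants.
Subtracting the second-listed instance from the first gives

    Y_Di = Y_i1 − Y_i2 = b_0 + Σ_k b_k w_k(W_i) + e_i,

with b_k the per-condition coefficient *differences* and e_i iid with
variance σ1² + σ2² − 2ρσ1σ2. OLS on this single equation therefore tests
every condition × moderator-term interaction at once; no correlation
parameter needs to be estimated. Coefficient covariance uses the unbiased
residual variance (denominator n − q − 1, q = non-intercept columns), so
all t ratios refer to t(n − q − 1). The per-condition fits of Y_i1 and
Y_i2 on the same design are reported alongside: their moderator
coefficients are the simple slopes of each moderator within each
condition, and by construction each difference-model coefficient equals
the difference of the corresponding per-condition coefficients (verified
to 1e−10 in tests).

The subtraction order is always first-listed minus second-listed outcome;
every reported sign is documented against that order (a positive
difference-model intercept means the first instance is larger at
moderator zero).

## Probing

The conditional effect of condition at moderator values w is θ(w) = l′b
with l the evaluation of each design term at w (intercept weight 1), and
var(θ) = l′Σl. Pick-a-point defaults probe each continuous moderator at
its mean and mean ± 1 SD (sample SD, ddof = 1); the percentile option uses
the 16th/50th/84th percentiles computed by linear interpolation between
order statistics (numpy's default), which keeps every probe inside the
observed range. Dichotomous or indicator-coded moderators are probed at
their observed codes. Multi-moderator probes take the Cartesian product of
per-moderator value lists, last moderator varying fastest.

The Johnson–Neyman procedure applies to a single continuous moderator
(at least three distinct values; it is refused otherwise with an
explanatory message). Setting |θ(W)|/se(W) equal to the two-sided critical
t* and squaring gives

    (b1² − t*²var(b1)) W² + 2(b1b0 − t*²cov(b0,b1)) W + (b0² − t*²var(b0)) = 0,

solved in closed form. A quadratic coefficient below 1e−12 of the
coefficient scale degrades to the linear solution; a negative discriminant
means no real boundary. Real solutions are filtered to the observed
moderator range: in-range roots are reported with the percentage of
observations strictly above each (ties count below — deterministic and
matching the "% above" convention to rounding), out-of-range or imaginary
solutions are retained with flags but never interpreted as regions,
since there is no data to support a trend beyond the observed range. The
region table evaluates θ on a 21-point even grid over the observed range
with the in-range roots spliced in — 21 points balance readability and
resolution; significance is constant between consecutive grid points that
do not straddle a root (property-tested). Every reported root
back-substitutes to |t| = t* within 1e−6 and is cross-checked in tests
against a 100,001-point grid scan for sign changes of |t(W)| − t*.

## Centering and coding

Continuous moderators are mean-centered by default so that the intercept
and lower-order terms are interpreted at the sample average; original
means are stored so probe values can be given on the raw scale (the CLI's
`--wmodval` is raw-scale and is translated internally; the report prints
both scales). Numeric columns whose values are a subset of {0, 1} are
treated as dichotomous codes and left uncentered by default, so "moderator
zero" remains the reference group; a per-column flag can override this.
Categorical columns (declared, or any non-numeric column) are never
centered and are contrast-coded into k − 1 columns before entering the
design — indicator coding with the first sorted label as reference, or
Helmert coding (column j: −1 for earlier categories, j for category j + 1,
0 after; columns sum to zero). The two codings span the same column space
and give identical R² (tested). Product terms in the multiplicative model
are products of the centered columns, not centered products, so each
lower-order coefficient is conditional on the other moderators being at
their sample mean (or reference level).

Centering changes only the intercept parameterization: R², non-intercept
additive coefficients, and Johnson–Neyman boundaries mapped back to the
raw scale are invariant (tested).

## Missing data and degenerate inputs

Rows with a missing value in any named column are dropped listwise and
the count is reported — difference scores require complete pairs. At
least q + 2 complete rows are required. Rank deficiency is detected by a
condition-number threshold of 1e12 on the column-scaled design, a
deterministic and reproducible failure mode. A constant response yields
coefficients but an undefined-R² flag rather than a spurious 0/0; a
perfect fit reports F = ∞ with p = 0. Two-sided p values are used
throughout, matching how such analyses are reported; `conditional_effect`
accepts `alternative="greater"/"less"` for directional questions.

## Synthetic data generator

`repmod.synthetic.generate` draws moderators (normal, uniform, or
bernoulli(p) coded 0/1 — the convention for randomized two-arm
treatments), then builds both instances' outcomes from separate
coefficient vectors plus bivariate-normal errors with SDs σ1, σ2 and
within-person correlation ρ. Defaults emulate a small clinical pre/post
study: n = 40 participants on a roughly 6-point outcome scale, one
standard-normal moderator whose slope is near zero in the first instance
(0.03) and substantial in the second (0.43), intercepts 3.5/3.3, unit
error SDs, ρ = 0.5. All randomness flows from one integer seed;
`simulate_test` spawns per-replicate child seeds deterministically so any
single replicate is individually reproducible.

What the generator emulates: the linear per-condition structure, the
within-person error correlation that motivates the design, dichotomous
treatment coding. What it does not: non-normal or heteroscedastic errors,
measurement error in moderators, floor/ceiling effects on bounded scales,
missingness mechanisms. Passing tests therefore demonstrate correctness
of the estimator and probing algebra under the assumed model, not
robustness to those violations.

Monte-Carlo checks (test suite sizes, chosen as the package's standard
validation workload): type-I error of the interaction test at n = 100
with 2000 replicates must lie within 0.05 ± 0.015 (≈3 binomial SEs);
coverage of the 95% CI for θ(w) at the moderator mean within 0.95 ± 0.02
at 2000 replicates; coefficient unbiasedness within 3 Monte-Carlo SEs at
500 replicates; the difference-model residual variance reproduces
σ1² + σ2² − 2ρσ1σ2.

## Design choices and limitations

- Wide form only (one row per participant); long-form data must be
  reshaped by the caller. Designs with more than two instances,
  residualized-change or autoregressive change models, multilevel
  replicates, imputation/FIML, and robust or weighted standard errors are
  out of scope.
- A time-constant covariate whose effect does not differ by condition
  cancels in the difference score; a covariate whose effect may differ by
  condition should simply be entered as a moderator.
- With one moderator the additive and multiplicative designs coincide;
  the CLI maps both model numbers onto the same computation.
- Johnson–Neyman is deliberately limited to one continuous moderator;
  higher-dimensional regions of significance are hard to interpret and
  pick-a-point is preferred there.
- When several categorical moderators are probed jointly, the default
  probe grid is the Cartesian product of per-column codes and can include
  combinations not observed together; supply explicit probe values in
  that case.
- The report renderer only formats module-level results (no independent
  recomputation) at a fixed, configurable precision (default 4 dp), and
  identical inputs render byte-identical text.
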