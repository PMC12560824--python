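# Methods

## The estimation problem

Across steady-state cultures (chemostats at set dilution rates under
different limiting nutrients), how much information about a metabolic
reaction's rate is carried by (1) the abundance of its catalysing enzyme,
(2) the abundances of proteins in its pathway subsystem, and (3) the whole
proteome? `proteorate` answers this with two stages: scale-free covariation
statistics per focal enzyme–rate pair, and penalized linear prediction with
nested cross-validation at the three scales.

## Statistical model

For reaction *j* with rate vector *vⱼ* over conditions and predictor matrix
*P* of log₂ protein abundances:

    v_j = β₀j + Σ_i β_ij · P_i

Rates stay on their native linear scale (they may be zero or negative —
they are signed fluxes); only predictors are logged, since protein
abundances are approximately log-normal. Coefficients are estimated by
minimizing, with predictors internally centered and scaled to unit
population variance on the training split,

    (1/2n)·Σ(y − β₀ − Xβ)² + λ·[α‖β‖₁ + ((1−α)/2)‖β‖₂²]

with α = 1 (lasso), α = 0 (ridge) or λ = 0 (OLS, used for the
single-predictor focal scale). This is the glmnet/scikit-learn objective
convention, chosen so λ values are portable and the single-predictor
solutions are closed-form (ridge β = ρ/(1+λ); lasso β = soft(ρ, λ)) —
which the test suite exploits as exact oracles. The intercept is never
penalized; coefficients are reported back on the caller's predictor scale.
Ridge is solved in closed form via SVD (one decomposition yields the entire
λ path); lasso uses coordinate descent (scikit-learn), cross-checked in the
tests against an independent proximal-gradient solver.

### Cross-validation

Outer schemes: leave-*n*-out (default *n* = 2, 100 random iterations),
leave-media-out (every condition of one limiting nutrient held out),
leave-growth-rate-out (all media at one exact dilution rate held out), and
leave-one-out. Within each outer training split, λ is selected on a
100-point log-spaced grid from λ_max (smallest λ zeroing the lasso) down to
λ_max·10⁻⁴ by inner k-fold CV (k = min(10, n_train)), minimizing mean
squared validation error; ties resolve to the larger λ. The minimum-error
rule (not 1-SE) is the default and is recorded in output metadata.
Standardization statistics are computed inside each training split only, so
no information from held-out conditions reaches any fit — the test suite
audits this by physically deleting held-out conditions from all inputs and
checking that refits are bit-identical.

Held-out predictions are pooled per condition by arithmetic mean across
iterations, and each reaction gets one cross-validated
R² = 1 − SSE/SST, with SSE over pooled out-of-fold predictions and SST from
the observed values. R² < 0 is meaningful (worse than predicting the mean).
An alternative pooling — summing SSE over all fold predictions without
per-condition averaging — is computed alongside (`cv_r2_fold_sse`).

### Filters and skip rules

* Focal scale: only reactions mapped to exactly one protein whose protein
  maps back to exactly that reaction (reason code NOT_ONE_TO_ONE
  otherwise).
* Subsystem scale: only subsystems with **more than five** quantified
  proteins (SUBSYSTEM_TOO_SMALL otherwise).
* Any outer fold whose training response is constant — e.g. rates that are
  zero except in one condition, under grouped CV — skips that
  reaction × scheme (CONSTANT_RESPONSE). Skips are flagged, logged and
  counted, never silently dropped.
* Covariation stage: user-specified conditions (e.g. genetically modified
  auxotroph cultures) can be excluded from both series before correlating.

### Covariation statistics

Spearman (average ranks for ties; the tie-free case uses the exact
rank-difference formula so perfect monotonicity gives exactly ±1), Pearson
with and without log₂ transform of abundances, and mutual information by
the Kraskov–Stögbauer–Grassberger k-NN estimator (variant 1, default
k = 3, Chebyshev metric). Small negative MI estimates are clipped to zero
with a flag; inputs with ties at more than half the points are flagged, as
the estimator assumes continuous marginals. Spearman is computed from raw
abundances; by rank invariance this equals the logged version.

## Synthetic chemostat generator

The generator emulates a factorial steady-state design: M limiting media ×
D dilution rates (defaults 5 × 5; dilution grid 0.05–0.30 h⁻¹, typical
chemostat range). Per protein *i* and condition *c*:

    log₂ e_ic = b_i + s_i·g_c + m_i,media(c) + ε_ic

with baselines b ~ N(0, 1), growth slopes s ~ N(0, 0.5), media effects
m ~ N(0, 0.5) and noise ε ~ N(0, noise_sd_log2²), default 0.25 — giving
log-normal abundance marginals. Rates are deterministic closed forms of the
realized (noisy) abundances:

* **simple-constant** (10): v = k·e — the naive regime; focal Spearman is
  exactly +1 by construction, at any noise level.
* **simple-hidden** (20): v = k·e·S_media, with a media-specific substrate
  factor log₂S ~ N(0, hidden_substrate_sd_log2²) that no protein reports
  directly — focal covariation is weakened by hidden supply.
* **branched** (10): v₁ from the two-enzyme competition steady state, with
  the competitor's media response equal to coupling_slope (default 2.0)
  times the focal's — focal covariation can invert. Substrate supply grows
  with dilution rate, C_c = C₀·(1+g_c), tying rates to growth without
  making them collinear with any single protein.

Rate constants k, k₁, k₂ are log-uniform over [½, 2] (C₀ over [1, 4]); each
motif plus five bystanders drawn from the 150-strong bystander pool forms
one annotated subsystem (6–7 quantified members, just above the >5
inclusion rule; bystanders may belong to several subsystems, as real
pathway annotations overlap). A `truth` side-channel records every latent
draw, so tests re-derive all rates independently and exactly.

Two generator constants are set by the qualitative structure the benchmark
must exhibit — that predictive information increases from focal through
subsystem to proteome scale, as in real chemostat data. With media effects
fixed at sd 0.5, this requires subsystems that are informative but
incomplete: five bystanders per subsystem (enough to identify media
noisily, too few to average out measurement noise) and
hidden_substrate_sd_log2 = 2.5 (substrate pools across limitation regimes
vary by orders of magnitude in metabolomic surveys, so a ~6-fold typical
swing is realistic). At these defaults the benchmark's median
cross-validated R² is 0.16 (focal) < 0.77 (subsystem) < 0.81 (proteome) at
seed 0.

All draws derive from one seed through named substreams; regeneration is
bit-identical, and different seeds differ.

### What the benchmark does and does not show

The generator produces linear-in-latent-factors log-abundances, complete
matrices, exactly steady-state rates, 1:1 reaction–protein maps, and
noiseless rate "measurements" (all rate error comes through expression
noise). Real datasets add rate-inference error, missing proteins,
multi-enzyme reactions, allosteric and post-translational regulation, and
pathway topologies far richer than one competition motif. Passing the
benchmark therefore certifies the *pipeline* — transforms, filters, nested
CV without leakage, scoring, determinism — and the qualitative
scale-ordering phenomenon, not quantitative transfer of any R² value to a
real organism.

## Numerical choices and edge cases

* Expression must be strictly positive (log₂ must exist everywhere); zeros
  are an error, not pseudocounted — silent pseudocounts distort log-scale
  statistics. Missing cells are a hard error (complete-case contract).
* z-scoring (display mode for comparing coefficient magnitudes) uses
  sample sd (n−1) and is applied globally across conditions; predictive
  runs standardize within training folds instead. Constant rows are an
  error naming the protein.
* Constant predictor columns within a training split get coefficient 0
  silently; a rank-deficient design is an error for OLS only.
* Quantiles in summaries use linear interpolation between order
  statistics; medians of odd-length sets are exact order statistics.
* TSV round-trips write floats via `repr`, so re-reading recovers binary
  identical values.
* Outer-fold and inner-fold seeds derive deterministically from one user
  seed (numpy SeedSequence substreams, kept below 2³¹); the full pipeline
  writes a manifest (config hash, seed, version) and identical config +
  seed reproduce every output byte-for-byte.

## Problem sizes

The shipped benchmark uses 25 conditions, 200 proteins and 40 reactions
with 100 leave-2-out iterations — large enough for stable medians across
three reaction archetypes at three scales, small enough that the whole
suite (including a noiseless variant and a leave-media-out run) completes
in a few minutes on one CPU.

## Known limitations

* Only first-order kinetics in the toy motifs; no Michaelis–Menten or
  allosteric terms, no post-translational modification channel.
* The elastic-net mixing is restricted to α ∈ {0, 1}; Gaussian responses
  only.
* The Bayesian hierarchical correlation alternative and feature-based
  hypothesis tests (thermodynamics, shared substrates) are out of scope.
* Multi-protein reactions are excluded from the focal analysis by design
  and are not generated.
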