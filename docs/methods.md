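# Methods

## The problem

Generic surveillance of bark- and wood-boring beetles (BWBB;
longhorned, bark, and ambrosia beetles) around ports, airports and
other entry points relies on grids of semiochemical-baited funnel
traps. Budgets limit how many traps an agency can run, so two design
questions matter: *where* should traps sit along the urbanization
gradient around an entry point, and *how many* are needed before the
species list stops growing? `trapsurv` implements the statistical
machinery for answering both from a multi-landscape trapping campaign:
13 landscapes (sites), 16 traps each, season-pooled captures per
(species, trap).

## Urbanization index

Each trap carries two covariates measured in a 250-m buffer: percent
tree cover and the angular percentage of the horizon free of
artificial barriers (roads, buildings). The urbanization index is the
Euclidean distance from the full-natural state (100, 100):

    U = sqrt((100 - tree)^2 + (100 - barrier)^2) / sqrt(2)

The sqrt(2) divisor maps the raw range [0, 100·sqrt(2)] onto [0, 100]
globally. We deliberately do **not** min–max rescale within a dataset:
a global scaling keeps indices comparable across studies and stable
under subsetting. The two deficits are equally weighted; no weighting
scheme is imposed. The index is symmetric in the two deficits,
satisfies U(100−x, 100−x) = x, and is strictly increasing in each
deficit.

## Incidence-based diversity estimation

All diversity work runs on the binary species × trap incidence matrix
of one landscape with T sampling units, incidence frequencies Y_i,
total incidences U = ΣY_i, and Q1/Q2 species found in exactly one/two
traps.

* **Chao2 richness** uses the small-sample-corrected form in both
  branches: `S_obs + ((T−1)/T)·Q1²/(2Q2)` when Q2 > 0 and
  `S_obs + ((T−1)/T)·Q1(Q1−1)/2` when Q2 = 0 — the convention of the
  standard incidence-estimation software family, chosen for
  reproducibility against analyses done with those tools.
* **Sample completeness** (order q = 0) is S_obs / Chao2.
* **Sample coverage** (order q = 1) is `1 − (Q1/U)·Â` with the slope
  factor `Â = (T−1)Q1 / ((T−1)Q1 + 2Q2)`; when Q2 = 0 the standard
  (Q1−1) substitution is used, and Q1 = 0 gives coverage 1 exactly.
* **Rarefaction** of coverage to t < T units uses the combinatorial
  expectation `1 − Σ (Y_i/U)·C(T−Y_i, t)/C(T−1, t)`; **extrapolation**
  to T + t* units multiplies the coverage deficit by Â^(t*+1). The
  stitched profile (rarefied, observed, extrapolated) is nondecreasing
  in t.
* **Expected rarefied richness** `S(t) = Σ [1 − C(T−Y_i, t)/C(T, t)]`
  is the exact mean of observed richness over all C(T, t) trap subsets.
  It doubles as the analytic oracle for the random trap-removal
  simulation (see below).

Binomial-coefficient ratios are evaluated in log space (gammaln), with
C(n, k) = 0 whenever n < k, so profiles remain stable for sampling-unit
counts far beyond any realistic trap grid.

The full order-q completeness profile of the four-step diversity
framework is intentionally out of scope; only q = 0 (completeness) and
q = 1 (coverage) are implemented, as these are the quantities the
surveillance design questions need.

## Beta diversity

Between two traps with a shared species, b and c unique to each, the
replacement (turnover) component is `2·min(b, c)/(a + b + c)` — the
Jaccard-family denominator. Species swaps count; pure richness
differences do not (nested assemblages give 0). A landscape's turnover
is the mean over all unordered trap pairs; pairs where both traps are
empty have an undefined ratio and are excluded (their count is
reported as a diagnostic rather than silently treated as zero).

## Effort-reduction simulation

Traps are removed one at a time; after each removal the percentage of
the landscape's species pool lost by the retained traps is recorded:
`loss%(k) = 100·(1 − S_retained(k)/S_total)` with k retained traps.
"Reduce to k" keeps the last k traps of the removal sequence.
Policies:

* **random** — full removal permutations drawn uniformly without
  replacement (not independent subsets per k, matching stepwise
  removal); 100 randomizations by default, seeded.
* **most_urbanized_first / least_urbanized_first** — deterministic
  orders by the urbanization index, ties broken by lexicographic trap
  id. Policy names are semantic because "ascending/descending" labels
  are ambiguous across reports.

The mean random-removal loss at k equals
`100·(1 − S(k)/S_obs)` analytically (a permutation average reduces to
a subset average); the test suite asserts this identity exactly by
exhaustive enumeration for T ≤ 5 and to ±1.5 percentage points by
Monte-Carlo at n = 1000.

Policies are compared at a fixed k with landscape as a blocking
factor: a likelihood-ratio chi-square between the linear models
`loss ~ landscape + policy` and `loss ~ landscape` (df = number of
policies − 1), plus paired t contrasts with raw p-values (no
multiplicity correction). Landscape-scale relationships (loss,
coverage, turnover, completeness vs 2-km tree cover) use simple OLS
with the F test on 1 and n−2 df.

## Catch models

Per-trap species richness (Poisson) or total abundance (negative
binomial, Var = μ + μ²/θ) is modelled with a log link:

    log μ_ij = α + β·U_ij + u_i,   u_i ~ N(0, σ²)   (landscape i, trap j)

The marginal likelihood integrates u_i by **adaptive Gauss–Hermite
quadrature** (15 nodes recentred at each group's posterior mode and
rescaled by the Laplace curvature) and is maximised with L-BFGS-B on a
standardized covariate; a Nelder–Mead polish runs if the line search
reports failure. statsmodels provides no maximum-likelihood Poisson/NB
mixed model, so this marginal likelihood is implemented here; the
implementation reproduces `lme4::glmer` (nAGQ = 21) on a frozen
fixture to four decimals in slope, SE, σ and intercept, and collapses
to the plain statsmodels GLM when σ is forced to 0. Inference on β is
a likelihood-ratio test against the intercept + random-intercept null
(df = 1); Wald SEs come from a central finite-difference Hessian.
Non-convergence is flagged on the fit object, never silent. A Pearson
dispersion ratio (χ²/df > 1.5) accompanies each fit as a
family-adequacy diagnostic.

Calibration is part of the module's contract and is verified by
simulation: data generated from the model itself (13 × 16 design,
β = −0.015) give nominal 95% Wald coverage of the true slope, and
under β = 0 the LRT rejects at the nominal 5% level (measured 4.7%
over a 600-replicate diagnostic; the shipped test uses 200).

## Synthetic-study generator

The generator emulates the campaign's statistical structure so every
stage is testable without field data:

* **Design**: 13 landscapes × 16 traps; landscape tree cover uniform
  on 10–80%.
* **Covariates**: trap cover = landscape cover + N(0, 14.6), clipped
  to [0, 100]; barrier-free angle = trap cover + N(0, 15.5), clipped.
  These defaults put the trap-level cover–cover correlation near 0.81
  and the tree–barrier correlation near 0.85 (clipping attenuates both
  slightly; accepted). Correlation is induced by shared structure, not
  rejection sampling, so targets are approximate but generation is
  O(n).
* **Community**: 150-species pool with lognormal (sd 2.5) *relative*
  abundances normalised to an expected 280 individuals per trap at
  full naturalness. Normalising to a fixed community total encodes
  resource limitation: enlarging the pool makes species rarer rather
  than adding individuals, which is what makes completeness fall with
  pool size. Each species is present in each landscape with
  probability 0.5 (occupancy thinning); counts are negative binomial
  (θ = 0.4) around `exp(α_s + β·U + u_i)` with β = −0.015 and
  landscape intercepts u_i ~ N(0, 0.3²). 7% of species carry a
  non-native label (label only — no distinct dynamics); guild labels
  follow a rough longhorned/bark/ambrosia mix.

Under these defaults a study realises per-landscape observed richness
≈ 35–45, completeness ≈ 0.75, coverage ≈ 0.92, within-landscape
turnover ≈ 0.55, and random-removal species loss ≈ 22% at half effort
and ≈ 42% at quarter effort — the regime of a season-long BWBB
campaign. What the generator does **not** emulate: spatial
autocorrelation among traps, dispersal and barrier permeability,
phenology within the season, distinct non-native dynamics, and
taxonomic structure. Passing tests therefore demonstrate correctness
of the estimators and the recovery of log-linear urbanization effects
under idealised mixing — not robustness to spatially structured or
temporally aggregated field data.

One known gap between the generator and a real campaign: because trap
placement noise is purely within-landscape, the correlation between
per-landscape *mean* trap cover and landscape cover is ≈ 0.99, higher
than a field deployment would show. Making it lower would require a
landscape-level placement bias, which injects cover-independent noise
into the landscape-mean urbanization index and visibly dilutes the
loss-vs-tree-cover relationship; the trap-level calibration was chosen
instead.

## Numerical and design choices

* Percentages validated to [0, 100] at parse time with row-numbered
  errors; duplicate trap ids within a landscape rejected.
* Empty traps are retained as all-zero matrix columns — a zero-catch
  trap is still a sampling unit, and coverage formulas count units.
* Captures are pooled per season; collection-interval structure is not
  modelled.
* Species identity is an opaque string key; no taxonomic
  normalisation.
* Matrix row order is sorted lexicographically and column order
  follows the trap table, so construction is permutation-invariant in
  the record stream.
* Removal ties: lexicographic trap id, stable and documented.
* The 15-trap landscape case (one damaged trap) is supported — any
  T ≥ 2 — and percentages normalise out differing T.
* Seeds are mandatory wherever randomness enters (generator config,
  random-removal scenarios, pipeline config); reruns with the same
  seed are byte-identical.

## Problem sizes used in the shipped checks

Exhaustive oracles enumerate subsets at T ≤ 8 and full permutations at
T ≤ 5. Monte-Carlo convergence uses 1000 randomizations; generator
calibration averages 20 replicates; GLMM calibration uses 50 (coverage)
and 200 (test size) replicates; effect-recovery properties use 25–60
generated studies. These sizes give stable pass/fail behaviour at the
stated tolerances while keeping the default test run fast.

## Known limitations

* The GLMM supports one random intercept (landscape); no crossed or
  nested effects, no spatial terms, no zero-inflation.
* No bootstrap confidence intervals for diversity estimates — point
  estimates only.
* The spreadsheet adapter for externally deposited capture workbooks
  is a best-effort stub; its column mapping must be supplied by the
  user because deposited layouts vary.
* The field-data tier of the acceptance tests requires a local copy of
  the deposited campaign dataset (converted to the canonical CSVs
  under `data/deposit/`) and fails with an explanatory message when it
  is absent.
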