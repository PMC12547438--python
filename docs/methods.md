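# Methods

This note records the model, the procedure, the numerical choices and the
limits of what the synthetic experiments demonstrate.

## Model

Microplastic abundance MP (particles kg⁻¹ d.w. sediment) at a station is
modelled as an unknown function of p = 10 physical seabed predictors,
MP = f(X₁,…,X₁₀), estimated by stage-wise boosting with squared-error
loss:

    f̂(x) = ȳ + ν · Σₘ₌₁..M Tₘ(x)

Each Tₘ is a depth-1 regression tree (stump) fitted to the current
residuals on a random row subsample. Defaults are the survey
configuration M = 400, depth = 1, minobs = 10, with shrinkage ν = 0.1 and
bag fraction 0.5 — the conventional defaults of the gbm family, since
only M/depth/minobs are fixed by the configuration being reproduced; both
are exposed in `BoostParams`. The response is used untransformed (a
log1p switch exists and is off by default). Because only depth 1 is
exercised by that configuration, deeper trees are supported but treated
as an extension.

### Split search

Candidate thresholds are midpoints between consecutive distinct sorted
feature values; a row goes right iff x > t; both children must hold at
least minobs rows; the split maximises S_L²/n_L + S_R²/n_R (equivalent to
squared-error reduction, as the node total is constant); ties break
toward the lowest feature index, then the lowest threshold, by
strict-improvement scanning. `fit_tree` additionally requires the
reduction to exceed 1e-12 of the node SSE, so constant targets yield a
single leaf. A tree with no legal split contributes a single leaf holding
the bag-residual mean, so the ensemble always contains exactly M trees.
Exact ties between *different* features that induce the same partition
can be resolved either way at the last ulp (summation order differs);
predictions are unaffected and the oracle tests compare up to such ties.

The depth-1 training loop is compiled with numba (pure-Python fallback
with identical arithmetic); the recursive `fit_tree` is the reference
implementation and a test pins the two to the same splits.

### Seeding and subsampling

All randomness derives from a master seed through `SeedSequence` streams
(string/int tag paths), so the entire pipeline is a pure function of
(data, params, master seed). Per-tree bags are drawn without replacement
from one seeded uniform (ntrees × n) matrix generated row-major, making
bag m a pure function of (seed, m, n): earlier trees never change when
the ensemble grows. The per-case LOO seed is params.seed + j.

## Model selection

- **LOOMAE** = (1/N) Σ |MPⱼ − M̂Pⱼ| with M̂Pⱼ from a fit on the other
  N−1 cases. Absolute error keeps isolated badly predicted stations from
  dominating. A "run" is a full LOO pass with a fresh seed; the score is
  the mean over `reps` runs (100 in the original procedure; desk-scale
  experiments here use 10, which leaves the Monte-Carlo error of the mean
  well below the between-size differences the tests rely on). The sd of
  a single rep is reported as absent rather than 0.
- **Permutation importance**: per replicate refit of the full model, the
  increase in *training* MAE when one column is shuffled. This is one
  member of the permutation-importance family, chosen for determinism
  and low cost; individual values can be negative by sampling noise, so
  only rankings are interpreted.
- **Forward selection**: variables enter by descending mean importance;
  `select_best_model` takes the size at the curve minimum, ties toward
  the smaller model (parsimony). `tune_parameters` scores a user grid by
  the same replicated LOOMAE, ties toward earlier entries.
- No train/validation split mode exists (deliberately), and no spatially
  blocked cross-validation is implemented.

## Diagnostics

Matheron semivariogram γ(h) = Σ(zᵢ−zⱼ)²/(2|N(h)|) of model residuals,
pairs binned into equal-width great-circle-distance bins up to max_dist
(default: half the maximum pairwise distance); empty bins report count 0
and NaN. A planar metric is available for synthetic tests. Judging
"flat" is inherently visual, so the module reports a 95 % envelope from
199 value-over-location permutations and makes no pass/fail claim.

## Risk mapping

The selected model is evaluated at grid-cell centres; the surface is
relative and deliberately *not* rescaled (an affine `rescale_surface` to
a user-stated range exists, off by default — the mapping from relative
storage potential to absolute abundance is not something the model
defines). Predictions can be mildly negative (boosting is not
constrained to the response range); polygon means are clamped at 0 only
at classification time. Band edges are half-open real-valued versions of
the published integer bands: [0,1000], (1000,2000], (2000,3000],
(3000,∞). Polygon membership is cell-centre containment with boundaries
inside (shapely `covers`); no area weighting, since the overlay being
reproduced is visual. Percentages are over classified polygons;
polygons containing no cell centre are counted as no-data separately.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:

- 56-station tables (configurable) with coordinates scattered around
  uniform cluster centres (σ = 3 % of the bbox span) on a UK-shelf-like
  box, reproducing the close station pairs that motivate the residual
  autocorrelation check;
- 10 standard-normal predictors; names follow the five informative
  seabed variables of the original analysis plus five documented
  placeholders — names are configuration, not semantics;
- response = baseline + Σ effects, truncated at 0, with optional
  gaussian or negative-binomial noise. The NB family is a gamma–Poisson
  mixture with Var = μ + α·μ²; the default truth (five effects of
  ~300–1500 particles kg⁻¹ amplitude, baseline 600, α = 0.3) gives
  counts with mean ≈ 2600 spanning ≈ 0–8000 particles kg⁻¹, matching the
  reported survey spread (mean ≈ 3000, range 0–6933);
- recovery experiments use a variant truth in which every informative
  effect has marginal sd ≈ 500 against gaussian noise sd 500/3, i.e.
  effect-to-noise ≈ 3 for each variable individually;
- prediction grids carry smooth low-rank cosine-basis random fields
  standardised to the station predictor scale; risk layers are random
  convex CCW polygons; residual fields have exponential covariance
  sill·exp(−d/range) + nugget via Cholesky with 1e-10 jitter.

What the generator does **not** emulate: real bathymetry or predictor
rasters, predictor–predictor correlation, spatial correlation between
predictors and coordinates at the stations, detection/recovery error of
the laboratory counts, or preferential survey design. Passing recovery
tests therefore show the pipeline recovers structure *of this kind*, not
that five variables would be selected on any real shelf dataset.

## Problem sizes and budgets

Tests and the acceptance run use desk-scale sizes chosen as the package's
own defaults: n = 56 stations, reps = 10 replicates, 20 × 20 grids, 20
master seeds for recovery rates. These keep the full suite in a few
minutes while leaving Monte-Carlo error far smaller than the effects
asserted.

## Known limitations

- Permutation importance uses training error with refits; out-of-bag
  variants would de-bias it but cost bag bookkeeping the procedure being
  reproduced does not describe.
- LOOMAE on spatially correlated responses is optimistic; the
  semivariogram reports, but does not correct, such structure.
- The exposure percentages depend on the polygon-mean convention;
  cell-level tallies inside polygons would weight large polygons
  differently.
- Negative surface values are possible and are left visible rather than
  clipped, since the surface is declared relative.
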