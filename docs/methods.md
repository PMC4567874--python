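# Methods note

This note records the statistical model, the default parameters and the
numerical design choices behind `npmrocc`, and the scope of the
synthetic generator. It makes no empirical claims beyond what the test
suite and `scripts/acceptance.py` compute.

## The NPMR local-mean model

For a survey table of sites with binary occupancy `y` and mixed-type
covariates, the occupancy estimate at a target point `t` is

    ŷ(t) = Σ_i w_i(t) y_i / Σ_i w_i(t)

with multiplicative weights over the model's predictors

    w_i(t) = Π_p k_p(t_p, x_ip)

where `k_p` is a Gaussian kernel `exp(−(t_p − x_ip)² / 2τ_p²)` for a
continuous predictor with tolerance `τ_p`, and an exact-match indicator
for a categorical predictor. A missing covariate value gives that site
weight 0 under any model containing the predictor, so effective sample
size varies with the model. If the weight sum (the neighbourhood size)
falls below `min_neighborhood` (default 1.0, self excluded for LOO),
the estimate is not applicable and the naive rate ȳ is used in its
place when scoring.

Fit is the leave-one-out cross-validated log likelihood ratio

    logβ = log10 [ Π_i p̂_i(y_i) / Π_i p̄(y_i) ]

where `p̂_i` is the LOO Bernoulli likelihood of the model estimate at
site i and `p̄` that of the naive model (ȳ everywhere). Estimates are
clamped to [ε, 1−ε] with ε = 10⁻³ before taking logs. The
zero-predictor model's logβ is identically 0. N* is the mean over sites
of the LOO weight sum and measures how local the model is.

## Model search and selection

- Tolerance grid: 5%…100% of a predictor's observed range in 5% steps.
- Free search: for each model size up to `max_predictors` (default 5),
  all predictor subsets are scored; within a subset the tolerance
  combination is optimised. Subsets of size ≤ 3 are enumerated
  exhaustively; larger sizes extend the best smaller model greedily,
  keeping the base tolerances fixed and gridding only the new
  predictor.
- Tolerance optimisation within a subset: the full factorial grid is
  evaluated when it has ≤ `max_exhaustive_combos` (default 400)
  combinations — i.e. up to two continuous members — and deterministic
  coordinate descent on the same grid is used beyond that (start at the
  mid-grid point, sweep predictors in name order, ≤ 5 passes, ties
  prefer the larger tolerance). logβ is smooth in the tolerances on
  these surfaces, and coordinate descent reaches the same optima at a
  small fraction of the cost of the up-to-20³ = 8000-point factorial;
  raising `max_exhaustive_combos` restores the exhaustive behaviour.
- Constraints: average neighbourhood size ≥ `min_avg_neighborhood`
  (default 1.0) and at least `min_data_per_predictor` (default 10)
  sites per predictor.
- Ties are broken by higher N*, then lexicographic predictor names.
- Final-model rule: the largest size whose every step from the previous
  size improved logβ by at least 2.5% (the first step must make logβ
  positive); otherwise the naive model.

## Inference

- Bootstrap (default 100 resamples): sites are resampled with
  replacement, the *model* (predictors and tolerances) is held fixed,
  and logβ is recomputed against the resample's own naive rate;
  degenerate resamples (constant response) are redrawn. Reported as
  mean ± SD of the replicates.
- Monte Carlo test (default 100 permutations): the response is
  shuffled and the free search rerun restricted to the selected model's
  size; p = (1 + #{null logβ ≥ observed}) / (n_perm + 1), so the floor
  is 1/101 ≈ 0.0099 and p is never 0.
- Sensitivity of a continuous predictor: every site's value is nudged
  by ±5% of the observed range, the LOO estimates recomputed with the
  other predictors' weights held fixed, and the mean absolute change
  divided by 0.05. A value of 1 means a 5% nudge moves estimates by 5%
  on average.
- Screening before the search: predictor pairs with association ≥ 0.7
  (|Pearson r| for continuous pairs, Cramér's V for categorical pairs,
  the correlation ratio η for mixed pairs) drop the member with the
  smaller univariate logβ.
- Duncan's multiple-range test drives the letter displays: group means
  are ranked, ranges tested top-down with the studentized-range
  quantile at protection level (1−α)^(r−1), the harmonic mean n of the
  span's extreme groups, and the containment rule (a range inside a
  non-significant range is not tested).

## Landscape availability

- Stream polylines are rasterised by exact parametric splitting of each
  segment at every grid-line crossing; total length is conserved to
  machine precision and is independent of a joint translation of lines
  and grid.
- Moving-window line density divides the summed length in a circular
  window (default radius 5 km on a 270-m grid) by the full window area
  π r² everywhere, including at the study-area edge — the standard GIS
  line-density convention. Window membership is by cell-centre
  distance, so the discretisation error vanishes as cells shrink
  relative to the radius (< 1% at the 270-m default; tests use ≥ 18
  cells per radius where the uniform-field limit is asserted).
- The suitability mask keeps cells with suitability ≥ 0.20; patches are
  8-connected components of the mask; availability distributions are
  Gaussian KDEs with Silverman bandwidth; ownership shares are cell
  counts of the masked area per owner class.
- Coordinates are planar kilometres throughout; no geodesic maths.

## Threat summaries

Per-category naive occupancy rates and shares of occupied sites (rows
with a missing category are excluded and counted, so sample sizes vary
per variable); fractions of focal points within given radii of any
reference feature using exact planar point-to-geometry distances; and
pairwise species overlap along gradient rasters via the overlap
coefficient ∫ min(f, g) of the two normalised KDEs, a number in [0, 1]
that is 1 for identical distributions and 2Φ(−½) ≈ 0.617 for
unit-variance Gaussians one unit apart.

## Synthetic generator: scope and limits

Surveys draw covariates independently from declared distributions
(uniform, lognormal, categorical frequencies) and occupancy from a
multiplicative true surface: base rate × Gaussian or sigmoid responses
for continuous effects × per-category multipliers. The base rate is
calibrated by bisection on a 10 000-draw Monte Carlo estimate so the
expected occupancy hits the profile's target within ±0.01; unreachable
targets raise an error. The presets match the three study conditions —
n = 78 / 778 / 75 with occupancy targets 0.28 / 0.14 / 0.15 — and
field-realistic covariates (maximum depth, emergent vegetation, habitat
type, fish status, plus structure-free noise predictors).

Landscape bundles use boundary-reflected random-walk streams trimmed to
a target total length, a smoothed-Gaussian-noise suitability field
raised to a power (default 3) to mimic the right skew of climate
suitability surfaces, argmax-of-smoothed-fields ownership, and
observation points placed with probability increasing in shoreline
density (weight 0 gives exactly uniform placement).

Limits: covariates are drawn independently (no built-in collinearity
beyond what users add), detection is perfect (naive occupancy
throughout), landscapes are planar and unprojected, and the generator
does not model stream network topology, climate-suitability modelling
itself, or disease dynamics.

## Numerical choices

- The search engine caches per-(predictor, tolerance) weight matrices
  in float32 and scores candidate models from partial products; ladder
  winners are re-scored in float64. On an n = 778 survey with seven
  candidates a full search runs in ~15 s on one CPU.
- All randomness flows through `numpy.random.default_rng` seeds;
  derived seeds are drawn as integers below 2³¹. Fits, the CLI pipeline
  and the acceptance script are byte-reproducible given a seed.
- Rasters are ESRI ASCII grids with NODATA −9999 (values stored via
  `repr(float)`, so round-trips are exact); vectors are GeoJSON; models
  and search controls are YAML.
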