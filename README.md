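# npmrocc

Nonparametric multiplicative regression (NPMR) occupancy modelling for
pond-breeding amphibian surveys, with landscape habitat-availability
analysis and threat-category summaries — plus a synthetic-data generator
that reproduces the statistical structure of multi-state Columbia
spotted frog survey programmes, so the whole pipeline is testable
without any field data.

## What it does

**NPMR occupancy models** (`npmrocc.npmr`, `npmrocc.search`). A site's
occupancy estimate is the kernel-weighted mean of the binary responses
at all other sites; weights are the *product* over predictors of a
Gaussian kernel (continuous, with a per-predictor tolerance) or an
exact-match indicator (categorical). Multiplicative weighting means a
site must be close on *every* predictor to count as a neighbour, which
captures interacting, nonlinear habitat responses without coefficients.
Fit is measured by logβ: the base-10 log of the leave-one-out
cross-validated likelihood ratio against the naive model that predicts
the overall occupancy rate everywhere. A free search over predictor
subsets and tolerance grids builds a ladder of best models per size;
the final model is the largest one whose every step improved logβ by at
least 2.5%. Inference: bootstrap stability of logβ, a Monte Carlo
shuffled-response test of the whole search, and per-predictor
sensitivities (mean response change under ±5%-of-range nudges). A
predictor's selected tolerance is interpretable as niche breadth.

**Reporting** (`npmrocc.pipeline`). Collinearity screening (|r|,
Cramér's V, correlation ratio ≥ 0.7 drops the weaker predictor),
end-to-end `fit_dataset` reports, leave-one-out group predictions with
Duncan's multiple-range letters, and 1-D response profiles at fixed
context.

**Landscape availability** (`npmrocc.landscape`). Exact rasterisation
of stream polylines to per-cell shoreline length (length is conserved
to machine precision), 5-km circular moving-window line density on a
270-m grid, masking by a climate-suitability threshold (0.20), patch
statistics under 8-neighbour adjacency, kernel-smoothed availability
distributions, and per-owner shares of available habitat.

**Threat summaries** (`npmrocc.threats`). Per-category naive occupancy
rates and shares of occupied sites, fractions of focal sites within
given distances of threat features (exact planar point-to-line
distances), and pairwise species overlap along environmental gradients
via the overlap coefficient ∫ min(f, g).

**Synthetic data** (`npmrocc.simulate`, `npmrocc.presets`). Survey
generators draw covariates from declared distributions and occupancy
from a multiplicative true surface (Gaussian/sigmoid continuous
responses × categorical multipliers), with the base rate calibrated by
bisection so realised occupancy hits a target. The presets mirror the
three study datasets: Idaho (n = 78, occupancy 0.28), Nevada (n = 778,
0.14) and Oregon (n = 75, 0.15). Landscape bundles contain random-walk
streams, a right-skewed smoothed suitability raster, an ownership
raster and density-biased species observation points.

## Worked example

```python
from npmrocc import SearchControls, fit_dataset, generate_survey
from npmrocc.presets import nevada_profile, nevada_surface

table = generate_survey(nevada_profile(), nevada_surface(), seed=1)
report = fit_dataset(table, controls=SearchControls(max_predictors=4, seed=1),
                     run_monte_carlo=False, n_boot=100)
print(report.to_text())
```

prints

```
dataset: NV   n = 778   naive rate = 0.163
logB = 26.54   N* = 32.5   bootstrap = 32.36 +/- 4.24
predictor       kind          sensitivity         tolerance
emergent_veg    continuous           0.26          15 (15%)
fish_status     categorical            na                na
max_depth       continuous           0.30       0.375 (15%)
```

The search recovered exactly the three predictors the generating
surface uses (Gaussian in maximum depth, sigmoid in emergent
vegetation, fish-status multipliers) from seven candidates, and the
15% tolerances echo the narrow true response widths. Group reporting on
an Idaho-style survey (`examples/02_habitat_report.py`):

```
estimated occupancy by habitat type (Duncan letters, alpha=0.05):
  beaver pond            mean=0.737  se=0.016  n=18  a
  stream                 mean=0.221  se=0.005  n=23  b
  reservoir/stock pond   mean=0.174  se=0.004  n=24  c
  spring/seep            mean=0.166  se=0.035  n=6   cd
  pond                   mean=0.124  se=0.034  n=7   d
```

The `examples/` directory holds four short narrative scripts covering
fitting, reporting, landscape availability and threat summaries; each
runs standalone in seconds to a couple of minutes.

## Command line

A thin CLI mirrors the library:

```bash
npmrocc simulate --profile idaho --seed 7 --out-dir work --landscape
npmrocc fit      --table work/survey_idaho.csv --seed 1 --out fit.json
npmrocc report   --table work/survey_idaho.csv --model model.yaml \
                 --group habitat --out-dir reports
npmrocc density  --lines work/streams.geojson \
                 --suitability work/suitability.asc \
                 --ownership work/ownership.asc --out-dir density
npmrocc threats  --table work/survey_idaho.csv --variables habitat,grazing \
                 --focal work/observations.geojson \
                 --reference work/streams.geojson --out-dir threats
```

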