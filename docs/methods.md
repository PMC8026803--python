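# Methods

This note documents the models, parameter choices and numerical
conventions behind `foragesim`, and what the synthetic conditions do and
do not show about real field data.

## Ground-truth generator

Each hypothesis is a mean moisture–strength curve plus a moisture-versus-
location map, sampled with truncated normal noise.

**Transect and moisture map.** 22 labeled locations on an integer grid,
location 1 at the dry dune crest and location 22 at the wet interdune.
Mean moisture rises linearly from 0 % to 6 % water content across the
transect. Linearity is the simplest map consistent with a monotone
groundwater-driven gradient and is configurable (`moisture_min`,
`moisture_max`).

**Mean strength curve.** Below the saturation moisture `b_true` the mean
strength follows a concave rise

    s(m) = k_true · b_true · (m / b_true)^rise_power ,

whose average slope over the rise is `k_true`; at and above `b_true` it
sits at the stabilized level `a_true`. The alternative hypothesis instead
declines linearly by `dip_depth` over `dip_width` percentage points of
moisture past saturation, then levels off; `dip_depth = 0` reduces it
exactly to the given curve.

Defaults: `k_true = 2` strength units per % moisture, `a_true = 10`
strength units, `b_true = 3` % (saturation at 3 % moisture, the full span
being 0–6 %), `rise_power = 0.25`, `dip_depth = 1` (a "slight" decrease,
10 % of the plateau) over `dip_width = 1.5` %.

Two deliberate shape choices:

* *Concave rise* (`rise_power = 0.25`). Pore-water binding strengthens
  loose sand most effectively at low moisture — prior wind-tunnel work
  found the effect operating between 0 and 1 % moisture and levelling off
  by about 2 % — so most of the strength gain happens early in the rise.
  Scientifically this puts the ground truth *outside* the piecewise linear
  class used for fitting, which matters for the Monte-Carlo comparison:
  when the generator sits inside the fitted model class, residuals are
  the same everywhere along the transect and *any* equally sized sample
  estimates the representative error equally well, so evenly spaced and
  random designs become indistinguishable. Real field data are never
  inside the analyst's model class; the concave rise restores the smooth,
  spatially structured misfit that makes systematic (evenly spaced)
  sampling genuinely more informative than simple random sampling — the
  phenomenon the simulation exists to exhibit. Setting `rise_power = 1`
  recovers the exactly-linear in-class generator (used in tests of the
  fitting machinery itself).
* *Level change at saturation.* The stabilized level `a_true = 10`
  exceeds the rise's endpoint `k_true · b_true = 6`. The fitted model
  family (below) places no continuity constraint at the breakpoint, and a
  distinct level change at `b` is what makes the saturation moisture a
  sharply identifiable quantity: with a merely continuous kink, noise of
  the stated magnitude leaves the breakpoint located only to a few tenths
  of a percent moisture, an order of magnitude coarser than the fit's
  search grid.

**Noise.** Strength noise: sd 2, truncated at ±2 about the mean (absolute
offsets). Moisture noise: sd 0.5, truncated at ±1. Truncation suppresses
chance outliers so replicate experiences stay comparable. Sampling is by
inverse-CDF of the truncated normal, so exactly `n` uniforms are consumed
per call and draws are reproducible; each location has its own
counter-derived substream (`SeedSequence([seed, location, channel])`), so
enlarging the grid never reshuffles earlier locations' draws.

By default each replicate's strength is centered on the curve evaluated at
that replicate's own noisy moisture draw
(`couple_strength_to_noisy_moisture=True`): a sample's strength and
moisture describe the same physical patch of sand, and the scatter in
(moisture, strength) space — the space where data are displayed and fit —
then follows the hypothesis curve. The alternative convention (strength
centered on the curve at the location's *mean* moisture, fully independent
noise channels) is available via the same switch; it behaves like
measurement error in moisture and blurs the saturation breakpoint by
roughly the moisture-noise bound.

Moisture draws at the crest (mean 0 %) can be slightly negative, an
artifact of symmetric truncated noise about a boundary mean; they are kept
as-is and handled by the fit (the clip inside the rise term applies to the
mean curve only).

## Piecewise fit

The hypothesis model is `y = k·x` for `x < b` and `y = a` for `x ≥ b`,
taken literally: the rise passes through the origin (no intercept) and no
continuity `a = k·b` is imposed (a `continuous=True` variant constrains
the junction). The fit is an exhaustive grid search over 200 equally
spaced breakpoint candidates spanning the observed moisture range
(`candidates="observed"` restricts candidates to sampled moistures
instead). For each candidate, `k` is the least-squares through-origin
slope of the points below and `a` the mean strength of the points at or
above; the candidate minimizing RMSE over all points wins, ties resolving
to the smallest breakpoint. Degenerate splits stay in the search: an empty
rise branch fixes `k = 0`, an empty plateau branch fixes `a` at the global
mean strength. The implementation uses prefix sums over the sorted points
(O(n log n + candidates)), which limits achievable RMSE precision on exact
data to about 1e-7 through cancellation; tests of exact fits use that
tolerance. Fitting requires at least 3 points with 2 distinct moistures.

**Effective coverage** partitions the full dataset's moisture range into
`n_intervals = 10` equal bins (coverage then reads in 10 % steps); the
range maximum belongs to the last bin, observations outside the range are
ignored. Coverage and bin count are configurable; the range can also be
fixed explicitly.

## Strategy execution and the Monte-Carlo comparison

Executing a strategy reveals, per step, the requested number of that
location's remaining replicates uniformly at random without replacement;
a request beyond what remains draws what is left, with a warning. After
every step the cumulative coverage and fitting error are recomputed from
scratch — no warm starts, so any step's value equals an independent refit
of the observations so far, and an exhaustive log ends exactly at the
representative fitting error.

`strategy_error_distribution` repeats a strategy family `n_iter = 100`
times against one fixed dataset and keeps each iteration's final RMSE.
Evenly spaced ("heuristic") strategies keep their locations fixed across
iterations — only replicate draws vary; random strategies redraw their
locations each iteration. Iterations reuse the fixed dataset rather than
regenerating noise, matching a design in which all runs are executed
against the same two stimulus datasets. Evenly spaced placement rounds
real equispaced coordinates to the nearest grid points (half-up), shifting
collisions outward from the center — deterministic and, for sizes that
divide the span, exactly uniform.

The headline comparison measures, per hypothesis and master seed, the mean
absolute deviation of 100 final errors from the dataset's representative
error, for `even:11x3` versus `random:11x3`; the heuristic is expected to
deviate less in at least 8 of 10 master seeds. This is a stochastic
property: each master seed regenerates the dataset and all draws, and the
10-seed win count fluctuates by a seed or two between batches.

## Heuristic classification

The **average interval discrepancy** of an initial plan sorts the
intervals between consecutive distinct locations ascending and averages
the successive differences of that sorted list — zero exactly when all
intervals are equal, and algebraically equal to
(max − min)/(n_intervals − 1). This is the literal reading of
"ordering interval sizes smallest to largest and taking the mean
difference"; a mean-absolute-pairwise-difference variant is available via
`method="pairwise"`. Plans at or below a threshold of one grid step count
as equal spacing. With a single interval the discrepancy is 0 by
convention; a single location is an error. The **magic number** is the
common initial per-location count, or absent when counts differ.
Duplicate initial locations are deduplicated before computing intervals.

## Behavioral classification

A record is *anchored* when its executed steps equal the initial plan
exactly — same locations, same counts, nothing added. An added step before
the plan finishes marks *deviation before completion* (encounter-
conditional / area-restricted search); added steps only after the plan
completes mark *adjustment after completion*. Quitting the plan early
without additions is neither (an "other" adjustment). Magic-number changes
are counted per location whose executed total differs from the initial
magic number, and the cohort change rate divides total changes by total
distinct locations sampled over records that had a magic number; records
without one are excluded (no baseline to change). Conclusions score as
correct when they match the assigned dataset (accept given / reject
alternative); rejecting a supported given hypothesis is a Type 1 error,
accepting under the alternative a Type 2 error.

`make_fixture_cohort` generates synthetic participant records whose
composition is exact by construction: mixture fractions are converted to
counts once (round half-up) and assigned by shuffling, so cohort summaries
equal the implied counting identities rather than their expectations. Its
defaults mirror the expert-cohort composition the behavioral analyses
tally (34/39 equal spacing, 9/39 anchored, 7/30 of adjusters deviating
mid-plan). These records exercise every classification path but are not
behavioral simulations — they encode no decision process.

## What the synthetic conditions do not show

The generator emulates the stimulus datasets' structure — two hypothesis
curves, 22 × 10 replicates, truncated noise of the stated magnitudes — not
the original study's exact mean-curve values (re-parameterized here) or
its pseudo-random draws (seed unknown). Passing tests therefore establish
that the pipeline's statistics behave as designed under these conditions,
not that numeric outputs match the original stimuli. Geometry is a single
1-D transect; no multi-transect or 2-D extension is attempted. Strategy
inference from free-form annotated images is out of scope: the pipeline
consumes digitized location lists. External participant deposits have
unknown schemas; `convert_external_log` documents the expected fields and
is deliberately a stub.

## Problem sizes

Default problem sizes throughout — 220-record datasets, 200 breakpoint
candidates, 100 Monte-Carlo iterations, 10 master seeds, 50 recovery
datasets, 100 fit-oracle instances — are the study conditions themselves;
the full test suite and the acceptance script each run in well under a
minute on one CPU.
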