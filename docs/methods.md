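# Methods

`soyscout` reimplements, as a tested library, the analysis chain used to
assess an insect defoliation outbreak in soybean from drone RGB orthomosaics
and satellite reflectance: damage quantification by green-pixel counting,
grid-level spatial statistics (semivariogram models and SADIE), NDVI change
detection, and a survey cost model.  Because the original imagery is not
publicly deposited, the package ships a synthetic-scene generator with
known, controllable spatial structure; every statistical claim the test
suite makes is made against that generator's exact ground truth or against
an independent oracle, never against unavailable field data.

## Synthetic scenes

Damage intensity is modeled per lattice cell as a stationary Gaussian random
field (GRF).  The covariance between cell centroids at distance *h* is
`C0·1[h=0] + C·rho(h)` where `rho` is the exponential `exp(-3h/a)`,
spherical `1 - 1.5(h/a) + 0.5(h/a)^3` (0 beyond *a*), or Gaussian
`exp(-3(h/a)^2)` correlation; *a* is always the *effective range* — the lag
at which correlation has essentially vanished — matching the fitting
module's parameterization so that recovery experiments are self-consistent.
Sampling uses a dense Cholesky factor of the centroid covariance; the factor
is cached on a `GaussianRandomField` object so many seeds can be drawn from
one factorization.  At the 60×60-cell scale used in the recovery tests the
factorization takes a couple of seconds and is performed once.

The raw field (variance = total sill) is pushed through the standard normal
CDF, giving a uniform marginal, and affinely mapped to `[low, high]`.  This
decouples the marginal damage level from the variogram shape.  Defaults
`low = 0.2, high = 1.0` span the block-level defoliation range observed in
the motivating survey (roughly 22–100%).  Variogram-recovery experiments use
the raw Gaussian field (`transform="none"`), since the CDF transform is a
marginal transformation that mildly distorts semivariance ratios.

Rendering draws each pixel as bare soil with probability equal to its cell's
damage intensity, otherwise vegetation green.  Base colors (vegetation
(60, 140, 60), soil (150, 120, 90)) are separable by the excess-green index
with a wide margin; a ±10 per-channel jitter (default) adds realism.  The
per-pixel Bernoulli outcome is stored as the truth mask and the realized
per-cell defoliated fraction is recorded — truth-recovery tests compare
against the *realized* fraction, not the requested intensity, so they are
exact rather than statistical.  What the generator does not emulate: plant
morphology, shadows, exposure gradients, stitching artifacts, mixed pixels.
Passing tests therefore demonstrate correctness of the analysis chain, not
robustness of the green threshold to real-world radiometry.

NDVI triplets hold NIR + Red constant (default 0.6) so each NDVI target maps
to a unique reflectance pair; damaged pixels get the low-NDVI pair during
the outbreak, and an exactly chosen fraction (default 0.5) of damaged pixels
reverts to healthy afterwards.  Gaussian band noise (default sd 0.02) is
clipped to keep reflectances in [0, 1].

## Defoliation mapping

A pixel is foliage iff ExG = 2G − R − B > τ (default τ = 20 on 8-bit data);
an HSV hue/saturation gate is available as a config alternative.  The
original workflow used an interactive selection whose parameters were not
recorded, so the ExG threshold is this package's deterministic stand-in,
not a reconstruction.  Block defoliation is the calibrated relative
reduction `100·(1 − gf_block / gf_reference)`, clipped to [0, 100]; the
reference green fraction comes from a designated undamaged area (the
pipeline defaults to the greenest block when none is named).  Areas use a
per-pixel ground footprint (0.02 m² in the original survey; in synthetic
scenes it follows from cell size and pixels per cell).  Damage categories
use the five-band scouting scale with half-open bands closed at the lower
edge of the higher band (so 50% → "high", 75% → "severe"), making boundary
assignment deterministic.

## Gridding

Blocks are tiled by square cells (54 m in the original survey; configurable
because small blocks need finer grids to support a variogram).  A damaged
pixel belongs to the cell containing its center, with centers exactly on a
shared edge assigned to the smaller (row, col) cell; only pixels inside the
block polygon count.  These rules make cell counts conserve the in-block
damaged-pixel total exactly, which the tests assert.  Cells with zero
overlap with the block are dropped; partially covered cells are kept.

## Semivariograms and the degree of spatial dependence

The empirical semivariogram is the Matheron estimator on equal-width lag
bins up to `max_lag` (default: half the maximum inter-point distance, 12
bins); empty bins are dropped.  Models are fitted by bounded least squares
(`C0, C ≥ 0`, `a > 0`) from several starting points (range at 0.25/0.5/1.0
of the maximum lag, nugget at 0 or 30% of the sill scale), keeping the
lowest-RSS solution; this avoids the local minima that single-start
variogram fits are prone to.  `r² = 1 − RSS/TSS` with TSS about the mean
semivariance; for a perfectly flat (pure nugget) curve with zero residuals
r² is defined as 1.  Model selection minimizes RSS, with relative ties
(1e-9) broken by higher r² and then by the fixed order exponential <
spherical < gaussian.  Fitting is unweighted by default (pair-count
weighting is a config option) because the selection criterion is plain RSS.

The degree of spatial dependence is `DD = 100·(sill_total − C0)/sill_total`
with `sill_total = C0 + C` the *total* sill — the only reading under which
the reference worked examples are internally consistent — and is classed
weak (≤ 25), moderate (25–76, including the 75–76 gap between the published
class labels), strong (≥ 76).  DD is invariant to rescaling the counts,
which the tests check both algebraically and through the fitting path.

## SADIE

The distance to regularity D is the optimum of a continuous transportation
problem: units with counts above the mean ship their surplus to units below
it, cost = Euclidean distance × flow.  Surpluses are shipped as continuous
quantities (no integer scaling heuristics), and the bipartite LP is solved
exactly with the HiGHS solver under a fixed unit ordering, making D
deterministic; D is unique at the optimum even where flows are not.  The
test suite cross-checks D against an independently written
successive-shortest-paths solver on random instances at 1e-9 relative
tolerance.

Inference permutes the observed counts over the fixed coordinates K times
(default 999; the calibration simulations in the test suite use K = 199 to
keep 500-replicate runs tractable).  `Ia = D_obs / mean(D_perm)` and
`Pa = (1 + #{D_perm ≥ D_obs})/(K + 1)` (add-one convention).  Ia is
invariant to adding a constant to all counts and to similarity transforms
of the coordinates; under permuted data its mean is ~1 and the Pa < 0.05
rate is at the nominal level (both asserted in the suite).

Clustering indices: for each donor the mean transport distance per unit of
surplus in the optimal plan, `w_i = Σ_j f_ij·d_ij / s_i` (receivers
analogously), is normalized by that unit's mean |w| across the K
permutations, giving `v_i = w_i / mean_perm(|w_i|)` with gap-side values
negated.  The exact normalization constants of the classic SADIE software
are not published; this construction enforces the interpretive contract
instead — E[|v|] ≈ 1 under randomness (asserted by simulation) and strongly
patched instances exceed the conventional ±1.5 thresholds.  One-sided
p-values for the side means reuse the same permutation set (the
normalizers and the null draws share permutations; the induced dependence
is O(1/K) and ignored).  Uniform counts make D = 0 with Ia and v reported
as undefined rather than an error.

## NDVI change detection

`NDVI = (NIR − Red)/(NIR + Red)` per pixel, with NIR + Red = 0 masked as
nodata.  Inputs are assumed to be surface reflectances already in [0, 1];
no digital-number rescaling is performed.  Damage is `NDVI_before −
NDVI_during > τ`, regrowth `NDVI_after − NDVI_during > τ`, overlap their
intersection.  The default τ = 0.05 sits just below the smallest NDVI
change reported for the outbreak region (0.058) and is a config knob, since
the original analysis reported observed ranges but no explicit cutoff.
Raising τ can only shrink a mask (asserted as a property).

## Survey economics

Aerial: `hours(N) = t_preflight + (t_flight + t_analysis)·N`, billed at
`F_expert + F_technology`.  Ground: person-hours scale linearly at the
observed per-block rate `n_surveyors·hours_per_surveyor / blocks_surveyed`
(only one observation of the ground crew exists, so linear extrapolation is
the only defensible model), billed at `F_labor`.  Defaults: 0.5 h
pre-flight, 0.05 h flight and 0.0645 h analysis per block, USD 50 + 100
aerial fees, a 19-person crew covering 45 blocks in 1.1 h each at USD 10/h.
The time comparison uses person-hours on both sides; under the defaults the
aerial survey wins from N = 2 onward.  The per-block aerial cost decreases
monotonically to the asymptote `(t_flight + t_analysis)(F_expert +
F_technology)` = USD 17.175, which exceeds the ground per-block cost of USD
4.64 — so under these printed parameters the *cost* curves never cross, and
`breakeven(mode="cost")` honestly returns None; a crossing requires
different ground-cost assumptions, which callers can supply explicitly.

## Pipeline

`run_pipeline` executes the configured stages in dependency order against
one directory, records every output with a SHA-256 hash in `manifest.json`,
and derives all stage seeds from the single config seed.  Rerunning a config
is byte-identical apart from timings.  Unknown config keys are rejected
rather than ignored.  The default simulation (16×16 cells of 27 m, 2×2
blocks, analysis grid at 27 m) is sized for interactive use; all sizes are
config parameters.

## Known limitations

- The green classifier is a threshold on rendered or well-exposed imagery;
  no radiometric correction or shadow handling is attempted.
- Variograms are isotropic and un-nested; no kriging is provided.
- The SADIE permutation engine solves one LP per randomization; very large
  grids (thousands of units) at K = 999 are computationally heavy.
- The NDVI block-level caller (which blocks count as "damaged or regrown")
  is threshold-based and config-exposed; no validated default is claimed.
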