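# Methods

This note records how each quantity in `reefscape` is defined and computed,
and the rationale for the numerical choices. Defaults live in the module
named in each section.

## Elevation profiles (`reefscape.profiles`)

A transect is an `ElevationProfile`: strictly increasing planar positions
`x` (m) with elevations `z` (m). Profiles can be supplied directly or
sampled from a DEM raster with `sample_transect_from_dem`, which walks the
segment between two endpoints at a fixed step and bilinearly interpolates
the four surrounding grid cells; endpoints outside the raster raise
`OutOfBoundsError` and NaN cells under the transect raise `DataGapError`
(a profile never silently interpolates across a reconstruction hole).

**Contour length and rugosity.** `contour_length` sums segment hypotenuses
`sqrt(dx² + dz²)`; sub-ranges are handled by linear interpolation at the
cut points so the measure is exactly additive over a partition. The
rugosity index is contour length divided by planar length, ≥ 1 by the
triangle inequality, and 1 only for flat terrain.

**Verticality.** The profile is divided into consecutive 10 cm planar
intervals anchored at the transect start; each interval contributes the
absolute elevation change across it divided by the interval length, and
the metric is the mean over full intervals (a trailing partial interval is
dropped rather than given inflated weight).

**Benthic cover.** A `BenthicSegmentation` is an ordered set of
non-overlapping labelled intervals. Cover fractions are contour-weighted:
a label's share is the contour length of its intervals over the transect's
total contour length, so structurally complex patches count by their true
surface extent. Grazing surface area is the cover fraction of turf/EAM
(macroalgae, sand, coral and other substrata are excluded).

**Refuge detection.** The rule: a crevice is a concavity 10–20 cm wide and
≥ 10 cm deep that a 10 cm-diameter disc can occupy; a near-vertical
surface (inclination ≥ 80°) with > 10 cm vertical extent is an overhang
refuge. Implementation: candidate concavities are the regions where a
morphological closing of the profile lies above the terrain. Each
candidate is measured by a descending level scan — starting at the
candidate's spill level, the width of the cavity below each level is
measured outward from the deepest sample, and the highest level whose
width fits within the 10–20 cm band (± 1.5 samples) and whose depth below
the level is ≥ 10 cm is accepted if a 10 cm disc fits wholly inside the
cavity (below the closing surface, above the terrain). Candidates
separated by less than the disc diameter merge into one detection. Walls
of counted crevices are not double-counted as overhangs; remaining
near-vertical runs with > 10 cm extent are. All geometry is translation
invariant in `x` and `z`.

## Feeding field-of-view (`reefscape.viewshed`)

Virtual observers sit 2.5 cm above the benthos at 0.5, 1.5, … m along the
transect and look horizontally toward the transect midpoint out to a 2.5 m
sight range; the observer at the exact midpoint looks both ways and
averages its two directions. An observer's obstruction angle is the
largest angle above horizontal subtended by terrain within range (clamped
to [0°, 90°]; downhill terrain does not obstruct). Its visible fraction is
`(90 − θ)/90`, and the transect value is the equally weighted mean over
observer locations.

## Tides (`reefscape.tides`)

Heights between consecutive opposite extremes follow the Rule of Twelfths:
the six equal sub-intervals carry cumulative fractions (1, 3, 6, 9, 11,
12)/12 of the range, linearly interpolated inside each sub-interval. This
stays within 3% of the tidal range of a true sinusoid. Tide-corrected
benthos levels are `tide_height(t) − measured_depth`. Accessibility is the
percentage of the series span (sampled on a 10-minute grid) with at least
30 cm of water over the habitat — roughly the minimum depth a roving
herbivore needs to graze; depth exactly at the threshold counts as
accessible. Note that the time-above-threshold of the twelfths curve
differs from the smooth-sinusoid arccos closed form by up to ~2 percentage
points; the exact closed form for the twelfths curve is obtained by
inverting its piecewise-linear cumulative schedule.

## Fish surveys (`reefscape.fish`)

Timed swims record counts in total-length size classes on two belts: 1 m
wide for fish < 10 cm TL, 5 m wide for larger fish. Each record is
standardized to individuals per 250 m² (`count / belt area × 250`), belts
and split records are summed within a replicate day, and replicate days
are averaged — a day with no sightings still dilutes the mean. Biomass
uses W(g) = a·L^b at the size-class midpoint with species-specific
allometric parameters (b restricted to the plausible (2, 4) range).
`build_assemblage` pivots the standardized densities to unit × species
matrices (abundance split into small/large columns, biomass pooled) with a
unit table carrying totals and joined covariates; expected units with no
records raise `DataGapError` rather than appearing silently as zeros.

## Hierarchical models (`reefscape.models`, `reefscape.bayes`)

All models are GLMMs `g(μ) = Xβ + u_site`, `u ~ Normal(0, σ_site)`, with
one of four observation families: Gaussian (identity link; response
standardized internally, results back-transformed), beta regression
(logit; for continuous proportions, boundary values first moved off 0/1 by
`add_offset`), negative binomial (log; counts) and Gamma (log; biomass and
other positive continuous responses). Priors are weakly informative:
Normal(0, 5) on cell means and intercepts and Normal(0, 2.5) on
standardized slopes, half-Normal(1) on σ_site, log-Normal on the
auxiliary (dispersion) parameter.

Posteriors are sampled with three independent affine-invariant ensembles
(32 walkers, 5 000 steps, first half discarded, thinned by 3) initialised
near the posterior mode; convergence requires rank-normalised split-R̂ ≤
1.01 across ensembles, with the run repeated at doubled length (up to
twice) before `ConvergenceError` is raised. Habitat-contrast models report
back-transformed per-habitat means, 95% highest-posterior-density
intervals (shortest contiguous interval, exact over the sorted draws) and
all pairwise contrasts, flagged when a difference's HPDI excludes zero.
Continuous-covariate models report slopes per original covariate unit on
the link scale and `P(slope > 0)`.

**Covariate selection.** Structural metrics are screened for collinearity
(connected groups under |Pearson r| > 0.7); each collinear group collapses
to its first principal component (standardized columns, sign anchored so
rugosity loads positively — higher scores mean more structure). Candidate
fish models are ranked by exact leave-one-out cross-validation: each of
the 15 site × habitat units is left out in turn, the model refit (Laplace
approximation warm-started at the full-data mode), and the left-out
log predictive density averaged over posterior draws; ties break toward
fewer covariates.

## Multivariate tests (`reefscape.multivariate`)

Assemblage matrices are converted to zero-adjusted Bray–Curtis
dissimilarities: a constant dummy species (value 1, the smallest possible
abundance) is appended before computing BC, which bounds dissimilarities
between depauperate samples and makes two all-zero samples identical.
Marginal DistLM tests relate the dissimilarity matrix to one covariate at
a time through the Gower-centred inner-product matrix G:
`pseudo-F = [tr(HGH)/1] / [tr((I−H)G(I−H))/(n−2)]`. For Euclidean
distances of a single variable this reduces exactly to the classical
regression F. Inference uses unrestricted permutation of unit labels with
the observed statistic included in the null set (`p = (count+1)/(n_perm+1)`).

## Synthetic studies (`reefscape.synthetic`)

The generator emulates the field design the package analyses: 3 sites × 5
habitat zones × 2 reconstructions × 5 transects of 5 m at 5 mm resolution.
Per-habitat archetypes set a base gradient, midpoint-displacement
roughness, benthic cover mix and refuge planting rates so that complexity
peaks on the slope and crest, grazing surface area peaks on the outer
flat, the mid flat is macroalgae-dominated and the inner flat sandy.
Crevices are carved as taper-rimmed notches with a level floor set `depth`
below the lower rim (so the planted geometry satisfies the detection rule
even on sloping terrain); overhangs are ~84° steps snapped to whole
samples. Fish surveys draw per-unit totals from a negative binomial with
`log μ = β₀ + β₁ · grazing fraction` (defaults β₀ = 2.5, β₁ = 3, k = 5),
allocate them to species/size classes, and Poisson-thin to the surveyed
belt areas. Tides are a two-constituent semidiurnal harmonic (M2 12.4206 h
amplitude 1.2 m, S2 12 h amplitude 0.4 m, mean level 1.8 m) whose extremes
feed the tide module. Every quantity is deterministic given the seed, and
the planted ground truth (refuges, grazing fractions, benthos levels,
generating parameters) is returned for validation.
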