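# Methods

## The analysis pipeline

The pipeline mirrors a field workflow for surveying a resident population
of group-living grazers across cleared zones with different
human-disturbance regimes: assign individuals to groups by the chain rule,
compute per-group spatial and demographic metrics against the forest-edge
geometry, and fit the inferential models. Every stage also runs on
synthetic surveys whose ground truth is known, which is how the package
validates itself.

### Chain-rule grouping

Groups are the connected components of the graph linking every pair of
individuals at Euclidean distance ≤ the chain distance (15/30/50 m by
default). The threshold is closed: a pair at exactly the chain distance is
linked — the distinction is unmeasurable in practice (rangefinder error
±0.9 m, GPS ±5 m) and the closed convention is the usual one.
Coordinates are planar metres in a local frame; at sub-kilometre extents
the difference from geodesic distances is far below measurement error.
Group ids are assigned by each group's minimum member id, so the labelling
is deterministic and independent of input order. Individuals flagged as
disturbed during a survey are excluded from grouping but kept in the
density table.

Pouch young are carried: they are removed from the chaining point set,
attached to the group of the nearest out-of-pouch individual (their
mother, with whom they share coordinates), excluded from group size,
centroids and clusteredness, and included in demographic composition. The
two denominators — group size *excludes* pouch young, composition
*includes* them — are intentional and deliberately not reconciled; they
reflect different field conventions for counting a group and describing
it.

### Landscape metrics

Distance to cover is the distance from a point (or group centroid) to the
boundary of its cleared polygon; the forest matrix surrounds every cleared
polygon, so that boundary *is* the forest edge. Vulnerable individuals are
young-at-foot, pouch young, and mothers; a "mother" is identified
operationally as an adult carrying a pouch young at its own coordinates,
or the nearest adult to a young-at-foot in the same group (motherhood is
not observable directly in survey data). Positioning uses
`delta = GDC − IDC` with `front ⇔ delta > 0`; an exact tie is classed
"behind", the conservative choice that cannot inflate the front
proportion. The pipeline skips singleton groups when building positioning
records: a lone member coincides with the group centre, so front/behind is
undefined for it. Front proportions are tabulated per zone in half-open
20 m brackets of the group's distance to cover.

Greenness is the uncalibrated relative green channel brightness of an RGB
patch: summed green digital numbers over summed total brightness. It lies
in [0, 1], is invariant to a common rescaling of the three channels, and
is undefined (signalled) for an all-black patch. Channels are assumed
8-bit; other depths are normalised before summation. No NDVI or
radiometric calibration is attempted.

### Statistical models

All logs are natural; distances are floored at 1 m before logging.

* **Density**: one-way ANOVA of log density (individuals per km² of
  cleared habitat per session) across zones, Tukey HSD for the six
  pairwise contrasts. If every cell is identical the result is F = 0 with
  all p = 1; any non-positive density is rejected (log undefined).
* **Moment tests**: sample skewness g1 = m3/m2^1.5 and non-excess
  kurtosis b2 = m4/m2² from central moments, mapped to approximately
  standard-normal Z by the D'Agostino (1970) Johnson-SU transformation
  (n ≥ 8) and the Anscombe–Glynn (1983) Wilson–Hilferty cube-root
  transformation (n ≥ 20). Kurtosis is reported non-excess (normal ⇒ 3)
  so leptokurtic reads "> 3".
* **Linear mixed models**: Gaussian LMMs via statsmodels MixedLM. Log
  group size is modelled on zone × chain cells with a random session
  intercept; clusteredness (log mean NN distance, groups of size > 1) and
  each demographic proportion are modelled on zone with crossed random
  intercepts for session and group-size level ("group size as a random
  variable" read as a grouping factor, not a covariate). Zone inference
  is a maximum-likelihood likelihood-ratio test; pairwise contrasts are
  least-squares means with a studentized-range (Tukey) adjustment on
  residual degrees of freedom. Zone-level means are computed unweighted —
  groups within session, then sessions — with a size-weighted variant
  behind a flag. Mixed fits are tried with two optimizers and never
  report a "maximum" below the σ = 0 boundary (plain OLS), to which they
  fall back when the mixed likelihood is degenerate; the fallback is
  flagged in the result.
* **NB GLMM (the centrepiece)**: group size is NB2 with log link on
  log distance-to-cover nested within zone (per-zone intercept deviations
  from the reference zone HB and per-zone slopes), plus a Gaussian
  session intercept. The session effect is integrated out by a Laplace
  approximation: the inner mode is found by a damped 1-D Newton per
  session (the NB log-likelihood is concave in the linear predictor), and
  the outer optimization is L-BFGS-B over (β, log k, σ) with σ bounded at
  zero, followed by a Newton polish on the numerical gradient/Hessian.
  At σ = 0 the marginal likelihood reduces exactly to the plain NB GLM,
  which is the oracle for the reduction test. Wald 95% CIs come from the
  inverse numerical Hessian; when σ sits on the zero boundary it is
  dropped from the Hessian (its curvature is uninformative there). A
  dispersion estimate k > 10⁴ is flagged as the Poisson limit; optimizer
  failure is reported with the gradient norm. The "logged group sizes
  with a negative binomial function" description is internally
  inconsistent (an NB acts on counts through its log link); the model
  here is NB on raw counts with a log-distance covariate, the only
  coherent reading that reproduces the log–log regression
  interpretation.
* **Positioning GAM**: individual-level binomial response (front = 1)
  with a zone factor and a cubic B-spline smooth (6 basis df) of the
  group's distance to cover. The penalty weight is chosen by AIC over a
  log-spaced grid, so a flat truth shrinks the smooth to an effective df
  of 1. Whether the original response was group-level proportions or
  individual-level binary is unstated; individual-level is used here.
  Pairwise zone contrasts are Wald tests on differences of zone offsets
  from one fit's coefficient covariance — numerically identical to
  refitting with each zone as the reference level, without the refits.
* **Greenness models**: (A) greenness (%) on zone with a random session
  intercept, LRT + Tukey contrasts; (B) log group size on greenness (%)
  nested in zone with a random session intercept, Wald CIs per zone
  slope.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with every effect planted and recoverable.

* **Landscape**: square cleared polygons of the study's zone areas
  (HB 17.1, LB 232.4, LH 104, HH 139 ha) placed in a row inside a
  5 km forest extent with 100 m margins, so every cleared polygon is
  surrounded by forest and areas are exact. Infeasible packings are
  rejected with a diagnostic.
* **Headcounts**: each zone hosts a near-constant resident headcount per
  session — target = density × area, jittered with a lognormal CV of 5%.
  Real session totals of a resident population are stable (a few percent
  CV), and this is what makes the density ANOVA as decisive as field
  data; an earlier i.i.d. Poisson-groups design produced per-session
  totals with ~50% CV in the smallest zone, which no survey of a
  resident population shows. Default densities (HB 200, LB 82, LH 80,
  HH 43 per km²) were chosen once so the four zones together yield
  ≈ 368 individuals per session with the ordering
  HB > LB ≈ LH > HH.
* **Groups**: seeds are uniform in the polygon; group size is
  max(1, NB2) with log mean = intercept + β·log(distance to cover)
  (+ session effect), dispersion k = 1.5 (strongly right-skewed group
  sizes, as observed in the field). Groups are drawn until the session
  target is met; a renewal-theory overshoot correction
  (E[S²]/2E[S] − ½) keeps realized density calibrated to ≈1%. Default
  slopes are β = 0.31 (HB), 0.23 (LB), 0 (LH), 0.21 (HH): benign zones
  carry the antipredator slope, LH none, and HH a moderate slope that is
  statistically undetectable at its sample size — the qualitative
  pattern the analysis is meant to recover.
* **Placement**: members are placed sequentially within the 15 m chain
  distance of an existing member and within a compact radius of the
  seed; seeds keep a hard-core separation of both radii + 15 m + 1, so
  members of different groups are always > 15 m apart. The planted
  partition is therefore *exactly* the 15 m chain-rule partition — the
  identifiability property the grouping tests rely on. On a placement
  conflict only the location is redrawn (never the size), so rejection
  cannot thin large groups and bias density. Within-group spacing is a
  loose target (mean-6 m gamma steps); no claim is made about its
  distribution beyond the chain constraint.
* **Demography**: classes are drawn i.i.d. from the zone's six-class
  mix; pouch young attach to adults (each adult carries one with
  probability p_PY/p_adult, keeping the marginal mix) at the mother's
  exact coordinates. The HB mix plants elevated small-adult and
  young-at-foot shares and a reduced medium-adult share; the
  young-at-foot contrast (HB 0.20 vs 0.04 elsewhere) is sized so the
  planted effect is unambiguous (z ≈ 5) at the study's ~36 HB groups,
  matching the uniformly strong significance the field analysis reports
  for this contrast.
* **Edge bias**: vulnerable classes are assigned preferentially to
  member positions on the cover-facing side of the centroid with
  probability 0.5 + 0.45·exp(−decay·GDC), decay 0.01/m — near cover
  most vulnerable individuals sit in front; far from cover the bias
  vanishes.
* **Greenness patches**: per-pixel green fractions are Gaussian around
  the requested mean; red and blue split the remainder equally, with the
  channel scale chosen so nothing clips and only 8-bit rounding remains
  (< 1/255 on the patch greenness at zero noise). Zone means default to
  HB 35.76%, HH 34.53%, LB 33.5%, LH 33.0%; the pipeline draws each
  group's patch mean with the same SD as the pixel noise (2%), which is
  the pasture-to-pasture heterogeneity a camera actually sees.
* **Sessions** are i.i.d. draws (no animal movement dynamics, no
  camera-trap simulation); individuals are not identifiable between
  sessions, matching the survey design. The session random effect on log
  group size defaults to 0, consistent with the essentially zero session
  variance the field fits report; a disturbed-during-survey flag is set
  i.i.d. at rate 19/2228.

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure — densities, group-size distributions and their
distance-to-cover dependence, demographic mixes, edge bias, greenness
levels — not animal behaviour: there is no movement, no social structure
beyond the group draw, no temporal correlation, and zone geometry is
schematic (squares, not property boundaries). Recovery of planted effects
validates the estimators and the pipeline plumbing; it cannot validate
ecological conclusions about real kangaroos.

## Numerical choices and degenerate inputs

* Ties at the chain distance link (closed threshold); duplicate ids are
  rejected; an empty session yields an empty partition.
* Clusteredness is undefined for singletons (signalled; excluded
  upstream). Positioning ties (delta = 0) go to "behind".
* Zero distance to cover is floored at 1 m before logging; all-zero or
  negative densities are rejected before the log-scale ANOVA; an
  all-equal density table returns F = 0, p = 1.
* The NB-Laplace optimizer: inner Newton tolerance 1e-10 with step
  clipping at ±5; outer L-BFGS-B ftol 1e-14 plus up to 6 damped Newton
  polish steps; linear predictors clipped at ±30 to avoid overflow.
  Starting values come from a Poisson GLM and moment-matched dispersion.
* GAM penalty grid: 10⁰ … 10¹² by decades, selected by AIC; the spline
  basis is reduced (and flagged) when distinct distances are scarce.
* Moment tests guard their validity floors (n ≥ 8 / n ≥ 20) and zero
  variance.

## Problem sizes

The test suite and the acceptance script size their simulations for a
single CPU: density calibration uses 150–700 single-zone sessions per
zone; oracle equivalence uses 100 instances of up to 500 points; slope
recovery uses 100 replicates of 300 groups per zone; type-I calibration
uses 500–2000 replicates per test at reduced n (e.g. 120–192 observations
per mixed-model fit); planted-effect recovery uses 15 full six-session
surveys. These sizes keep Monte Carlo noise well inside the documented
bands.

## Known limitations

* The Laplace approximation is a single-mode Gaussian approximation per
  session; with very few groups per session and large σ it can be crude
  (adaptive quadrature is out of scope). At the default σ ≈ 0 it is
  exact.
* max(1, NB) truncation in the generator slightly attenuates planted
  slopes where expected sizes are small; at the default intercepts the
  effect is negligible relative to CI width.
* The ML likelihood-ratio test for fixed effects in small mixed models is
  mildly anticonservative; calibration holds at the documented sizes.
* Greenness patches are synthetic stand-ins for real photographs; the
  mapping from photos to group locations is taken as given input.
* GeoJSON I/O assumes a local planar frame; no CRS handling or GIS
  interoperability beyond plain GeoJSON.
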