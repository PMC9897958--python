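# Methods

This note documents the models implemented in `nhpi`, the choices made
where the methodology was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Telemetry screening

GPS fixes carry a horizontal dilution of precision (HDOP) and a fix
dimension (2D/3D). The screening convention retains accurate fixes: a 2D
fix is kept iff HDOP < 5, a 3D fix iff HDOP < 6 (both thresholds
configurable), censoring the inaccurate high-HDOP fixes. The comparison
direction is a switch (`retain_low_hdop=False` removes low-HDOP fixes
instead) because the censoring rule is sometimes quoted with the
inequality reversed; the default follows the intent of removing
inaccurate positions. Timestamps within 5 minutes of the hour are snapped
onto it; anything else is off-schedule and excluded, since step
construction requires regular 1-h intervals. Steps spanning a missing fix
are excluded from kernel fitting and from strata.

## Brownian bridge movement model

Between consecutive fixes z₀ (time 0) and z₁ (time T), the position at
time fraction a is bivariate Normal with mean the linear interpolation and
isotropic variance

    s²(a) = T·a(1−a)·σ²ₘ + ((1−a)² + a²)·δ²,

σ²ₘ the Brownian motion variance (m²/h) and δ the telemetry location
error. σ²ₘ is estimated by the leave-one-out scheme: odd-indexed fixes are
scored under the bridge implied by their two neighbors and the summed log
density is maximized by a bounded 1-D search on the log scale. The scoring
variance adds the scored fix's own error term (+δ²) on top of the two
propagated endpoint errors; omitting it — as the scoring rule is often
written — biases σ̂²ₘ upward by ≈ 2δ², which is a 40% error at δ = 20 m and
σ²ₘ = 2000 m²/h. With the term included the estimator is unbiased to
within sampling error (≈ 9% SD at 500 fixes).

The utilization distribution is the duration-weighted average of the
bridge densities, integrated over the time fraction by trapezoid
quadrature (10 nodes, doubled until the total-variation change of the
normalized UD is below 1e-3, capped at 80). Defaults: 30-m grid (matching
the covariate rasters), margin of 3 maximal bridge SDs, δ = 20 m. The
literature rarely states the grid, δ, or quadrature used; these values are
declared, not inferred, and are configuration. Computation deposits each
bridge-node Gaussian on a local window with a single vectorized pass;
mass truncation beyond 0.1% raises rather than silently renormalizing.

The 95% isopleth ranks cells by density and takes the smallest top-ranked
set reaching the target mass; the polygon is the dissolved union of the
member cell squares. Membership tests use the cell mask; distances to the
polygon use exact geometry.

## Detecting extra-home-range movements

A 30-day pre-event window plus the 2 days immediately following slide
along each trajectory in 24-h increments (the increment, unstated in the
source protocols, bounds cost without skipping any 2-day analysis
window). Window placements holding under 50% of the expected hourly fixes
are skipped for BBMM stability. A candidate event needs, within the
analysis window, (1) at least 2 relocations more than 500 m outside the
window's 95% isopleth and (2) at least 4 consecutive relocations outside
it (strict readings of ">1" and ">3"). The event is delimited at the
first sufficiently long outside run that itself reaches beyond the
distance threshold — conditions (1) and (2) are window-level, and tying
the start to a run without any far fix would let brief boundary runs
absorb evidence belonging to a later departure.

Classification replaces visual confirmation with two automated rules,
both configurable:

- **Return:** the animal re-enters the pre-event polygon → excursion,
  ending at the last outside fix. A return can be required to last
  ≥ `reentry_min_consecutive` fixes (default 1, the literal rule;
  the synthetic study uses 2 so a single-fix clip of the isopleth edge by
  a passing disperser does not read as a return).
- **Settlement:** a fully observed 168-h run of fixes, all outside the
  polygon, with maximum pairwise spread ≤ 2 × 1000 m → dispersal, ending
  at the run's first fix. Settlement counts only if declared before any
  return. After a dispersal the scan restarts with the pre-event window
  beginning at the settlement, since the residence has moved.

Events still open at the end of the data are labeled unresolved and
excluded. Fixes of previous events are excluded from later pre-event
windows before the BBMM is fit. Raising the distance threshold or the
consecutive-fix requirement can only shrink the event set.

## Landscape metrics and dissimilarity

Seven landscape-level metrics are computed over circular moving windows
(cell-center distance ≤ radius; truncated at the raster border) with
rook, single-count adjacencies, and edges at the window boundary not
counted: %forest, %developed, %open, edge density (m/ha), the
interspersion–juxtaposition index (IJI, %), patch richness density
(classes per 100 ha), and the aggregation index (AI, %). AI caps the
maximal like-adjacency count at the window's internal adjacency total, so
a uniform circular window scores exactly 100 (the textbook
largest-square formula alone, derived for unconstrained arrangements,
caps below the attainable count in a circular window and would leave a
uniform landscape at ≈ 99.5). IJI is undefined for windows with fewer
than 3 classes and propagates as missing — listwise through Mahalanobis
references and as undefined D² at affected points — rather than as a
silent zero. All window counts are integers obtained by FFT convolution
and rounded back exactly; the test suite verifies equality with a direct
per-window enumeration.

Distance covariates are Euclidean: cell-center to nearest target cell
center (raster classes) or to the nearest polyline segment (streams,
roads).

For each movement, the 7-metric vectors at its pre-event window
relocations define the reference: sample mean μ and sample covariance C
(denominator n − 1, minimum 30 usable relocations). D²(x) =
(x − μ)ᵀC⁻¹(x − μ). Two scopes: per-movement (D_IND, recomputed per
event) and pooled across all animals' pre-event relocations (D_ALL, once
per dataset per grain). Near-collinear metrics (AI and edge density,
notably) can make C ill-conditioned; when the condition number exceeds
1e8 a ridge λI is added, starting at λ = 1e-6·tr(C)/7 and escalating
tenfold until conditioned, with λ recorded. The ln transform of D² uses
ln(max(D², 1e-12)); D² = 0 occurs only at exact mean equality.

## Step-selection estimation and model selection

The movement kernel is fit by maximum likelihood to all event steps
pooled across individuals (gamma for lengths floored at 1 m, von Mises
for turn angles); pooling is deliberate because single events can be very
short. Each used step is matched with J = 50 random steps sharing its
start point, lengths and turns drawn from the kernel relative to the
previous bearing (drawn uniformly when undefined); endpoints off the
raster are resampled up to 100 times.

The conditional logistic likelihood
Σₛ [βᵀx_used − ln Σ_c exp(βᵀx_c)] is maximized by Newton ascent with
step-halving from β = 0, converging at gradient ∞-norm < 1e-6; standard
errors come from the inverse observed information. Strata containing an
undefined covariate are dropped and counted; covariates without
within-stratum variation are flagged and excluded with NaN coefficients.
The estimator is checked in the tests against a grid-search oracle and
against an independent conditional-logistic implementation.

AICc uses n = number of strata (each contributes one conditional term).
Tiers: (1) per covariate, single-covariate fits (plus step length) under
linear, quadratic, and ln forms, lowest AICc retained, ties to fewer
parameters then linear; ln uses ln(z+1) for distances in meters; (2) the
three base hypotheses with the chosen forms; (3) the best grain × form
for D_ALL added to the base, then for D_IND added on top, demoting D_IND
candidates whose Pearson r with the chosen D_ALL column exceeds 0.70 (to
the second- then third-best; omitted if all fail). Within a dataset, the
tier tables are computed on a common stratum set: an available step with
undefined D² is removed from its stratum's choice set, and a stratum is
lost only when its used step is undefined — otherwise models with and
without D² terms would be scored on different data and their AICc would
not be comparable. Model averaging over the tier-3 set (triggered by
ΔAICc ≤ 2 competitiveness, and reported regardless) produces ln(RSS)
curves: per model, Σ β̂·(f(v) − f(v_ref)) over the focus covariate's
terms, other covariates held at their means, averaged by Akaike weight,
with a 95% band from 2000 seeded draws of each model's coefficient
vector.

The estimator is fixed-effects conditional logistic throughout; random
slopes per individual are out of scope, so coefficient comparisons with
mixed-model analyses carry that caveat.

## The synthetic study generator

The generator defines the study conditions under which the pipeline is
validated:

- **Landscape:** modified-random-clusters mosaic of 7 cover classes
  (open water, wetland, forest, agriculture, open, developed, other;
  default composition 5/10/18/45/18/3/1%, matching a fragmented
  agricultural region), 30-m cells. `clumping` sets patch aggregation;
  `gradient` modulates cluster-class assignment with smooth per-class
  random fields (correlation length `gradient_scale` × extent), creating
  forest-rich vs. crop-dominated districts while deficit-chasing keeps
  the global composition on target. Regional districts are what give
  individuals distinct natal references — without them D_IND and D_ALL
  collapse into one another. Streams and roads are random-walk polylines.
- **Resident movement:** a discrete-time mean-reverting walk (rate 0.15/h,
  stationary spread `hr_sigma`) radially reflected at 2.5 `hr_sigma` —
  home ranges are bounded, and an unbounded Gaussian tail would produce
  rare multi-hour forays indistinguishable from genuine events.
- **Events:** excursions travel to a waypoint ~2.4–2.8 km out, dwell a few
  hours, and return; dispersals travel ~4.8–5.5 km and settle. With no
  habitat chooser, travel is a brisk direct walk (used by the detector
  validation). With a chooser, travel is itself a step-selection process:
  candidates from a von Mises (κ = 0.6, around the previous bearing) ×
  gamma kernel, used step drawn ∝ exp(dir·cos(angle to waypoint) +
  β·ln D²_IND@175), with the natal reference built from the animal's own
  simulated resident path — exactly the covariate the analysis later
  reconstructs. The waypoint pull (0.6 excursions / 0.8 dispersals,
  boosted to 1.4 within 700 m of the departure point so leavers leave
  decisively) lives in the utility, not the proposal, so the generating
  availability matches what a fitted kernel describes.
- **Defaults of the end-to-end study:** 10 animals, `hr_sigma` 180 m,
  46-day tracks, excursion day 31, dispersal day 33, planted dispersal
  coefficient −0.3 on ln(D_IND@175), zero excursion coefficient, 5% poor
  fixes. Detection uses a 750-m settlement radius and 2-fix returns.

What the generator does not emulate: memory or energetics, conspecifics,
irregular duty cycles, habitat-dependent fix loss, seasonal landscape
change, and individual heterogeneity in the selection coefficient.
Passing tests therefore demonstrate that the pipeline recovers planted
selection through the full detection–reference–selection chain under
clean movement; they do not certify performance on field data with
behavior the generator lacks.

## Known limitations

- **Joint recovery is noisy at this scale.** A replicate of the
  end-to-end study "succeeds" when the dispersal tier-3 table puts ≥ 0.8
  weight on the D_IND model, the selected D_IND CI is negative, and every
  excursion D_IND CI covers zero. At 10 animals (~300–600 dispersal
  strata) the per-replicate joint success rate is ≈ 0.5–0.6, not ~1:
  AICc selection across 8 correlated grain × form candidates picks a
  wrong grain or form in roughly a quarter of replicates when the true
  term's z is 2–3; Wald CIs of linear-form D² covariates (heavy-tailed)
  can cover zero even when the likelihood gain is decisive; the D_ALL
  term absorbs part of the planted D_IND signal; and the within-stratum
  variance of ln D² varies severalfold across landscape draws. Successful
  replicates reproduce the expected scientific outcome exactly
  (ln(D_IND@175) selected, strongly negative, weight ≈ 1); the failure
  modes are properties of small-sample tiered model selection, not of
  the estimator, and the acceptance suite reports the rate honestly.
- Under a pure null, picking the best of 8 noise D² candidates by AICc
  lets the D_ALL model edge out the base model in a substantial fraction
  of replicates; "the base wins" is not a reliable null signature, and
  the tests check base competitiveness (ΔAICc within the selection-noise
  envelope) and null CIs instead.
- BBMM variance recovery quotes aggregate accuracy (median/mean within
  15% at 500 fixes); single replicates have ≈ 9% sampling SD, so a few
  percent of them exceed 15% by chance.
- IJI-undefined windows make D² undefined at those points; in landscapes
  dominated by large uniform patches this can remove many available
  steps (and, rarely, whole strata through the used step).
- Coordinates are pass-through projected meters; no datum handling.
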