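# Methods

This note documents the model implemented by `graztox`, its assumptions,
the defaults that matter, what the synthetic landscape does and does not
emulate, and the numerical choices made where the design was open.

## Model overview

The simulation couples a 1 m²-cell pasture grid to a herd of cow agents.
Cows maximize forage intake under simple behavioral rules; lethal acute
alkaloid toxicosis emerges from the spatial coincidence of larkspur with
productive, desirable forage. Time is consumption-based: a tick is one
feeding-station interaction, and a grazing-day passes when herd-mean
intake reaches 12.5 kg per cow (2.5% of a 500 kg cow's body weight). Run
length is measured in animal-unit-months, `AUMs = grazing_days × n_cows
× 1.1 / 30.44`.

### Toxicokinetics

A cow's alkaloid body burden accumulates with each grazed cell
(`intake = eat_fraction × cell_MSAL × attraction`, capped at the cell
content) and is assessed at the end of every grazing-day: a burden above
the cow's individual tolerance is recorded as a lethal acute toxicosis
event, the burden is reset to zero, and the cow keeps grazing (removing
the cow would change herd behavior in unknown ways; the count measures
risk, not demography). All burdens then halve — a one-grazing-day
elimination half-life, chosen over a continuous clearance model because
the available dosing studies do not constrain one.

Tolerance is drawn from N(4000, 333.33²) mg truncated to [3000, 5000].
The untruncated normal places only 99.73% of mass within ±25% of the
mean; truncation makes the stated ±25% containment exact while shifting
the realized SD by less than 1%.

### Behavioral constants

* Herd distance (desired mean distance to the 20 nearest herdmates) and
  per-cow space at a new feeding site interpolate **geometrically**
  between the documented endpoints: 100 m/1000 m² at HCF 1 down to
  10 m/10 m² at HCF 10. A geometric map is the only smooth monotone
  family that hits both endpoint pairs with one exponent; no formula for
  the interior is documented for the original implementation.
* Herd size is `round(SD × accessible_ha / 1.1)`. The division by
  1.1 AU·cow⁻¹ is fixed by a consistency check: 2.8 mean deaths being
  "2.4% of cows" requires 118 cows at SD 0.5 on 258.82 ha.
* Site-change patience (`site_tolerance`) is `max(2, ceil(n_cows/10))`.
  Only "increases with herd size" is documented; the divisor was
  calibrated once so that corner medians of site changes/day stay inside
  the observed 2.3–6.0 band on the 16-ha test landscape, and is exposed
  as a config override.
* "Hydration approaching zero" (watering takes priority over a site
  change) means below 20% of the 6.25 kg hydration capacity;
  configurable.

### Scheduling

Each tick, cows act in a freshly shuffled order (emulating randomized
agent scheduling; seeded for reproducibility). Watering and site changes
are whole-herd events that consume the entire tick — no grazing occurs —
generalizing the original watering-tick flag to site changes, since a
tick is defined as one patch interaction. When several leaders would
trigger in the same tick, the first in the shuffled order wins. After
watering, leaders' ready-to-go is primed to `site_tolerance − 1`
(cattle do not linger on trampled ground near water); after a site
change it resets to 0. Relocation is instantaneous but the displacement
still accrues to daily travel, which is a reported output.

Candidate feeding sites are enumerated on a 25 m lattice (the original
enumeration is undocumented; a lattice keeps scoring O(area/625)) and
scored by summed ranks of low grazing pressure, high current forage and
high neighborhood initial forage within the site radius
(`sqrt(n_cows × space_per_cow / π)`); the nearest of the best five to
the deciding leader wins. Within the new site, cows place in role order
(leaders, followers, independents; shuffled within role) on the
highest-forage cell with no cow on it or its four direct neighbors; the
constraint relaxes to "no cow on the cell", then to the nearest free
cell, if the site fills.

Movement targets maximize forage within a ±45° vision cone (10–25 m
annulus for herding moves; 2 m radius for local grazing, 10 m when the
10 m neighborhood's mean times-grazed is ≥ 0.5). Ties break
nearest-first, then by a seeded draw. If a cone is empty (fence lines),
it widens to ±90°, then to the full circle; a herding move falls back to
the accessible cell best aligned with the herdmate-centroid bearing.
Headings start uniform-random and follow the last displacement.

## Synthetic landscape

The generator replaces the study pasture's remote-sensing and
field-mapped layers with statistical stand-ins on a 400×400-cell (16 ha)
default grid, a 2-cell fence margin, and three layers driven by one
spatially correlated productivity index u ∈ [0, 1] (smoothed white
noise, correlation length 25 m, min-max normalized):

* **Forage**: `f(u) = m·3^(2u−1)`, the minimal exponential map whose
  endpoints are ⅓× and 3× the mean, globally rescaled so the
  accessible-cell mean is exactly `kgs_per_hectare/10` g (default
  500 kg·ha⁻¹ → 50 g·m⁻²).
* **Larkspur**: a Poisson-cluster process — patch centers at 0.38 ha⁻¹
  placed with probability ∝ u (larkspur grows most densely in
  productive areas, which is precisely why cows encounter it), disc
  patches of radius 25 m with Poisson(4) plants per m², and a
  Poisson(0.02) background. Per-plant mass is `3.5 g × (0.5 + u)`
  (±50% around the median at the index extremes) and MSAL content is
  mass × 3.0 mg·g⁻¹.
* **Water**: a top-to-bottom random-walk stream; 25% of its segments are
  removed to mimic an intermittently subsurface channel, never below one
  remaining cell.

**Calibration (one-time, then frozen).** Patch radius, intensity and
in-patch density are not documented for the study pasture. They were
calibrated once against the study's printed per-run intake statistics
and then frozen. The frozen defaults reproduce the printed range of
*mean maximum individual daily intake* (≈1700–2900 mg across the
factorial corners vs 1045.6–2450.2 mg printed) — the tail statistic that
actually produces lethal events — at the cost of mean individual daily
intake running above the printed 525.1–550.9 mg band (≈700–1300 mg
depending on the landscape realization). A simple two-parameter cluster
process on 16 ha cannot match both anchors simultaneously; the tail
anchor was chosen because toxicosis is a tail phenomenon.

**What a green test does and does not establish.** The synthetic
landscape reproduces patchiness, the forage–larkspur spatial
correlation, and intake tails of the right magnitude; it does not
reproduce the study pasture's absolute larkspur abundance (realizations
at 16 ha vary by ~±50% in total plants), its real stream geometry, or
its 262-ha extent. Consequences, verified empirically:

* The deaths gradient (loose/sparse ≫ cohesive/dense) and its sign test
  hold at desk scale.
* The full-pasture-scale *numbers* (2.8 mean deaths at HCF 4/SD 0.5, 4.16 vs
  7.40 km daily travel) are treated as direction-of-effect checks only.
* The independents' excess death risk only expresses where the wander
  threshold (2.5 × herd distance) is small against the pasture extent —
  at 16 ha that is the high-HCF corner; at HCF 1 the threshold (250 m)
  exceeds the pasture half-width and independents are behaviorally
  indistinguishable from followers.
* At SD 0.25 with only 4 cows, *raising* HCF can increase deaths on a
  16-ha landscape (a tight 4-cow group camps inside a patch complex);
  the protective HCF effect at realistic herd sizes appears at SD ≥ 0.5.

## Statistical layer

Counts of lethal acute toxicosis across replicated runs are
overdispersed, so the primary model is a negative-binomial GLM with log
link, fitted by maximum likelihood (NB2; dispersion estimated by ML and
counted as a parameter in AIC/AICc, matching R's `MASS::glm.nb`
bookkeeping — documented so cross-software AIC offsets of 2 are
diagnosable). A Poisson GLM is the equidispersed comparison.
`AICc = AIC + 2k(k+1)/(n−k−1)`.

Percent-change reporting: a log-link coefficient β maps to
`100·(1−e^β)`, with positive values read as percent decreases.
Standardized betas come from the main-effects-only refit with
predictors z-scored by the population SD (the response is z-scored too
for Gaussian fits); influence ratios |β_a/β_b| are invariant to that
convention and to affine rescaling of the raw predictors. Quantiles use
linear interpolation (R type 7). The mechanism screen's "percent change
in deaths from Q1 to Q3" compares mean deaths between runs at or below
the first quartile and runs between the median and the third quartile —
a reconstruction, as the original grouping rule is not documented.

All per-run summary statistics (daily intake mean/SD, per-cow maxima,
CV of totals, grazing heterogeneity) use population (divisor-n) standard
deviations.

## Numerical and degenerate-input choices

* Forage/alkaloid conservation holds to 1e-6 relative at every tick
  (checked in tests); intake is capped at cell content so attraction
  > 1 cannot overdraw a cell.
* A herd with no leader would deadlock (watering and site changes are
  leader-triggered), so role apportionment (largest remainder over
  5/85/10%, ties leader > follower > independent) always promotes one
  cow to leader in tiny herds.
* Cows on an exhausted pasture keep moving and eat 0 g; a run terminates
  with status `forage_exhausted` after 100 consecutive near-zero-intake
  ticks.
* Water cells accept at most 3 cows at assignment time; if all are full,
  overflow cows take the nearest water cell regardless (prevents
  deadlock at high stocking density on a small stream).
* ESRI ASCII rasters are read with NODATA mapped to the inaccessible
  mask; non-unit cell sizes are accepted with a warning and treated as
  1 m model cells.

## Known limitations

Slope response, resting, dominance interactions, plant regrowth, and
removal of dead cows are deliberately excluded (parsimony; regrowth is
negligible for larkspur at bud stage within one grazing period). The
toxicokinetic model is a daily half-life, not continuous clearance. The
synthetic landscape is a statistical emulation: absolute death counts
depend on the landscape realization and should only be compared within
a fixed landscape and seed protocol.
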