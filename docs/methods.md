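# Methods

## The model

`splitroot` simulates the root system of a perennial grass growing in one
compartment of a split-root box (20 × 27 × 107 cm, divided by a vertical
barrier at *x* = 0 with a small gap at the top where the rhizome sits).
Roots are classified by *branching number* — the centrifugal
(developmental) order: 0 for primaries emerging from the rhizome, each
lateral one more than its parent.

Each branching number *b* has its own parameter set. A new axis realises
a private triple (*r*, *lmax*, *ln*) — elongation rate (cm day⁻¹),
maximum length (cm), inter-branch interval (cm) — drawn from normal
distributions around the per-order means and truncated below at a small
positive floor (default 0.01 × mean, implemented as clamping). Growth
follows

  length(t) = min(r · (t − t_birth), lmax),

i.e. constant elongation capped at the maximum length. The negative
exponential law `lmax·(1 − exp(−r t / lmax))` used by ancestral
root-architecture models is available per order via
`growth_law = "exponential"` and is off by default.

Branch sites sit at arc lengths `la + i·ln` along the parent, where `la`
is the unbranched (axial) zone at the base and `lb` the unbranched
(basal) zone behind the tip. **Note the convention:** `la` = base, `lb` =
tip — the reverse of some ancestral models' naming. A root whose branched
zone `lmax − la − lb` is not strictly positive never branches; otherwise
sites exist up to `lmax − lb` inclusive, and a site emits its lateral the
moment the parent's length first reaches `site + lb` (so the zone behind
the tip is always branch-free, and the site exactly at `lmax − lb`
activates when the root completes growth). No additional emergence delay
is modelled. A lateral's axial insertion angle is normal around the
per-order mean θ (clamped to [0, 180)); its radial (roll) angle around
the parent is uniform on [0, 360). Angles are sampled per insertion
event.

Because per-axis length is closed-form in time, every branch site has an
exact activation time and the simulation is resolved *event-driven*:
`grow(dt)` advances the clock and materialises, in chronological order
(ties broken by creation order), every activation event that falls within
the interval — including cascades of laterals on laterals. Axis counts
and lengths are therefore exactly independent of the stepping interval.

### Geometry

Geometry does not feed back on growth, so each axis's full eventual
polyline is traced once at creation and "grown" by revealing arc length.
The heading performs a biased random walk per 0.1-cm step: a fixed
gravitropic pull (fraction 0.06 of a unit step toward +z, which points
downward) plus an isotropic normal perturbation with per-order standard
deviation `tropism_sigma` (degrees per step), then renormalisation. This
tortuosity layer is model plumbing for 3D realism: it affects no length,
count or biomass, only the shapes that RSML/OBJ exports show. Steps that
would leave the compartment are split at the wall, the offending heading
component is mirrored, and the walk continues with the remaining length —
so arc length is conserved exactly through reflections, and no polyline
crosses the barrier plane or the box walls. For simplicity the barrier is
treated as impenetrable over its full depth; the top gap exists only as
the rhizome's location above the simulated domain, which is consistent
with treating compartment membership as fixed at axis origin.

### Tabulated traits

Per (replicate, compartment, branching number): total length, cylindrical
surface area (2π · radius · length with a per-order radius), tip count
(every axis carries exactly one tip, so tips = axes), biomass
(length × per-order linear density, g cm⁻¹) and mean axial insertion
angle (arithmetic mean in degrees; angles stay well below 90°, so no
circular statistics are needed). Derived traits: branching intensity
BI(b) = tips(b)/length(b); branching density BD(b) = tips(b)/length(b−1);
branching ratio BR(b) = tips(b)/count(b−1); specific root length
SRL = Σlength/Σbiomass; mass fraction = compartment biomass / clone
biomass. BD and BR are undefined at b = 0 and raise/print n/a; zero
denominators raise an explicit undefined-value error rather than
returning 0. The identity BR(b) = BD(b) × mean parent length holds
exactly on any table.

### Relative elongation rate

Trace series record cumulative traced length per tracing day. Per
interval the absolute rate is ΔL/Δdays (cm day⁻¹); the relative rate is
the absolute rate divided by the traced length at the *end* of the
interval, ×10 for cm→mm, giving mm cm⁻¹ day⁻¹. The published formula
text for this quantity divides the length increment by the absolute rate,
which is dimensionally inconsistent with its stated units (it reduces to
10·Δdays); the interpretation above reproduces the units and is the
package default, with the literal text form retained behind
`literal=True` for auditability. End-of-interval normalisation was chosen
over start-of-interval because traces accumulate and the end length is
the one recorded with the increment; under linear growth the rate of a
sub-interval ending at the same day is unchanged by splitting. Pooled
rate sets are summarised by a 20 % trimmed mean (floor(0.2·n) values
dropped from each tail) to suppress the artificially high early-trace
values.

## The synthetic experiment

`generate_experiment` emulates a split-root study: per replicate, one
simulated system per compartment (sides +1/−1 of the barrier), a trace
series per compartment, and a per-order trait table. Study conditions
follow the emulated design: two treatments — resource-partitioned (one
compartment watered to capacity, "water"; the other receiving nutrient
solution at low volume, "nutrient"; default n = 9) and resource-mixed
(both compartments identical, default n = 4) — duration 25 days, tracing
three times weekly (days 2, 4, 7 of each week), 10 primary roots per
compartment.

Observation model (invented, clearly separate from the growth model):

* **Tracing visibility.** Only roots pressed against the transparent
  front are traceable, so traced length = true total length × a
  Beta(4, 16) visibility fraction (mean 0.2), constant within a
  replicate × compartment. Relative elongation rates divide by traced
  length, so the visibility factor cancels from them exactly.
* **Trace noise.** Multiplicative lognormal noise (σ = 0.05) on
  per-interval increments, keeping traces non-decreasing.
* **Biomass noise.** A lognormal tissue-density multiplier (CV 10 %) per
  replicate × compartment, so SRL and mass fraction vary realistically
  across replicates.

What the generator does *not* emulate: measurement error on scanned
lengths/tips, root mortality and turnover, diameter variation within an
order, water/nutrient transport, and any plant-level covariance beyond
the shared calibration. Passing recovery tests therefore shows that the
pipeline's estimators are consistent with the architecture model that
generated the data — not that the model captures every property of real
root systems.

## Packaged calibrations

The raw data of the emulated study are not deposited, so the shipped
"nutrient", "water" and "mixed" calibrations are reverse-engineered from
its published per-order summary tables and labelled approximations.
Anchors: nutrient BD₁ ≈ 5.0 tips cm⁻¹ sets the primary branching
interval (ln₀ ≈ 0.18 cm); nutrient BR₁ ≈ 45 and water BR₁ ≈ 47.8 set
site counts; the ≈ 60–64 % water share of primary-root length sets the
lmax₀ contrast (water ≈ 16 cm vs nutrient ≈ 9 cm); per-order insertion
angle means are taken directly from the published table; linear densities
are set so nutrient-compartment SRL lands near 3700 cm g⁻¹ with balanced
(≈ .50/.50) mass fractions; and the water compartment's slow, short
high-order laterals reproduce the collapse of its bn ≥ 2 allocation
while keeping growth active through the trace window (pooled trimmed
relative elongation ≈ 1.0 mm cm⁻¹ day⁻¹).

The published summary statistics are means of per-plant ratios and are
not jointly satisfiable by any single parameter set: BR₁/BD₁ implies
mean primary lengths of 9.0 cm (nutrient) and 7.8 cm (water), while the
allocation of primary length toward water requires water primaries to be
≈ 1.6× longer, and BI₀ implies yet other lengths. The packaged
calibrations keep BD₁ (nutrient), BR₁ (both), angles, SRL, mass
fractions, elongation rates and the allocation pattern, at the cost of
understating water BD₁ (≈ 3 vs 6.1 printed) and the BI column. Two
further consequences are documented rather than hidden: tip allocation
at order 0 is pinned at 0.5 by the even split of primaries across the
barrier, so the monotone decline of the water share holds for length and
surface area over all orders but for tips only from order 1; and the
validity constraint `la + lb ≤ lmax_mean` bounds how sparse high-order
branching ratios can be (≈ 0.5 at the boundary), so the water side's
high-order scarcity is achieved through slow elongation and late
emergence instead. The replication-style configuration mentioned in the
emulated study assumed branching only to order 2; the packaged
calibrations use `max_order = 4` so that the full five-order trait
tables are exercised.

## Numerical choices

* Geometry step 0.1 cm; default `dt` for stepped growth 0.1 day (results
  are dt-insensitive by construction; `dt` only controls how often the
  caller observes the system).
* Event-time tolerance 1e-9 days: activations falling exactly on the
  clock boundary are included, matching the site-at-full-length rule.
* Arc length equals reported length to 1e-6 relative tolerance
  (asserted in tests), including through wall reflections.
* Parameter draws are clamped, not resampled: deterministic RNG
  consumption per axis, which underpins byte-identical reproducibility.
* Zero-variance configurations consume no RNG draws for that quantity,
  so the deterministic limit is exactly reproducible and matches the
  closed-form enumeration oracle to 1e-6.
* RSML floats: coordinates to six decimals (1e-6 cm), properties via
  `repr` round-trip; re-imported axes are static (their stored polyline
  is exposed verbatim), which makes write → read → write byte-identical.
* Random-number architecture: one `numpy` SeedSequence per run, spawned
  hierarchically (replicate → compartment → system/observation), so any
  subset of the experiment is reproducible in isolation.

## Statistical comparisons

Allocation questions are tested with an exact two-sided binomial test
against p₀ = 0.5, discretising lengths and areas to 1-mm(²) units as
trials; scalar traits are compared with classical one-way ANOVA
(F = t² for two groups; all-identical data returns F = 0, p = 1 by
contract). These deliberately replace the negative-binomial mixed models
a full field analysis would fit: no random plant effects, no
multiple-testing correction. Under a symmetric null the exact binomial
test's size is slightly conservative (≈ 4–5 % at α = 0.05 for ~500
trials), which the test suite checks by simulation.

## Problem sizes

Recovery checks use 100-system ensembles per calibration and 9
resource-partitioned replicates — the ensemble size of the emulated
study's own simulation and its replicate count; a full run of the
recovery suite takes about a minute on one core.

## Known limitations

* Compartment calibrations are approximations reconstructed from
  summary tables; they are not the study's (unpublished) fitted values.
* No root mortality, secondary thickening, soil mechanics, or resource
  transport; tropism is phenomenological.
* Biomass is strictly proportional to length within an order.
* Re-imported RSML systems are measurement-only; they carry no random
  state and cannot be grown further.
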