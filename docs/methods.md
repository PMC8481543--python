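# Methods

This note documents the models, conventions and numerical choices behind
`fireselect`, and what the synthetic-data validation does and does not
demonstrate about real fire data.

## Observation model

The unit of observation is the single-part fire footprint. Multi-part
perimeters are split (`geometry.split_multipart`), with footprint ids formed
from the parent event id plus an ordinal suffix; parts are ordered by
descending area, ties broken by centroid x then y, so ids are deterministic.
Zero-area parts are dropped with a warning.

**Availability.** The available area is the burned polygon plus an outside
buffer of equal area. The buffer is a Euclidean outward offset with round
joins (64 segments per quadrant); the width solves
`area(ring(w)) = burned area` by Brent root-finding on a bracket expanded
from an initial guess `area/perimeter`, failing if no bracket exists below
10× the bounding-box diagonal. The relative area tolerance is 1e-3
(configurable). For a disk of radius r the solution is the annulus to r√2,
i.e. w = r(√2 − 1); this closed form anchors the tests.

**Interior holes** (unburned islands) are honoured as unburned. By default
(`holes="excluded"`) hole area counts neither as used nor as buffer and is
not part of the available area; `holes="available"` treats hole interiors
as available unburned land instead. The difference is immaterial for
footprints without holes.

**Study-area exclusion.** A footprint is excluded when more than `edge_tol`
(default 1e-4) of its available area falls outside the study boundary;
"outside" is conceptually binary, the tolerance only absorbs floating-point
slivers from overlay.

**Proportions.** Used and available proportions are computed over ownership
classes only; area uncovered by any parcel is assigned to `other`. The
unburnable fraction of the available area is reported alongside but does not
reduce the ownership denominators. An alternative convention (removing
unburnable land before computing ownership proportions) would change π̂ for
fires abutting developed land; the reported unburnable fraction lets users
gauge the exposure.

**Fire typing.** The 2:1 dominance rule is applied to burned *burnable*
vegetation (forest vs grass/shrub; unburnable-mapped burned area is
excluded from the ratio). At exactly 2:1 the footprint takes the predominant
type; a strict mode classifies the boundary as mixed instead. The boundary
is measure-zero for continuous data; the choice matters only for constructed
inputs. Footprints burning no burnable-mapped land are flagged
unclassifiable and excluded from type-stratified analyses.

## Selectivity and the proportional-use test

The Jacobs index D = (o − π̂)/(o + π̂ − 2oπ̂) is evaluated with exact fast
paths at o ∈ {0, 1} and a clamp to [−1, 1] against float round-off; the
degenerate o = π̂ (including o = π̂ = 1, a 0/0) is defined as 0, consistent
with the o → π̂ limit. A class enters a footprint's record set iff π̂ > 0.

Distribution summaries per (ownership × fire type) report the median,
quartiles (linear interpolation) and a 95% distribution-free median CI from
binomial order statistics: the interval [x₍k₎, x₍n+1−k₎] with k the largest
integer such that P(X < k) ≤ 0.025, X ~ Binomial(n, ½), falling back to the
sample range for very small n. Groups with n < 25 are flagged
not-for-display; the flag never affects the test. The violin figure uses a
Gaussian KDE with Silverman bandwidth reflected at the ±1 support bounds and
seeded horizontal jitter.

The sign-test P-value P(max(X, n − X) ≥ t) is computed with exact integer
arithmetic (sums of binomial coefficients divided as big integers), so it
equals exhaustive enumeration over all 2ⁿ sign vectors bit-for-bit. Ties
(|o − π̂| ≤ 1e-9) are removed from both counts, the classical sign-test
convention; an all-tied class degenerates to p = 1. The overall statistic is
the minimum per-ownership P; its permutation distribution is simulated with
a seeded generator, and the overall P uses the add-one estimator
(1 + c)/(n_perm + 1). Two resampling schemes are provided: `pairwise`
(independent Bernoulli(½) per (fire, ownership) pair, the default) and
`fire` (all of a fire's indicators flip together, preserving within-fire
dependence — the analogue of permuting whole observations). Both match the
Binomial(n_j, ½) marginal null; calibration runs on ideal sign data
(anticorrelated within-fire pairs, fair marginals) measured 4.3% and 4.7%
rejection at α = 0.05 over 300 replicates.

## The synthetic-data generator

The generator emulates the structure of a regional fire atlas over an
ownership mosaic: multi-class mosaics in checkerboard, Voronoi or swath
patterns; a three-class vegetation layer allocated on coarse tiles to match
target area fractions (defaults 51/31/18% forest/grass-shrub/unburnable);
heavy-tailed fire sizes (log-normal in lattice cells; with the default
96 km extent and 512-cell lattice, cell area 3.52 ha, μ = ln 142, σ = 1,
the median fire is ≈ 500 ha); and fires grown on the lattice by repeatedly
sampling a frontier cell with probability ∝ exp(β(owner(cell))), never
entering unburnable cells. β = 0 for every class makes growth blind to
ownership; raising β(A) strictly increases mean selectivity for A. One
master seed drives everything; each fire uses a counter-derived substream,
so fire k is reproducible regardless of how many fires are drawn. The
default Voronoi mosaic uses 32 sites per class (grain ≈ 7 km), chosen so
that most fires have several ownerships available — the partial-overlap
regime the method is designed for — while parcels stay much larger than the
median fire.

Two evaluation routes consume the grown fires. The **polygon route**
polygonises cell sets into footprints and runs the exact geometric pipeline
(buffer root-finding, polygon overlay). The **lattice route** computes
proportions by cell counting, with the availability ring taken as the
burned-cell-count nearest unburned cells by Euclidean distance — the
discrete equal-area annulus. The routes agree on used/available proportions
to within a few percent at the default cell size (tested), diverging only
in the degenerate o = π̂ = 1 corner where a sliver of availability flips the
index between 0 and 1. Replicated simulation studies use the lattice route;
running the polygon buffer solver ~10⁵ times would dominate their cost
without changing the statistics being studied. The lattice can be bounded
(fires whose ring would leave the extent are excluded, mirroring the
study-area rule) or periodic (a torus: translation-invariant, no
exclusions), the latter for calibration studies.

## When does the β = 0 null actually satisfy the test's null?

A central finding of the validation, worth stating prominently: an
ownership-blind *contiguous* fire does **not** automatically burn each
ownership in proportion to availability, so "β = 0" and "proportional use"
are not the same hypothesis. Three distinct effects emerged:

1. **Compositional (core–periphery) bias.** A contiguous fire against a
   concentric equal-area buffer over-uses whatever class lies at its core
   and under-uses the classes at its periphery. When availability spans k
   classes, roughly one sign per fire is positive and k − 1 are negative,
   so with k > 2 every class's sign fraction falls below ½ (measured
   f ≈ 0.40 on the default Voronoi mosaic) and the overall test rejects
   ownership-blind spread with high probability at n = 500. This is a
   genuine property of the use/availability construction for spatially
   contiguous "users", and plausibly contributes to real analyses in which
   most ownerships appear avoided. Per-class sign symmetry holds exactly
   when each availability region spans at most two classes with a straight
   shared boundary.

2. **Extent-edge asymmetry.** On a bounded landscape the exclusion rule
   removes large fires near the study edge. At the outermost ownership
   boundaries this removal is one-sided, leaving surplus peripheral
   negatives for the edge classes (measured f ≈ 0.445 there). A periodic
   lattice removes the effect.

3. **Shared-landscape correlation.** Conditioning on a fire-type stratum
   couples the selected fires to the vegetation layout, which is spatially
   correlated with which side of each ownership boundary those fires sit
   on; per-class sign counts then over-disperse relative to binomial
   (z-variance 1.38 vs 1.06 unconditioned). With homogeneous vegetation (a
   single stratum) the dispersion is binomial.

Consequently the type-I calibration study runs under conditions where the
null provably holds: periodic lattice, one 12-km swath per class (each
availability region spans ≤ 2 classes; the log-normal tail makes 3-strip
fires a ~0.8% rarity), homogeneous forest vegetation, 500 fires, 8 classes,
n_perm = 2000, 200 replicate datasets. Measured rejection: 4.0% (pairwise
null) and 4.5% (fire null) at α = 0.05. The bias-recovery study runs on a
32×32-tile checkerboard (3-km tiles, the high-encounter regime), 300 fires,
β = ±3 on one class: 50/50 dry-run replicates recover "preferred" and
"avoided" respectively. On the coarser Voronoi default, recovery of
β = +3 saturates near f ≈ 0.6–0.9 because ~30% of fires with the class
available only touch it with their ring — the fire never contacts the class
during growth, so the bias cannot act — a β-independent ceiling that
illustrates how mosaic grain limits the method's power.

**What passing these tests shows — and does not.** The tests validate the
statistical machinery (exact P-values, calibrated permutation combination,
monotone response to a known spread bias) under an idealised generator:
independent fires, a stationary mosaic, no weather or fuel covariates, no
spatial autocorrelation between fires, no severity gradation, single-part
fires, and perfectly mapped perimeters. Real fire atlases violate all of
these to some degree; in particular the compositional bias above means that
on real multi-ownership landscapes, rejecting proportional use does not by
itself distinguish boundary-respecting fire behaviour from the geometry of
contiguous spread. Interpretation should lean on the ranking and effect
sizes (f, Jacobs distributions), not the overall P alone.

## Numerical and interface conventions

All geometry is planar, in meters, in one shared CRS; areas are reported in
hectares. GeoJSON is the vector interchange format; invalid geometries are
repaired with a standard validity fix or rejected with a log message.
Tabular outputs are UTF-8 CSV with stable column order and full-precision
floats. Configuration is one YAML/JSON document (tolerances, seeds,
permutation count, class mappings); every CLI flag overrides it. The
pipeline writes a JSON run manifest with the config snapshot, input SHA-256
digests, stage timings and output paths; stage outputs are pure functions
of (inputs, config, seed), so fixed-seed reruns are byte-identical apart
from timings.

Problem sizes used in the shipped validation suite: the buffer sweep uses
100 generated footprints at a 256-cell lattice; the calibration and
recovery studies use the replicate counts and fire numbers stated above
with n_perm = 2000 per replicate. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands (e.g. ±1.5% on a 5% rejection
rate over 200 replicates).

## Known limitations

- GeoJSON only; no GeoPackage/Shapefile readers and no reprojection —
  inputs must share a planar metric CRS (a geographic CRS is rejected).
- The generator's fires are single-part; multi-part splitting is exercised
  on constructed fixtures.
- Buffers are purely geometric, not clipped to burnable land; whether that
  matches any particular field study's convention should be checked.
- The permutation test treats fires as independent; spatially clustered
  ignitions (lightning storms, complexes) violate this in real data.
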