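# Methods

## The estimation problem

In a philopatric, territorial raptor population, natal dispersal distance
(NDD) is the great-circle distance between a bird's natal nest and the nest
of its first breeding attempt with egg-laying. Most recaptures come from
genetic tagging: chicks DNA-profiled in the nest and breeding adults
re-identified from shed feathers collected under occupied nests, supplemented
by colour-ring resightings and GPS-tracked birds. The package implements the
full chain from raw tables (nests, individuals, long-format genotypes with a
sample register, encounters) to the fitted models, and a synthetic-data
generator that stands in for the withheld real data.

## Genotype identity matching

Two samples are one bird only under strict identity. Screen 1 requires all
nine primary microsatellite loci typed in both samples, zero mismatches, and
concordant known molecular sex. Screen 2 applies to pairs with 7 or 8
co-typed primary loci and no mismatch: both members are extended to eight
additional loci (in simulation, served on demand via a callback — the
in-silico analogue of re-genotyping) and accepted only with zero mismatches
across all co-typed loci of the 17. Samples typed at fewer than 7 primary
loci are unmatchable; unknown sex blocks acceptance. Allele pairs are
unordered; a locus is either fully typed or missing — half-calls are treated
as missing.

One-to-many acceptances are surfaced, never silently resolved. A feather
sample accepted against two different chicks is always a conflict (marked
chicks are distinct birds). A chick accepted against several feather samples
is a conflict only if some pair of those samples is itself incompatible (a
mismatch on co-typed loci or discordant sex); repeated sampling of the same
breeding adult across years is the expected case and is not penalised.

Reliability uses the probability of identity: PI = 2(Σp²)² − Σp⁴ for
unrelated pairs, and the sibling-corrected PI_sib = 1/4 + Σp²/2 + (Σp²)²/2 −
Σp⁴/4, multiplied across loci. PI_sib dominates PI at every locus (a property
test asserts this over random frequency vectors); both are validated against
brute-force enumeration of the genotype and sib-pair joint distributions.
Allele frequencies default to the breeding-adult (feather) sample, the larger
and less family-structured reference; this is configurable.

## Local density

Density at an active nest is the reciprocal area (km⁻²) of its Thiessen
(Voronoi) polygon truncated at r = 12.7 km — the population's mean
nearest-neighbour distance measured historically at low density, so the
truncation represents a generous upper bound on territory extent. Numerical
choices:

- Nests are projected to a spherical Lambert azimuthal **equal-area** frame
  centred on the nest-cloud centroid before tessellation, so polygon areas
  are true sphere areas; shape distortion at a few hundred km is irrelevant
  for areas. The projection refuses points more than 30° from its centre.
- The tessellation uses Qhull with the point set mirrored across the sides
  of a bounding box padded by 3r, which bounds every cell exactly and is
  robust to degenerate (cocircular) generators such as regular lattices.
- The truncation disc is a 256-vertex polygon; analytic-disc comparisons in
  tests use a 0.1 % area tolerance accordingly.
- Duplicate nest coordinates are an error (a data defect), not jittered.
- External nests (neighbouring countries) shape their neighbours' cells but
  receive no output row; cells intersecting a user-supplied exclusion
  geometry (e.g. an unmonitored border strip) are flagged and dropped from
  density analyses. The exclusion geometry must be supplied by the user; no
  default is meaningful.

Every density is bounded below by 1/(πr²) ≈ 1.974·10⁻³ km⁻². One projection,
centred once on the full study, is reused for all years so densities are
comparable across years.

## Dispersal records

Breeding encounters are validated by four joint criteria: age ≥ 3 cy (hatch
year = 1 cy), assignment to a nest known active that year, observer-confirmed
breeding, and egg-laying. The earliest valid event per bird defines first
detected breeding; identities from DNA, ring and GPS routes are merged with
the earliest year winning and same-year territory disagreements flagged as
inconsistencies (kept, never dropped silently).

Both natal and breeding densities are read in the **expected recruitment
year** to compare like with like under a changing population: the first
observed breeding year for birds first seen breeding at ≤ 4 cy (the median
recruitment age of GPS-tracked birds — a configuration constant, not
re-estimated from the data); otherwise the first year the bird was ≥ 4 cy
old, the territory existed, and it was not *known* to be occupied by another
same-sex bird. Occupancy knowledge comes from identified breeders and from
per-territory clustering of feather genotypes (exact match on ≥ 7 co-typed
primary loci); monitoring gaps count as "not known to be occupied", and the
rule never returns a year later than the first observed breeding.

The density difference is log(breeding density) − log(natal density); all
logarithms in the package are natural, so model coefficients read as log
ratios.

## Statistical layer

- **Median CIs** invert the sign test: bounds are order statistics
  x₍ₖ₊₁₎, x₍ₙ₋ₖ₎ with k the largest integer whose Binomial(n, ½) lower tail
  is ≤ (1−conf)/2; the achieved confidence is reported, and for n too small
  the whole range is returned with a warning.
- **Mixed models** are Gaussian LMMs with two crossed random intercepts
  (natal territory, natal year), fitted by REML. The fitter profiles the
  variance ratios through the Woodbury identity on the level space (never an
  n×n solve) and optimises with L-BFGS-B from two starts; fixed-effect df use
  the Satterthwaite approximation with finite-difference derivatives of the
  coefficient variance and of the REML deviance (central, switching to
  one-sided at the zero-variance boundary). The implementation reproduces
  lmerTest estimates, SEs, df and p-values to ≲0.1 % on test data, and the
  R fit serves as an independent oracle in the suite. Boundary (singular)
  fits are reported, fixed effects still returned; an exactly collinear
  design is pruned (aliased columns dropped with a warning, earlier terms
  taking priority); a zero-residual response short-circuits to the OLS
  solution.
- **Backward reduction**: continuous predictors are log-transformed then
  z-scored (constants stored for back-transformation); initial models carry
  all two-way interactions between main effects and the stated quadratics;
  interactions are eliminated before quadratics, one term per refit, largest
  p ≥ 0.05 first with ties broken by term name, and main effects are never
  dropped. The quadratic of a scaled predictor is the square of the scaled
  variable. The drop order and p-values are recorded.
- **Rayleigh tests** use Z = nr² with the standard series approximation,
  accurate to ~10⁻⁴ at n = 20 against a 10⁷-resample uniform null (tests
  check within Monte-Carlo error). r and p are rotation-invariant.
- **Holm adjustment** is applied exactly to the family of correlations
  passed in (by default the two sex-specific natal-vs-breeding density
  correlations); undefined (zero-variance) correlations are excluded from
  the family.
- **KDE mode**: Gaussian kernel, Scott's rule bandwidth, argmax on a
  512-point grid over the data range padded by three bandwidths, computed on
  the raw density scale (a log-scale option exists).
- **Zero crossing**: with z-scored predictors and reference factor levels,
  model 2's prediction reduces to β₀ + β₁z (+ β₂z²); the root (nearest the
  covariate mean if quadratic) is back-transformed to km⁻². The result is
  invariant to the scaling choice (a reparameterisation test asserts this);
  crossings outside the observed density range are flagged.

Records with NDD = 0 (a bird inheriting its natal territory) are kept for
medians and counts but excluded from the log-scale models and from bearings,
where they are undefined.

## The synthetic generator

The generator emulates the study conditions, not any particular dataset: a
150 × 150 km region holding 133 initial territories that stagnate
(rate 1.01/yr to 2014) then grow exponentially (1.13/yr from 2015, roughly
tripling by year 12, matching the reported territory counts 133 → ~380 and
median densities ~0.007 → ~0.014 km⁻²); new territories appear near existing
ones with probability 0.7 (uniform in an annulus of one to two territory
diameters — the simplest mechanism that yields spatial density
heterogeneity) under a hard 5 km minimum spacing. Planar km coordinates are
exported as WGS84 through the inverse equal-area projection so the pipeline's
spherical code paths are always exercised.

Demography runs year by year: resident pairs die at 0.12/yr per adult
(adult survival ~0.88, at the lower end of plausible for a large eagle,
chosen so the yearly vacancy supply gives recruits genuine settlement choice);
pairs breed with probability 0.5 (brood 1–3, mean ≈ 1.45); chicks survive to
recruitment with probability 0.35 and become eligible at 4 cy, drawing a
target distance from their sex's lognormal kernel — defaults
meanlog = log(57.6), log(35.9) km for females/males, common sdlog 0.85 — and
settling in the vacant same-sex territory that best matches the target on the
log-distance scale (plus an optional density-preference term, off by
default). Unfilled vacancies are taken by immigrant founders so pairs are
always complete; deferred floaters retry up to 4 years. Founder genotypes are
Hardy–Weinberg draws from Dirichlet(1) allele frequencies over 8 alleles per
locus; chicks inherit Mendelian; each locus call drops out independently at
0.05 per sample. Detection defaults mirror the marking effort of such
studies: 38 % of chicks DNA-profiled, 4.3 % GPS-tagged, feathers recovered
from 55 % of resident-years, 6 %/yr ring resightings of breeders.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: spatial truncation of DNA sampling at a country border
(detection is spatially uniform, so the real studies' downward NDD bias for
long dispersers is absent), breeding dispersal, genotyping error beyond
whole-locus dropout (no allelic drop-in or stutter), floater mortality
heterogeneity, habitat covariates, and observer heterogeneity. Settlement by
nearest-log-distance match is a stand-in mechanism: no mechanistic settlement
model is established for such populations, and conclusions about the
settlement *process* should not be read off the generator. Competition for
finite vacancies slightly attenuates realised sex differences relative to the
kernel ratio, which is why parameter-recovery experiments use a vacancy-rich
configuration.

## Problem sizes used in the suite

Property and oracle tests run at small n (seconds). The heavier experiments
are sized to be decisive yet quick: 10⁵ simulated sib pairs for the 9-locus
identity rate; 1.2·10⁵ unrelated pairs for the false-accept bound; 10⁶
resamples for the Rayleigh Monte-Carlo null; 2·10³ replicates for median-CI
coverage; and 500 replicate studies of ~100 recruits each for sex-effect
coverage (the package's standing estimate of pipeline calibration at
study-like sample sizes). All seeds are fixed; the whole suite runs in about
two minutes, the acceptance script in seconds.

## Known limitations

Satterthwaite df rely on finite differences and can be conservative exactly
at the zero-variance boundary (they are capped at the residual df). The
Voronoi mirror construction assumes the exclusion of nests farther than the
padding from the study cloud. The sign-test CI is exact but conservative at
small n. The generator's truth table treats first settlement as first
breeding with egg-laying; species where settlement and first laying decouple
would need an extra latency parameter.
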