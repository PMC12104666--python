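# natdisp

Natal dispersal analysis for territorial raptors studied by **genetic
mark–recapture**: chicks are DNA-profiled in the nest, breeding adults are
re-identified years later from shed feathers (plus colour-ring reads and GPS
tags), and each recaptured bird yields one natal dispersal distance — the
great-circle distance between its natal nest and the nest of its first
breeding attempt with egg-laying. The package is written for population
ecologists who want to ask how dispersal depends on **sex** and on **local
breeding density**, in species where direct tracking of enough individuals is
impractical.

## What it computes

**Identity.** Two multilocus microsatellite genotypes are the same bird only
on a strict full match: all 9 primary loci plus concordant molecular sex
(screen 1), or 7–8 co-typed primary loci extended to a 17-locus panel with
zero mismatches anywhere (screen 2). Reliability is quantified by the
probability of identity, in the sibling-rich case

    PI_sib = 1/4 + (1/2) Σpᵢ² + (1/2)(Σpᵢ²)² − (1/4) Σpᵢ⁴,

multiplied across loci (`PI = 2(Σpᵢ²)² − Σpᵢ⁴` for unrelated pairs).

**Local density.** Each active nest's territory is approximated by its
Thiessen (Voronoi) polygon truncated at r = 12.7 km; local density is the
reciprocal polygon area (km⁻²), computed per year in a local equal-area
projection. Isolated nests sit at the density floor 1/(πr²) ≈ 1.97·10⁻³ km⁻².

**Dispersal records.** Validated breeding encounters (age ≥ 3 cy, known nest,
confirmed breeding, egg-laying) and genotype matches are merged into one
record per bird: NDD, initial bearing, and natal/breeding densities looked up
in the *expected recruitment year* (first breeding year if first seen
breeding at ≤ 4 cy, else the first plausible unoccupied year).

**Inference.** Sex-specific median NDDs with sign-test-inverted 95% CIs;
Gaussian linear mixed models with crossed random intercepts (natal territory
× natal year) fitted by REML with Satterthwaite degrees of freedom —
model 1: `log(NDD) ~ sex + scaled log natal density (+²) + natal period`,
model 2: `log(breeding density) − log(natal density) ~ sex + scaled log natal
density (+²) + scaled log NDD (+²) + natal period` — each reduced by backward
elimination of non-significant interactions then quadratics (p ≥ 0.05), main
effects always retained; Holm-adjusted Pearson correlations of natal vs
breeding density; a density-by-year trend model; Rayleigh tests of dispersal
direction by sex and period; the KDE mode of breeding densities; and the
natal density at which model 2 predicts zero density difference.

Because real nest coordinates and genotypes for such studies are typically
withheld (sensitive species), the package ships a **synthetic study
generator** (`natdisp.synthetic`) with known ground truth: exponential
territory growth, Mendelian pedigrees with allelic dropout, sex-specific
lognormal dispersal kernels, density-dependent settlement, and per-method
detection. Under perfect detection the pipeline reproduces the truth table
bird for bird — that guarantee is part of the test suite.

## Worked example

```python
from natdisp import SimConfig, simulate_study, run_pipeline

study = simulate_study(SimConfig(seed=7))
res = run_pipeline(study.nests, study.individuals, study.genotypes,
                   study.samples, study.encounters)
```

`examples/05_full_analysis.py` prints, for this seed:

```
dispersal records recovered: 182

median NDD with 95% sign-test CI:
  female:  51.5 km  (42.3-63.0), n=89
    male:  39.8 km  (31.4-46.4), n=93

model 1 - response log(NDD):
                term  estimate       SE       df        t        p
         (Intercept)    3.6345   0.1225  13.8883  29.6772   0.0000
         sex[female]    0.4445   0.1118 146.5906   3.9769   0.0001
   log_natal_density   -0.0334   0.0627 107.5327  -0.5324   0.5956
natal_period[growth]   -0.0632   0.1427   8.3571  -0.4426   0.6693

density trend: 0.090 log-units/year (SE 0.002)
breeding-density KDE mode: 0.0116 /km^2
zero density-difference crossing: 0.0085 /km^2
```

Reading it: females disperse significantly farther than males (the
`sex[female]` coefficient is the difference in mean log NDD, here e^0.44 ≈
1.6× longer); local density grows ~9%/year as the population expands; and
birds hatched at densities below ~0.009 km⁻² tend to settle at denser sites
while birds from denser natal sites move down-density. The generator's
kernels (female median 57.6 km, male 35.9 km, true log ratio 0.47) sit inside
the fitted CI.

Each script in `examples/` demonstrates one capability (simulation, identity
matching, density, record assembly, full analysis). A thin CLI mirrors the
stages:

```bash
natdisp simulate --seed 1 --out study/
natdisp density --nests study/nests.csv --radius 12.7 --out density.csv
natdisp analyse --study study/ --out results/
```

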