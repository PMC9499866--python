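# genedaly

Comparative risk assessment for genetic exposures: how many healthy life
years does a risk allele, a rare-variant burden, or a polygenic score cost
— for one carrier, and for a population?

The package is aimed at statistical geneticists and genetic
epidemiologists who want to turn survival-model association results into
burden-of-disease estimates on the scale used by the Global Burden of
Disease (GBD) study: disability-adjusted life years (DALYs). It chains
four stages, each usable on its own:

1. **Hazard ratios** — Cox proportional-hazards fits (age timescale, sex
   and covariates adjusted, Efron ties) for every exposure–disease pair,
   with fixed-effects inverse-variance meta-analysis across cohorts and a
   composite mortality score built from polygenic scores.
2. **Spike-and-slab shrinkage** — per exposure, the log HRs across the
   disease panel get the prior
   `p_e ~ Beta(α, β)`, `b_{e,d} ~ Bernoulli(p_e) · ½[N(μ, σ²) + N(−μ, σ²)]`
   (defaults α=1, β=19, μ=0.3, σ=0.1), sampled by a collapsed Gibbs
   chain with an exact 3^d enumeration oracle for small panels. Pairs
   whose posterior null probability exceeds 10% are discarded; retained
   pairs keep their unshrunk Cox estimates.
3. **Attribution** — the multilevel population-attributable fraction
   `AFp_d = (Σ P_i HR_i − Σ P′_i HR_i) / Σ P_i HR_i` against an arbitrary
   counterfactual frequency vector, converted to yearly population DALYs
   per 100,000 (`AFp_d × DALY_d`) and lifetime individual DALYs
   (`AFp_d × DALY_d / (100,000 · P_exposed) × L`).
4. **Uncertainty** — delta-method CIs per disease; for totals, correlated
   resampling of the log-HR vector from `N(β̂, D Ĉ D)` where Ĉ is the
   disease–disease correlation of null-classified coefficients, plus a
   z-test for sex differences.

A synthetic-data module generates biobank-style cohorts (Hardy–Weinberg
dosages, exponential hazards calibrated to target incidences, death as
censoring) and GBD-style DALY tables with known ground truth, so the whole
pipeline is testable without any data access. An evaluation module
reproduces, on fully synthetic genotypes, the simulation study of how well
the shrinkage separates null from non-null effects after genome-wide
significance screening. See `docs/methods.md` for the full model account.

## Worked example

The attributable fraction for an allele with genotype frequencies
0.7 / 0.2 / 0.1 (zero / one / two copies), per-level hazard ratios
1.00 / 1.35 / 1.82, under the counterfactual that all one-copy carriers
had zero copies:

```python
import numpy as np
from genedaly.attribution import ExposureLevelSet, attributable_fraction

levels = ExposureLevelSet(
    P=[0.7, 0.2, 0.1], P_prime=[0.9, 0.0, 0.1],
    hr={"d": np.array([1.00, 1.35, 1.82])},
)
print(round(attributable_fraction(levels, "d"), 3))
# 0.061
```

i.e. about 6.1% of cases of this disease would be prevented if all
one-copy carriers had zero copies at birth. At 1,000 yearly DALYs per
100,000 for the disease and a life expectancy of 80 years, that fraction
converts to `0.061 × 1000 = 60.8` population DALYs per year per 100,000
and `60.8 / (100,000 × 0.2) × 80 = 0.243` lifetime healthy life years
lost per carrier.

The numbered drivers under `analysis/` run the same pipeline end to end
on a simulated cohort (20,000 individuals, 8 allele exposures, 10
diseases; run them in order, outputs land in `results/analysis/`):

```
$ python analysis/03_shrink_effects.py
shrinkage: 8/80 pairs retained (null probability <= 10%)
confusion table (rows: truth, cols: retained):
retained        False  True
truly non-null
False              72      0
True                0      8
```

— at this scale the shrinkage recovers the simulated truth exactly, and
`analysis/04_attribute_dalys.py` then prints each exposure's total
individual-attributable DALYs with resampling CIs, ranked by magnitude.

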