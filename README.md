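# evorescue

Individual-based, spatially and genetically explicit simulation of
**evolutionary rescue by introgressive hybridization** in fragmented
landscapes — built around the situation of the Taita Hills white-eyes,
where an endangered montane forest specialist lives in small forest
fragments surrounded by a widespread lowland congener, and occasional
hybridization may supply the genetic variation the specialist needs to
use the changing landscape.

The package is for eco-evolutionary modellers and conservation
scientists who want to simulate, on real or synthetic habitat rasters,
how mating behaviour (the hybridization propensity) and habitat change
(deforestation, corridors, plantation conversion) jointly shape
population recovery and gene-pool admixture.

## The model in brief

Space is a raster of 1-ha patches described by above-ground carbon
(AGC, Mg C ha⁻¹); montane forest is AGC ≥ 90, and per-habitat densities
set each patch's carrying capacity *K_p*. Birds are diploid for four
quantitative traits — AGC optimum *o*, AGC tolerance *τ* (suitable band
*o ± τ*), and dispersal-kernel parameters *μ_d, σ_d* — with one gene per
chromosome by default and an immutable species-of-origin tag on every
chromosome. Founder bands are 90–270 (specialist) and 3–97 (generalist).

Each year every bird undergoes **survival** (fixed s = 0.875, from a
mean lifespan of 8 years), **reproduction** (faithful pairs, 0–2
offspring; phenotype = allele mean; hybrids take the nearer parent's
species), and **natal dispersal**: a maximum distance drawn from a
truncated logistic kernel, a greedy walk to the 8-neighbour closest to
the bird's AGC optimum, and settlement by joining a partner-less
resident (conspecific always; heterospecific with probability *h*, the
hybridization propensity) or by founding a two-slot territory.

The headline statistic is **population heterozygosity**

&nbsp;&nbsp;&nbsp;&nbsp;H = 100 % × (chromosomes with extraspecific origin tag) / (all chromosomes in the species' gene pool),

an exact admixture measure that is identically 0 when *h* = 0, and the
**fragment-area regression**: OLS of mean fragment H (%) on ln(area in
ha), whose negative slope quantifies how much faster small, edge-heavy
fragments admix than large fragment interiors.

## Worked example

```python
import evorescue as ev

cfg = ev.SimConfig(
    synthetic=ev.SyntheticLandscapeSpec(n_rows=60, n_cols=60,
                                        fragment_areas=(25, 16, 9, 4, 2), seed=3),
    h=0.10,          # 10 % hybridization propensity
    years=60, replicates=3, seed=11,
)
result = ev.run_simulation(cfg)
final = result.final_record()
print(final[["replicate", "n_silvanus", "heterozygosity",
             "mean_agc_optimum", "mean_agc_tolerance"]].round(2).to_string(index=False))
```

```
 replicate  n_silvanus  heterozygosity  mean_agc_optimum  mean_agc_tolerance
         0         410            9.42            155.59               88.22
         1         439           17.03            147.57               86.38
         2         405           13.55            148.70               86.66
```

After 60 years at *h* = 10 %, 9–17 % of the specialist's chromosomes
descend from the generalist, and the mean AGC optimum has dropped from
the founder value 180 toward the contact zone — introgression is pulling
the specialist's habitat preference downslope while its broad tolerance
is retained, which is what lets the population grow beyond the pure
fragments. With `h=0` the heterozygosity column is exactly 0 in every
year and the specialist stays confined to montane forest.

The published fragment survey ships with the package:

```python
table = ev.taita_fragment_table()
slope, r2 = ev.fragment_regression(table.area_ha, table["mean"])
# slope -1.80 %/ln-ha, adjusted R^2 0.31
```

A command line mirrors the library (`evorescue simulate`, `evorescue
sweep --experiment hybridization|habitat`); see `evorescue --help`.

## Layout

- `evorescue.landscape` — AGC rasters, habitat classes, carrying
  capacities, fragment detection, the five habitat-change scenarios, and
  the synthetic landscape generator.
- `evorescue.genetics` — genomes, meiosis, trait expression, mutation,
  and the extraspecific-chromosome statistic.
- `evorescue.population` — bird agents, founder seeding, survival, pair
  formation, reproduction, hybrid species assignment.
- `evorescue.dispersal` — dispersal kernel, greedy movement, settlement
  (compiled cohort kernel plus per-bird reference API).
- `evorescue.engine` — annual cycle, replicates, experiments, YAML
  configuration.
- `evorescue.metrics` — censuses, density and heterozygosity maps,
  fragment statistics, the area regression, output serialization.
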