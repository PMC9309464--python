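# Methods

## The model

`evorescue` is an individual-based, spatially and genetically explicit
simulator built to ask whether introgressive hybridization with a common
lowland congener can rescue a small, fragmented population of a montane
habitat specialist — the situation of the Taita Hills white-eyes, where a
montane specialist (*silvanus* in the package's species tags) persists in
forest fragments embedded in a matrix occupied by a lowland generalist
(*flavilateralis*).

### Landscape

Space is a rectangular raster of one-hectare patches, each described by a
single habitat axis: above-ground carbon (AGC, Mg C ha⁻¹). AGC maps to
habitat classes through a breakpoint table (default: cropland < 10 ≤
woodland < 40 ≤ bushland < 90 ≤ montane forest), and each class carries a
density of breeding adults per hectare (default 2/4/6/8). These densities
are calibration knobs, not field estimates; they are even numbers because
capacity is committed in two-slot breeding territories. A *fragment* is an
8-connected component of montane-forest patches (queen adjacency — a bird
that can step diagonally experiences diagonal forest as contiguous).

### Individuals and genetics

Each bird is diploid for four quantitative traits: AGC optimum *o*, AGC
tolerance *τ* (suitable band *o ± τ*), and the location *μ_d* and scale
*σ_d* of its dispersal kernel. By default each trait sits alone on its own
chromosome pair (`genes_per_chromosome` = 1); settings of 2 or 4 co-locate
genes and thereby model genetic linkage. Chromosomes carry an immutable
founder-species tag. Meiosis is whole-chromosome: one homolog per pair,
independently across pairs, with no intra-chromosome crossover — linkage
is purely gene co-location. Phenotype is the per-trait mean of the two
alleles. Founders are homozygous at the species values: specialist
(180, 90, 30, 10), band 90–270; generalist (50, 47, 15, 5), band 3–97.

The central statistic, *population heterozygosity* H, is the percentage of
chromosomes in a species' gene pool whose origin tag is the other species.
It is an admixture measure, not locus-level heterozygosity, and is exact:
tags are only created at initialization and copied thereafter, so H
decomposes exactly into the chromosome-weighted mean of per-patch values,
and a closed gene pool has H ≡ 0.

Optional mutation perturbs each allele with probability 10⁻³ per
generation by a Gaussian whose sd defaults to 5 % of the founder
inter-species difference for that trait (6.5, 2.15, 0.75, 0.25 in trait
units); tolerance and the dispersal parameters are floored at 0. Both
defaults are calibration knobs for the exploratory mutation experiment and
are off in the standard runs.

### Annual cycle

Each iteration is one year: survival → reproduction → natal dispersal,
with the census after dispersal. Nobody reproduces or disperses in the
year they die; juveniles disperse in their natal year.

* **Survival** is annual, fixed and density-independent. The default
  s = 0.875 comes from the geometric mean-lifetime identity
  1/(1−s) = 8 years. Widowed partners stay in their patch as single
  residents.
* **Reproduction.** Pairs are heterosexual, faithful for life and
  sedentary. Each intact pair draws 0, 1 or 2 offspring (default uniform,
  mean 1; the brood distribution absorbs clutch size, breeding attempts
  and pre-dispersal juvenile mortality). A hybrid offspring is assigned to
  the species of the phenotypically nearer parent under a Euclidean
  distance with each trait scaled by the founder inter-species difference;
  exact ties (e.g. an F1 of pure founders) are uniform random.
* **Dispersal.** Each juvenile draws a maximum distance from a logistic
  kernel located at its own μ_d with scale σ_d, truncated at ≥ 1 patch
  length, then walks greedily: step to the 8-neighbour whose AGC is
  closest to the bird's optimum (ties uniform; orthogonal steps cost 1,
  diagonal √2; no path memory, no matrix-avoidance penalty). On each newly
  entered patch within its tolerance band the bird seeks a mate first: a
  partner-less opposite-sex conspecific resident is always joined; failing
  that, a heterospecific single is accepted with the hybridization
  propensity *h* — and a *refused* heterospecific advance sends the bird
  onward, free to retry at the next patch with a single. With no mate on
  offer it founds a two-slot territory if at least two capacity slots are
  uncommitted, else walks on. Exceeding the drawn maximum distance is
  death. The first step always leaves the natal patch.

Mate-seeking-first settlement is a deliberate reading of the model's
mating rule ("dispersers always try to mate with a conspecific; without
one they may accept an extraspecific mate"): under the alternative
territory-first reading, heterospecific pairing can only ever occur in
saturated patches, and introgression essentially never establishes.

Founders start unpaired, and pairing is otherwise triggered only by
dispersing settlers; to avoid a dead-locked first generation, initialization
performs a one-time conspecific pair-up of co-resident opposite-sex
founders. Co-resident widows never re-pair autonomously afterwards.

## Synthetic landscapes

The generator emulates the essential structure of the real AGC map: a
low-AGC matrix (default 20, woodland) containing compact high-AGC forest
blobs (default 150) of caller-chosen areas — by default the 19 published
fragment areas, 1–180 ha — each surrounded by a one-patch bushland
transition ring (default 60). Fragments are grouped into three
massif-like clusters with two-cell gaps, so that within a cluster the
bushland rings merge into one connected web, the way continuous scrub
links neighbouring fragments on a real massif. This connectivity is
load-bearing: under the greedy movement rule each phenotype is confined
to its preferred habitat component, so the bushland web is the only
conduit by which generalist-leaning admixed birds move between
fragments (their forest-optimum offspring then colonize the adjacent
fragment — a two-generation relay).

One structural feature matters more than any level choice: the two
founder bands overlap only at AGC ∈ [90, 97], which lies *inside* the
montane-forest class. On a raster with one flat AGC value per habitat
type, greedy walkers never step onto such cells (some neighbour is always
closer to a pure bird's optimum), the species never share a patch, and
hybridization is structurally impossible at any propensity. The generator
therefore assigns the outermost cells of every fragment (rim width 2 by
default) a contact-zone value of 93: still montane forest — so fragment
areas are exactly conserved — but inside both bands. A rim at least two
cells wide is self-sustaining (inner rim cells have only rim or forest
neighbours, so offspring born there settle there), which keeps the
species in contact; fragments smaller than the rim are all contact zone.
This is also the mechanism behind the fragment-size effect: small
fragments are mostly edge, so their gene pools admix faster than large
fragment interiors.

Scenario transforms are derived automatically from the generated
geometry, mirroring the conservation history the scenarios encode:
*edge depletion* deforests the outermost forest ring of the three largest
fragments (→ AGC 20); *fragment clearing* removes the four smallest
fragments (→ 20); *corridor planting* adds a one-patch-wide bridge
between the two largest fragments (→ 100); *plantation conversion* adds a
new forest block in the matrix (→ 100). Deforestation scenarios strictly
shrink montane-forest area; planting scenarios strictly grow it.

What the generator does *not* emulate: continuous AGC gradients (levels
are piecewise constant), topography and the real fragment geometry,
spatial autocorrelation of habitat quality, and landscape change over
time (scenario maps are static). Passing tests therefore demonstrate the
model's mechanisms — closed pools without hybridization, propensity-
ordered introgression, rescue, edge-driven admixture — on an idealized
archipelago, not quantitative predictions for the real landscape.

## Implementation and numerics

The population is held as parallel numpy arrays (structure of arrays);
survival, reproduction and meiosis are vectorized, and the dispersal year
is a single compiled (numba) pass over the juvenile cohort in a random
order. Every random number the dispersal kernel consumes (tie-breaks,
mate acceptance, mate choice) is pre-drawn from the replicate's numpy
Generator, so the interpreted and compiled kernels are bit-identical —
the test suite asserts exact agreement — and runs are reproducible on any
machine. Replicate r of a run with base seed b uses generator seed b + r;
the landscape has its own seed so that sweeps share one map.

Numerical conventions: greedy-step ties use exact float equality (level
sets share identical values); the kernel's truncated-logistic draw uses
the inverse CDF on the truncated support and is exact; a shape of 0
degenerates to max(μ_d, 1). Empty gene pools make H undefined (reported
as missing, never 0). The fragment regression uses natural log; the slope
in % per ln-ha depends on this choice. Degenerate inputs: isolated cells
kill dispersers; landscapes outside both bands initialize empty and stay
empty; an empty population is an absorbing state.

## Default experiment sizes

The reference experiments in the test suite and acceptance script run the
propensity sweep h ∈ {0, 0.01, 0.05, 0.1, 0.5, 1} on a 150 × 150 synthetic
landscape with the 19 published fragment areas, 10 replicates × 100 years
per propensity — population variables approach their quasi-stationary
trends well within that horizon, and one sweep completes in minutes on a
single core. Full-scale settings (50 replicates × 300 years, real AGC
raster via `landscape_file`) are plain configuration changes.

## Known limitations

* Dispersal has no perceptual range beyond one cell, no directional
  persistence and no cost surface; the greedy attraction to the AGC
  optimum is the only habitat response.
* A consequence worth stating precisely: a pure specialist standing in
  montane forest always has a forest neighbour closer to its optimum
  than any sub-90 cell, so the greedy step never leaves forest — pure
  specialists are confined to their natal fragment for life. With
  homozygous founders, whole-chromosome inheritance and mutation off,
  reachable optima are {50, 115, 180} and every specialist-labelled
  phenotype shares this confinement. Inter-fragment gene flow therefore
  runs exclusively through the bushland web (via admixed intermediates),
  which is slower and more stochastic than in a model with standing
  within-species trait variation. Very small fragments (1–3 ha, holding
  at most a couple of dozen birds) consequently lose their specialist
  populations to demographic stochasticity and are not recolonized by
  pure birds; the fragment-area admixture gradient is correspondingly
  weaker and noisier here than continuous-trait models produce.
* The kernel family and its founder parameters, the per-class densities,
  and the sub-90 class breakpoints are calibration knobs; empirical values
  would come from ringing and density data not shipped here.
* Species assignment by phenotype proximity makes the species label of
  deeply admixed birds somewhat arbitrary; the origin-tag statistic H is
  the robust quantity.
* Whether widow re-pairing should prefer conspecifics differently from
  first pairing is unknown; the same rule is applied everywhere.
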