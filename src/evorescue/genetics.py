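"""Diploid quantitative-trait genetics with chromosome-of-origin tracking.

Each bird carries a diploid genome of ``2 * n_pairs`` chromosomes. A
chromosome holds one or more genes (``genes_per_chromosome``), each coding
for one quantitative trait, and an immutable *origin* tag naming the founder
species the chromosome descends from. Inheritance is whole-chromosome:
meiosis picks one homolog per pair independently (independent assortment,
no intra-chromosome crossover), so genetic linkage is modelled purely by
gene co-location on a chromosome.

The origin tags are what make the population admixture statistic
well-defined: the "heterozygosity" of a species' gene pool is the
percentage of chromosomes whose origin tag is the *other* species, and tags
persist unchanged through arbitrarily many generations of backcrossing.

Two API levels coexist. The object level (:class:`Genome`, :func:`meiosis`,
:func:`fuse`, ...) operates on single individuals and is convenient for
inspection and testing; the batch helpers (:func:`meiosis_batch`,
:func:`express_traits_batch`) operate on stacked numpy arrays and back the
simulation engine. Both implement the same rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

# Trait layout (fixed order; trait t lives on homolog pair t // genes_per_chromosome)
TRAIT_NAMES: tuple[str, ...] = (
    "agc_optimum",
    "agc_tolerance",
    "dispersal_mean",
    "dispersal_shape",
)
N_TRAITS = len(TRAIT_NAMES)

# Species tags
SILVANUS = 0
FLAVILATERALIS = 1
SPECIES_NAMES: tuple[str, str] = ("silvanus", "flavilateralis")

# Traits constrained to be non-negative (tolerance and both dispersal parameters)
_NONNEG_TRAITS = (1, 2, 3)

_VALID_LAYOUTS = (1, 2, 4)


def species_index(tag: int | str) -> int:
    """Normalize a species tag (index or name) to its integer index."""
    if isinstance(tag, str):
        return SPECIES_NAMES.index(tag)
    if tag not in (SILVANUS, FLAVILATERALIS):
        raise ValueError(f"unknown species tag {tag!r}")
    return int(tag)


@dataclass(frozen=True)
class TraitSet:
    """Expressed phenotype of one bird.

    agc_optimum : preferred above-ground carbon, Mg C ha^-1
    agc_tolerance : half-width of the suitable AGC band, Mg C ha^-1
    dispersal_mean : location of the dispersal-distance kernel, patch lengths
    dispersal_shape : scale of the dispersal-distance kernel
    """

    agc_optimum: float
    agc_tolerance: float
    dispersal_mean: float
    dispersal_shape: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("trait values must be finite")
        if self.agc_tolerance < 0 or self.dispersal_mean < 0:
            raise ValueError("agc_tolerance and dispersal_mean must be >= 0")
        if self.dispersal_shape <= 0:
            raise ValueError("dispersal_shape must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.agc_optimum,
                self.agc_tolerance,
                self.dispersal_mean,
                self.dispersal_shape,
            ],
            dtype=float,
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "TraitSet":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_TRAITS,):
            raise ValueError(f"expected {N_TRAITS} trait values, got {values.shape}")
        return cls(*values.tolist())

    @property
    def band(self) -> tuple[float, float]:
        """Suitable AGC interval [optimum - tolerance, optimum + tolerance]."""
        return (self.agc_optimum - self.agc_tolerance, self.agc_optimum + self.agc_tolerance)


class Gene(NamedTuple):
    trait_id: str
    allele_value: float


class Chromosome(NamedTuple):
    """One haploid chromosome: its genes in fixed order plus the founder origin tag."""

    genes: tuple[Gene, ...]
    origin: int


@dataclass
class Genome:
    """Diploid genome as trait-major allele and pair-major origin arrays.

    ``alleles[t, k]`` is the allele value of trait ``t`` on homolog ``k``;
    ``origins[p, k]`` is the founder-species tag of homolog ``k`` of pair
    ``p``. Trait ``t`` resides on pair ``t // genes_per_chromosome``.
    """

    alleles: np.ndarray  # (N_TRAITS, 2) float
    origins: np.ndarray  # (n_pairs, 2) int8
    genes_per_chromosome: int = 1

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=float)
        self.origins = np.asarray(self.origins, dtype=np.int8)
        if self.genes_per_chromosome not in _VALID_LAYOUTS:
            raise ValueError(
                f"genes_per_chromosome must divide {N_TRAITS}; got {self.genes_per_chromosome}"
            )
        n_pairs = N_TRAITS // self.genes_per_chromosome
        if self.alleles.shape != (N_TRAITS, 2):
            raise ValueError(f"alleles must have shape ({N_TRAITS}, 2)")
        if self.origins.shape != (n_pairs, 2):
            raise ValueError(f"origins must have shape ({n_pairs}, 2)")

    @property
    def n_pairs(self) -> int:
        return N_TRAITS // self.genes_per_chromosome

    def chromosomes(self) -> Iterator[tuple[int, int, Chromosome]]:
        """Yield (pair_index, homolog, Chromosome) over the whole genome."""
        g = self.genes_per_chromosome
        for p in range(self.n_pairs):
            for k in (0, 1):
                genes = tuple(
                    Gene(TRAIT_NAMES[t], float(self.alleles[t, k]))
                    for t in range(p * g, (p + 1) * g)
                )
                yield p, k, Chromosome(genes, int(self.origins[p, k]))

    def copy(self) -> "Genome":
        return Genome(self.alleles.copy(), self.origins.copy(), self.genes_per_chromosome)


class Gamete(NamedTuple):
    """Haploid chromosome set produced by meiosis."""

    alleles: np.ndarray  # (N_TRAITS,)
    origins: np.ndarray  # (n_pairs,)
    genes_per_chromosome: int


def make_founder_genome(
    traits: TraitSet, species: int | str, genes_per_chromosome: int = 1
) -> Genome:
    """Homozygous genome of a founding individual.

    Both alleles of every gene equal the founder trait value and every
    chromosome carries the founder species' origin tag.
    """
    sp = species_index(species)
    if genes_per_chromosome not in _VALID_LAYOUTS:
        raise ValueError(
            f"genes_per_chromosome must be one of {_VALID_LAYOUTS}, got {genes_per_chromosome}"
        )
    alleles = np.repeat(traits.as_array()[:, None], 2, axis=1)
    n_pairs = N_TRAITS // genes_per_chromosome
    origins = np.full((n_pairs, 2), sp, dtype=np.int8)
    return Genome(alleles, origins, genes_per_chromosome)


def express_traits(genome: Genome) -> TraitSet:
    """Phenotype = arithmetic mean of the maternal and paternal allele per trait."""
    return TraitSet.from_array(genome.alleles.mean(axis=1))


def meiosis(genome: Genome, rng: np.random.Generator) -> Gamete:
    """Draw one gamete: per homolog pair, one whole chromosome with probability 1/2.

    Independent assortment across pairs; origin tags travel with their
    chromosome. No intra-chromosome crossover.
    """
    g = genome.genes_per_chromosome
    bits = rng.integers(0, 2, size=genome.n_pairs)
    trait_bits = np.repeat(bits, g)
    alleles = genome.alleles[np.arange(N_TRAITS), trait_bits]
    origins = genome.origins[np.arange(genome.n_pairs), bits]
    return Gamete(alleles.copy(), origins.astype(np.int8), g)


def fuse(gamete_a: Gamete, gamete_b: Gamete) -> Genome:
    """Zygote formation: pair the i-th chromosome of each gamete."""
    if gamete_a.genes_per_chromosome != gamete_b.genes_per_chromosome:
        raise ValueError("gamete layouts differ")
    if gamete_a.alleles.shape != gamete_b.alleles.shape:
        raise ValueError("gamete layouts differ")
    alleles = np.stack([gamete_a.alleles, gamete_b.alleles], axis=1)
    origins = np.stack([gamete_a.origins, gamete_b.origins], axis=1)
    return Genome(alleles, origins, gamete_a.genes_per_chromosome)


def mutate_genome(
    genome: Genome, rate: float, sd: float | np.ndarray, rng: np.random.Generator
) -> Genome:
    """Perturb each allele independently with probability ``rate``.

    Effects are zero-mean Gaussian with standard deviation ``sd`` (trait
    units; a scalar or one value per trait). Alleles of non-negative
    traits (tolerance, dispersal mean and shape) are floored at 0. Origin
    tags are untouched: mutation changes allele values, not ancestry.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be >= 0")
    sd_col = sd if sd.ndim == 0 else sd[:, None]
    out = genome.copy()
    hit = rng.random(out.alleles.shape) < rate
    if hit.any():
        out.alleles = out.alleles + hit * rng.normal(0.0, 1.0, size=out.alleles.shape) * sd_col
        out.alleles[_NONNEG_TRAITS, :] = np.maximum(out.alleles[_NONNEG_TRAITS, :], 0.0)
    return out


def extraspecific_fraction(
    genomes: Sequence[Genome] | np.ndarray, species: int | str
) -> float:
    """Percentage of chromosomes whose origin tag differs from ``species``.

    Accepts either a sequence of :class:`Genome` or a stacked origin array
    of shape (n, n_pairs, 2). Raises ``ValueError`` on an empty gene pool
    (the statistic is undefined there, and 0 would be misleading).
    """
    sp = species_index(species)
    if isinstance(genomes, np.ndarray):
        origins = genomes
        if origins.size == 0:
            raise ValueError("extraspecific fraction is undefined for an empty gene pool")
        return 100.0 * float(np.count_nonzero(origins != sp)) / origins.size
    if len(genomes) == 0:
        raise ValueError("extraspecific fraction is undefined for an empty gene pool")
    total = 0
    extra = 0
    for genome in genomes:
        total += genome.origins.size
        extra += int(np.count_nonzero(genome.origins != sp))
    return 100.0 * extra / total


# ---------------------------------------------------------------------------
# Batch (array) helpers used by the engine. Layouts mirror Genome:
# alleles (n, N_TRAITS, 2), origins (n, n_pairs, 2).
# ---------------------------------------------------------------------------

def express_traits_batch(alleles: np.ndarray) -> np.ndarray:
    return alleles.mean(axis=2)


def meiosis_batch(
    alleles: np.ndarray,
    origins: np.ndarray,
    genes_per_chromosome: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized meiosis over n genomes -> (gamete alleles (n, 4), origins (n, p))."""
    n, n_pairs = origins.shape[0], origins.shape[1]
    bits = rng.integers(0, 2, size=(n, n_pairs))
    trait_bits = np.repeat(bits, genes_per_chromosome, axis=1)  # (n, N_TRAITS)
    gam_alleles = np.take_along_axis(alleles, trait_bits[:, :, None], axis=2)[:, :, 0]
    gam_origins = np.take_along_axis(origins, bits[:, :, None], axis=2)[:, :, 0]
    return gam_alleles, gam_origins.astype(np.int8)


def mutate_batch(
    alleles: np.ndarray, rate: float, sd: float | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Batch counterpart of :func:`mutate_genome` (allele arrays only)."""
    sd = np.asarray(sd, dtype=float)
    sd_col = sd if sd.ndim == 0 else sd[None, :, None]
    hit = rng.random(alleles.shape) < rate
    out = alleles + hit * rng.normal(0.0, 1.0, size=alleles.shape) * sd_col
    out[:, _NONNEG_TRAITS, :] = np.maximum(out[:, _NONNEG_TRAITS, :], 0.0)
    return out


def genome_table(bird_ids: Sequence[int], genomes: Sequence[Genome]) -> pd.DataFrame:
    """Long-format genome dump: one row per (bird, pair, homolog, gene)."""
    rows = []
    for bird_id, genome in zip(bird_ids, genomes, strict=True):
        g = genome.genes_per_chromosome
        for p, k, chrom in genome.chromosomes():
            for gene in chrom.genes:
                rows.append(
                    {
                        "bird_id": bird_id,
                        "pair_index": p,
                        "homolog": k,
                        "origin": SPECIES_NAMES[chrom.origin],
                        "trait_id": gene.trait_id,
                        "allele_value": gene.allele_value,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["bird_id", "pair_index", "homolog", "origin", "trait_id", "allele_value"],
    )
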