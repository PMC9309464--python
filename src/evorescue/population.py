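"""Bird agents and the annual survival and reproduction processes.

The population is held as a structure-of-arrays (:class:`Population`):
parallel numpy arrays over individuals for species, sex, location, partner
index, age, genomes and cached expressed traits. This is what lets the
annual processes (survival, reproduction, dispersal) run vectorized or
compiled over tens of thousands of birds. A :class:`Bird` object view is
available for inspection and for the per-individual operations
(:func:`form_pair`, :func:`reproduce_pair`).

Demographic rules
-----------------
* Survival is annual, fixed and density-independent; the default
  s = 0.875 comes from the geometric mean-lifetime identity
  1 / (1 - s) = 8 years.
* Breeding pairs are heterosexual, faithful for life and sedentary; each
  intact pair produces 0, 1 or 2 offspring per year (default uniform,
  mean 1 — brood size absorbs clutch size, breeding attempts and juvenile
  mortality).
* A hybrid offspring is assigned to the species of the parent it is
  phenotypically more similar to, under a Euclidean distance in which each
  trait is scaled by the founder inter-species difference; exact ties are
  broken uniformly at random.
* Pair formation is triggered by dispersing settlers only (see the
  dispersal module); the single exception is a one-time conspecific
  pair-up within each patch at initialization, without which the founder
  population could never produce a first generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import genetics
from .genetics import (
    FLAVILATERALIS,
    N_TRAITS,
    SILVANUS,
    SPECIES_NAMES,
    Genome,
    TraitSet,
)
from .landscape import LandscapeGrid

FEMALE = 0
MALE = 1


@dataclass(frozen=True)
class SpeciesParams:
    """Founder traits and demographic parameters of one species."""

    tag: int
    founder: TraitSet
    survival: float = 0.875
    offspring_dist: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    hybridization: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.survival <= 1.0:
            raise ValueError("survival must be in (0, 1]")
        if not 0.0 <= self.hybridization <= 1.0:
            raise ValueError("hybridization propensity must be in [0, 1]")
        dist = np.asarray(self.offspring_dist, dtype=float)
        if dist.shape != (3,) or np.any(dist < 0) or not np.isclose(dist.sum(), 1.0):
            raise ValueError("offspring_dist must be 3 non-negative probabilities summing to 1")


def default_species(h: float = 0.0) -> tuple[SpeciesParams, SpeciesParams]:
    """Default montane specialist / lowland generalist parameter pair.

    The specialist's suitable band is 90-270 Mg C ha^-1 (optimum 180,
    tolerance 90); the generalist's is 3-97 (optimum 50, tolerance 47).
    Dispersal kernel defaults make inter-fragment distances on a
    Taita-like synthetic map reachable for the specialist.
    """
    silvanus = SpeciesParams(
        SILVANUS, TraitSet(180.0, 90.0, 30.0, 10.0), hybridization=h
    )
    flavilateralis = SpeciesParams(
        FLAVILATERALIS, TraitSet(50.0, 47.0, 15.0, 5.0), hybridization=h
    )
    return silvanus, flavilateralis


def founder_trait_matrix(species_list: Sequence[SpeciesParams]) -> np.ndarray:
    """(n_species, n_traits) founder phenotype matrix, indexed by tag."""
    out = np.zeros((len(species_list), N_TRAITS))
    for sp in species_list:
        out[sp.tag] = sp.founder.as_array()
    return out


def trait_scale(species_list: Sequence[SpeciesParams]) -> np.ndarray:
    """Per-trait scaling |founder_A - founder_B| for the similarity metric.

    Traits with identical founder values contribute unscaled (divisor 1).
    """
    mat = founder_trait_matrix(species_list)
    diff = np.abs(mat[0] - mat[1])
    return np.where(diff > 0, diff, 1.0)


@dataclass
class Bird:
    """Object view of one individual (used for inspection and unit-level ops)."""

    id: int
    species: int
    sex: int
    genome: Genome
    traits: TraitSet
    row: int
    col: int
    age: int = 0
    partner: Optional["Bird"] = field(default=None, repr=False)

    @property
    def species_name(self) -> str:
        return SPECIES_NAMES[self.species]


class Population:
    """Structure-of-arrays container for all living, settled birds."""

    __slots__ = (
        "ids", "species", "sex", "row", "col", "partner", "age", "reserved",
        "alleles", "origins", "traits", "genes_per_chromosome", "next_id",
    )

    def __init__(self, genes_per_chromosome: int = 1):
        self.genes_per_chromosome = genes_per_chromosome
        n_pairs = N_TRAITS // genes_per_chromosome
        self.ids = np.empty(0, dtype=np.int64)
        self.species = np.empty(0, dtype=np.int8)
        self.sex = np.empty(0, dtype=np.int8)
        self.row = np.empty(0, dtype=np.int32)
        self.col = np.empty(0, dtype=np.int32)
        self.partner = np.empty(0, dtype=np.int64)  # index into arrays, -1 = unpaired
        self.age = np.empty(0, dtype=np.int16)
        self.reserved = np.empty(0, dtype=bool)  # unpaired territory-holder
        self.alleles = np.empty((0, N_TRAITS, 2), dtype=float)
        self.origins = np.empty((0, n_pairs, 2), dtype=np.int8)
        self.traits = np.empty((0, N_TRAITS), dtype=float)
        self.next_id = 0

    def __len__(self) -> int:
        return self.ids.shape[0]

    @property
    def n_pairs(self) -> int:
        return N_TRAITS // self.genes_per_chromosome

    def add(
        self,
        species: np.ndarray,
        sex: np.ndarray,
        row: np.ndarray,
        col: np.ndarray,
        alleles: np.ndarray,
        origins: np.ndarray,
        partner: np.ndarray | None = None,
        reserved: np.ndarray | None = None,
        age: np.ndarray | None = None,
    ) -> np.ndarray:
        """Append birds; returns their new indices."""
        n = len(species)
        idx = np.arange(len(self), len(self) + n)
        self.ids = np.concatenate([self.ids, np.arange(self.next_id, self.next_id + n)])
        self.next_id += n
        self.species = np.concatenate([self.species, np.asarray(species, np.int8)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.int8)])
        self.row = np.concatenate([self.row, np.asarray(row, np.int32)])
        self.col = np.concatenate([self.col, np.asarray(col, np.int32)])
        self.partner = np.concatenate(
            [self.partner, np.full(n, -1, np.int64) if partner is None else np.asarray(partner, np.int64)]
        )
        self.age = np.concatenate(
            [self.age, np.zeros(n, np.int16) if age is None else np.asarray(age, np.int16)]
        )
        self.reserved = np.concatenate(
            [self.reserved, np.zeros(n, bool) if reserved is None else np.asarray(reserved, bool)]
        )
        self.alleles = np.concatenate([self.alleles, alleles])
        self.origins = np.concatenate([self.origins, origins.astype(np.int8)])
        self.traits = np.concatenate([self.traits, alleles.mean(axis=2)])
        return idx

    def compact(self, keep: np.ndarray) -> None:
        """Drop birds where ``keep`` is False; remap partner indices.

        A survivor whose partner is dropped becomes a widow (partner -1).
        """
        new_index = np.full(len(self), -1, dtype=np.int64)
        new_index[keep] = np.arange(int(keep.sum()))
        partner = self.partner[keep]
        self.partner = np.where(partner >= 0, new_index[partner], -1)
        for name in ("ids", "species", "sex", "row", "col", "age", "reserved",
                     "alleles", "origins", "traits"):
            setattr(self, name, getattr(self, name)[keep])

    def patch_index(self, n_cols: int) -> np.ndarray:
        return self.row.astype(np.int64) * n_cols + self.col

    def genome(self, i: int) -> Genome:
        return Genome(
            self.alleles[i].copy(), self.origins[i].copy(), self.genes_per_chromosome
        )

    def bird(self, i: int) -> Bird:
        return Bird(
            id=int(self.ids[i]),
            species=int(self.species[i]),
            sex=int(self.sex[i]),
            genome=self.genome(i),
            traits=TraitSet.from_array(self.traits[i]),
            row=int(self.row[i]),
            col=int(self.col[i]),
            age=int(self.age[i]),
        )

    def snapshot(self, year: int | None = None, replicate: int | None = None) -> pd.DataFrame:
        """Tidy per-bird snapshot (one row per living bird)."""
        extras = np.count_nonzero(
            self.origins != self.species[:, None, None], axis=(1, 2)
        )
        frame = pd.DataFrame(
            {
                "bird_id": self.ids,
                "species": np.asarray(SPECIES_NAMES)[self.species],
                "sex": np.where(self.sex == FEMALE, "F", "M"),
                "row": self.row,
                "col": self.col,
                "paired": self.partner >= 0,
                "agc_optimum": self.traits[:, 0],
                "agc_tolerance": self.traits[:, 1],
                "dispersal_mean": self.traits[:, 2],
                "dispersal_shape": self.traits[:, 3],
                "extraspecific_chromosomes": extras,
            }
        )
        if year is not None:
            frame.insert(0, "year", year)
        if replicate is not None:
            frame.insert(0, "replicate", replicate)
        return frame


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_population(
    grid: LandscapeGrid,
    species_list: Sequence[SpeciesParams],
    rng: np.random.Generator,
    genes_per_chromosome: int = 1,
    pair_bootstrap: bool = True,
) -> Population:
    """Seed founders on every patch inside a species' suitability band.

    Each eligible species adds Uniform{0..remaining capacity} homozygous
    founders of random sex to each patch (species considered in random
    order per patch), never exceeding the patch's carrying capacity. With
    ``pair_bootstrap`` (default), co-resident opposite-sex conspecifics
    are then paired up once, seeding the breeding structure.
    """
    pop = Population(genes_per_chromosome)
    valid = (~grid.nodata_mask) & (grid.capacity > 0)
    rows, cols = np.nonzero(valid)
    agc = grid.agc[rows, cols]
    cap = grid.capacity[rows, cols].astype(np.int64)
    remaining = cap.copy()

    order = np.argsort(rng.random((len(species_list), rows.size)), axis=0)
    counts = np.zeros((len(species_list), rows.size), dtype=np.int64)
    for rank in range(len(species_list)):
        for sp in species_list:
            pick = order[rank] == sp.tag
            lo, hi = sp.founder.band
            eligible = pick & (agc >= lo) & (agc <= hi)
            draw = rng.integers(0, remaining + 1)
            draw = np.where(eligible, draw, 0)
            counts[sp.tag] += draw
            remaining -= draw

    for sp in species_list:
        n_sp = counts[sp.tag]
        total = int(n_sp.sum())
        if total == 0:
            continue
        prow = np.repeat(rows, n_sp).astype(np.int32)
        pcol = np.repeat(cols, n_sp).astype(np.int32)
        founder = sp.founder.as_array()
        alleles = np.broadcast_to(founder[:, None], (total, N_TRAITS, 2)).copy()
        n_pairs = N_TRAITS // genes_per_chromosome
        origins = np.full((total, n_pairs, 2), sp.tag, dtype=np.int8)
        pop.add(
            species=np.full(total, sp.tag, np.int8),
            sex=rng.integers(0, 2, total).astype(np.int8),
            row=prow,
            col=pcol,
            alleles=alleles,
            origins=origins,
        )

    if pair_bootstrap and len(pop):
        _bootstrap_pairs(pop, grid.n_cols)
    return pop


def _bootstrap_pairs(pop: Population, n_cols: int) -> None:
    """One-time conspecific pair-up of co-resident opposite-sex founders."""
    key = pop.patch_index(n_cols) * 2 + pop.species
    for sex, other in ((FEMALE, MALE),):
        f_idx = np.flatnonzero(pop.sex == sex)
        m_idx = np.flatnonzero(pop.sex == other)
        f_idx = f_idx[np.argsort(key[f_idx], kind="stable")]
        m_idx = m_idx[np.argsort(key[m_idx], kind="stable")]
        f_keys, m_keys = key[f_idx], key[m_idx]
        common = np.intersect1d(np.unique(f_keys), np.unique(m_keys))
        for k in common:
            fs = f_idx[np.searchsorted(f_keys, k): np.searchsorted(f_keys, k, side="right")]
            ms = m_idx[np.searchsorted(m_keys, k): np.searchsorted(m_keys, k, side="right")]
            n = min(len(fs), len(ms))
            pop.partner[fs[:n]] = ms[:n]
            pop.partner[ms[:n]] = fs[:n]


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def annual_survival(
    pop: Population,
    s: float | Sequence[float],
    rng: np.random.Generator,
) -> int:
    """Apply one year of density-independent mortality in place.

    ``s`` is a single survival probability or one per species tag. Dead
    birds vacate their patch and widow their partner. Returns the number
    of deaths.
    """
    n = len(pop)
    if n == 0:
        return 0
    s_arr = np.asarray(s, dtype=float)
    if s_arr.ndim == 0:
        prob = np.full(n, float(s_arr))
    else:
        prob = s_arr[pop.species]
    if np.any((prob <= 0) | (prob > 1)):
        raise ValueError("survival probability must be in (0, 1]")
    alive = rng.random(n) < prob
    pop.compact(alive)
    return int(n - len(pop))


def repair_pairs(pop: Population) -> np.ndarray:
    """Post-survival pair bookkeeping; returns indices of widowed/single adults.

    Widows stay in their patch as partner-less residents; they re-pair
    only when a dispersing bird settles with them (no autonomous
    re-pairing among co-residents). This function validates partner
    symmetry and reports the current singles.
    """
    p = pop.partner
    paired = np.flatnonzero(p >= 0)
    if not np.array_equal(p[p[paired]], paired):
        raise AssertionError("partner relation is not symmetric")
    return np.flatnonzero(p < 0)


# ---------------------------------------------------------------------------
# Pair formation (per-individual rule; the batch path lives in dispersal)
# ---------------------------------------------------------------------------

def form_pair(resident: Bird, candidate: Bird, h: float, rng: np.random.Generator) -> bool:
    """Mate-acceptance rule between a partner-less resident and a settler.

    Conspecifics always pair; heterospecifics pair with probability ``h``
    (the hybridization propensity of the acting disperser). On success the
    partner references are set symmetrically.
    """
    if resident.partner is not None or candidate.partner is not None:
        raise ValueError("both birds must be unpaired")
    if resident.sex == candidate.sex:
        raise ValueError("pairing requires opposite sexes")
    if (resident.row, resident.col) != (candidate.row, candidate.col):
        raise ValueError("pairing requires co-located birds")
    if resident.species == candidate.species:
        accept = True
    else:
        accept = bool(rng.random() < h)
    if accept:
        resident.partner = candidate
        candidate.partner = resident
    return accept


# ---------------------------------------------------------------------------
# Reproduction
# ---------------------------------------------------------------------------

def assign_offspring_species(
    offspring_traits: np.ndarray | TraitSet,
    mother_species: int,
    father_species: int,
    mother_traits: np.ndarray | TraitSet,
    father_traits: np.ndarray | TraitSet,
    scale: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Species tag of one offspring.

    Conspecific parents pass on their common tag. A hybrid is assigned to
    the parent whose phenotype is nearer in scaled-Euclidean trait space
    (each trait divided by the founder inter-species difference); an exact
    tie is resolved uniformly at random.
    """
    if mother_species == father_species:
        return int(mother_species)
    off = offspring_traits.as_array() if isinstance(offspring_traits, TraitSet) else np.asarray(offspring_traits)
    mt = mother_traits.as_array() if isinstance(mother_traits, TraitSet) else np.asarray(mother_traits)
    ft = father_traits.as_array() if isinstance(father_traits, TraitSet) else np.asarray(father_traits)
    d_m = float(np.sum(((off - mt) / scale) ** 2))
    d_f = float(np.sum(((off - ft) / scale) ** 2))
    if d_m < d_f:
        return int(mother_species)
    if d_f < d_m:
        return int(father_species)
    return int(mother_species if rng.random() < 0.5 else father_species)


def reproduce_pair(
    mother: Bird,
    father: Bird,
    offspring_dist: Sequence[float],
    rng: np.random.Generator,
    scale: np.ndarray | None = None,
) -> list[Bird]:
    """Annual brood of one pair: 0, 1 or 2 juveniles at the natal patch.

    Each juvenile's genome is the fusion of one meiotic gamete per parent;
    sex is uniform; the species tag follows :func:`assign_offspring_species`.
    Juveniles are unpaired and do not count against patch capacity until
    they settle (see the dispersal module).
    """
    if (mother.row, mother.col) != (father.row, father.col):
        raise ValueError("breeding pair must be co-located")
    if scale is None:
        scale = np.ones(N_TRAITS)
    n = int(rng.choice(3, p=np.asarray(offspring_dist, dtype=float)))
    juveniles = []
    for k in range(n):
        genome = genetics.fuse(genetics.meiosis(mother.genome, rng), genetics.meiosis(father.genome, rng))
        traits = genetics.express_traits(genome)
        sp = assign_offspring_species(
            traits, mother.species, father.species, mother.traits, father.traits, scale, rng
        )
        juveniles.append(
            Bird(
                id=-1,  # assigned on settlement
                species=sp,
                sex=int(rng.integers(0, 2)),
                genome=genome,
                traits=traits,
                row=mother.row,
                col=mother.col,
            )
        )
    return juveniles


@dataclass
class JuvenileCohort:
    """Current-year juveniles awaiting natal dispersal (structure of arrays)."""

    species: np.ndarray
    sex: np.ndarray
    natal_row: np.ndarray
    natal_col: np.ndarray
    alleles: np.ndarray
    origins: np.ndarray
    traits: np.ndarray

    def __len__(self) -> int:
        return self.species.shape[0]


def reproduce_all(
    pop: Population,
    species_list: Sequence[SpeciesParams],
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    mutation_sd: float = 0.0,
) -> JuvenileCohort:
    """Vectorized annual reproduction over every intact pair.

    Brood size is drawn from the mother's species' offspring distribution.
    Optional mutation perturbs each juvenile allele with probability
    ``mutation_rate`` (Gaussian sd ``mutation_sd``) before traits are
    expressed.
    """
    g = pop.genes_per_chromosome
    idx = np.arange(len(pop))
    first = np.flatnonzero((pop.partner > idx))
    # orient as (mother, father)
    a, b = first, pop.partner[first]
    mothers = np.where(pop.sex[a] == FEMALE, a, b)
    fathers = np.where(pop.sex[a] == FEMALE, b, a)

    dists = np.zeros((len(species_list), 3))
    for sp in species_list:
        dists[sp.tag] = sp.offspring_dist
    cum = np.cumsum(dists, axis=1)[pop.species[mothers]]  # (n_pairs, 3)
    u = rng.random(len(mothers))
    n_off = (u[:, None] > cum[:, :2]).sum(axis=1)

    mother_rep = np.repeat(mothers, n_off)
    father_rep = np.repeat(fathers, n_off)
    nj = mother_rep.size
    if nj == 0:
        n_pairs_chrom = N_TRAITS // g
        return JuvenileCohort(
            *(np.empty(0, dt) for dt in (np.int8, np.int8, np.int32, np.int32)),
            alleles=np.empty((0, N_TRAITS, 2)),
            origins=np.empty((0, n_pairs_chrom, 2), np.int8),
            traits=np.empty((0, N_TRAITS)),
        )

    gam_m = genetics.meiosis_batch(pop.alleles[mother_rep], pop.origins[mother_rep], g, rng)
    gam_f = genetics.meiosis_batch(pop.alleles[father_rep], pop.origins[father_rep], g, rng)
    alleles = np.stack([gam_m[0], gam_f[0]], axis=2)
    origins = np.stack([gam_m[1], gam_f[1]], axis=2)
    if mutation_rate > 0 and np.any(np.asarray(mutation_sd) > 0):
        alleles = genetics.mutate_batch(alleles, mutation_rate, mutation_sd, rng)
    traits = alleles.mean(axis=2)

    scale = trait_scale(species_list)
    msp = pop.species[mother_rep].astype(np.int64)
    fsp = pop.species[father_rep].astype(np.int64)
    d_m = np.sum(((traits - pop.traits[mother_rep]) / scale) ** 2, axis=1)
    d_f = np.sum(((traits - pop.traits[father_rep]) / scale) ** 2, axis=1)
    coin = rng.random(nj) < 0.5
    hybrid_tag = np.where(d_m < d_f, msp, np.where(d_f < d_m, fsp, np.where(coin, msp, fsp)))
    species = np.where(msp == fsp, msp, hybrid_tag).astype(np.int8)

    return JuvenileCohort(
        species=species,
        sex=rng.integers(0, 2, nj).astype(np.int8),
        natal_row=pop.row[mother_rep].copy(),
        natal_col=pop.col[mother_rep].copy(),
        alleles=alleles,
        origins=origins,
        traits=traits,
    )
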