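"""Juvenile natal dispersal: kernel-drawn distance cap, greedy habitat-guided
stepping, and settlement with mate choice.

Every current-year juvenile draws a maximum dispersal distance from a
truncated logistic kernel parameterized by its own (heritable) dispersal
traits, then walks the raster greedily towards its AGC optimum (see
``_kernel`` for the step and settlement rules). The walk has no path
memory and no matrix-avoidance penalty: attraction to the optimum is the
only habitat response, so birds freely cross unsuitable matrix.

The cohort driver :func:`disperse_cohort` runs the whole year's juveniles
through the compiled kernel in a random order and applies the outcomes to
the population (settlers appended, pair links set, reservations updated).
:func:`disperse_juvenile` is the single-bird equivalent on the interpreted
kernel; :func:`sms_step` exposes one greedy step for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernel import SQRT2, _disperse_cohort_impl, disperse_cohort_kernel
from .landscape import LandscapeGrid, Patch
from .population import Bird, JuvenileCohort, Population, SpeciesParams


def draw_max_distance(
    dispersal_mean: float | np.ndarray,
    dispersal_shape: float | np.ndarray,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Maximum dispersal distance: logistic(mean, shape) truncated at >= 1.

    Sampled by inverse CDF on the truncated support, so the draw is a
    deterministic function of the generator state. A degenerate shape of 0
    returns max(mean, 1) exactly.
    """
    mu = np.asarray(dispersal_mean, dtype=float)
    s = np.asarray(dispersal_shape, dtype=float)
    scalar = mu.ndim == 0 and s.ndim == 0 and size is None
    if size is None:
        shape = np.broadcast_shapes(mu.shape, s.shape)
        size = int(np.prod(shape)) if shape else 1
    u = rng.random(size)
    mu_b = np.broadcast_to(mu, (size,))
    s_b = np.broadcast_to(s, (size,))
    with np.errstate(divide="ignore", over="ignore"):
        f1 = 1.0 / (1.0 + np.exp(-(1.0 - mu_b) / np.where(s_b > 0, s_b, 1.0)))
        up = f1 + u * (1.0 - f1)
        x = mu_b + s_b * np.log(up / (1.0 - up))
    x = np.where(s_b > 0, x, np.maximum(mu_b, 1.0))
    x = np.maximum(x, 1.0)
    return float(x[0]) if scalar else x


@dataclass
class DispersalState:
    """Running state of one dispersing juvenile."""

    bird: Bird
    position: tuple[int, int]
    distance_travelled: float
    max_distance: float
    visited_natal: bool = True  # the walk starts on the natal patch


def sms_step(
    state: DispersalState, grid: LandscapeGrid, rng: np.random.Generator
) -> Optional[tuple[int, int]]:
    """One greedy step: move to the 8-neighbour minimizing |AGC - optimum|.

    Ties are broken uniformly at random; the travelled distance grows by 1
    (orthogonal) or sqrt(2) (diagonal). Returns the new position, or None
    if there is no valid neighbour (the disperser dies).
    """
    r, c = state.position
    opt = state.bird.traits.agc_optimum
    best = np.inf
    ties: list[tuple[int, int, float]] = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if not (0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols):
                continue
            if grid.nodata_mask[rr, cc]:
                continue
            d = abs(float(grid.agc[rr, cc]) - opt)
            if d < best:
                best = d
                ties = []
            if d == best:
                ties.append((rr, cc, SQRT2 if (dr != 0 and dc != 0) else 1.0))
    if not ties:
        return None
    rr, cc, cost = ties[int(rng.random() * len(ties))]
    state.position = (rr, cc)
    state.distance_travelled += cost
    return (rr, cc)


def is_suitable(
    bird: Bird, patch: Patch, free_slots: int, singles: Sequence[Bird] = ()
) -> tuple[bool, Optional[str]]:
    """Settlement suitability of a patch for a dispersing bird.

    A patch qualifies only within the bird's AGC tolerance band; then
    ``join`` if a partner-less opposite-sex resident lives there —
    dispersers seek a mate before anything else (pairing is still subject
    to the hybridization propensity if that resident is heterospecific) —
    else ``territory`` if >= 2 uncommitted capacity slots remain (the
    settler reserves a slot for a future mate).
    """
    if abs(patch.agc - bird.traits.agc_optimum) > bird.traits.agc_tolerance:
        return False, None
    if any(s.sex != bird.sex and s.partner is None for s in singles):
        return True, "join"
    if free_slots >= 2:
        return True, "territory"
    return False, None


@dataclass
class DispersalResult:
    """Per-juvenile outcomes of one year's dispersal phase."""

    settled: np.ndarray        # (nj,) bool
    patch: np.ndarray          # (nj,) int64 flat index, -1 if dead
    mode: np.ndarray           # (nj,) int8: 0 territory, 1 join, -1 dead
    partner_gid: np.ndarray    # (nj,) int64 global id of joined resident
    distance: np.ndarray       # (nj,) float64
    steps: np.ndarray          # (nj,) int32
    max_distance: np.ndarray   # (nj,) float64

    @property
    def n_deaths(self) -> int:
        return int(np.count_nonzero(~self.settled))

    def log_frame(
        self, cohort: JuvenileCohort, n_cols: int, year: int | None = None,
        replicate: int | None = None,
    ) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "natal_row": cohort.natal_row,
                "natal_col": cohort.natal_col,
                "settled_row": np.where(self.settled, self.patch // n_cols, -1),
                "settled_col": np.where(self.settled, self.patch % n_cols, -1),
                "fate": np.where(self.settled, "SETTLED", "DEAD"),
                "distance": self.distance,
                "steps": self.steps,
            }
        )
        if year is not None:
            frame.insert(0, "year", year)
        if replicate is not None:
            frame.insert(0, "replicate", replicate)
        return frame


def _uniform_budget(maxdist: np.ndarray) -> np.ndarray:
    # <= 3 uniforms per walk iteration (tie-break, acceptance, mate pick);
    # iterations are bounded by floor(maxdist) successful steps plus one.
    return 3 * (np.floor(maxdist).astype(np.int64) + 2)


def _kernel_args(
    pop: Population,
    cohort: JuvenileCohort,
    grid: LandscapeGrid,
    species_list: Sequence[SpeciesParams],
    rng: np.random.Generator,
    order: np.ndarray | None = None,
):
    n_rows, n_cols = grid.n_rows, grid.n_cols
    n_patches = n_rows * n_cols
    n_adults, nj = len(pop), len(cohort)

    maxdist = np.atleast_1d(
        draw_max_distance(cohort.traits[:, 2], cohort.traits[:, 3], rng)
    ).astype(float)
    if order is None:
        order = rng.permutation(nj).astype(np.int64)
    budget = _uniform_budget(maxdist)
    u_off = np.zeros(nj + 1, np.int64)
    np.cumsum(budget, out=u_off[1:])
    u = rng.random(int(u_off[-1]))

    occ = np.bincount(pop.patch_index(n_cols), minlength=n_patches).astype(np.int32)
    res = np.bincount(
        pop.patch_index(n_cols)[pop.reserved], minlength=n_patches
    ).astype(np.int32)

    width = max(1, int(grid.capacity.max()))
    buf = np.zeros((n_patches, width), np.int64)
    singles = np.flatnonzero(pop.partner < 0)
    patch_s = pop.patch_index(n_cols)[singles]
    srt = np.argsort(patch_s, kind="stable")
    sorted_singles, sorted_patches = singles[srt], patch_s[srt]
    first = np.searchsorted(sorted_patches, sorted_patches, side="left")
    slot = np.arange(sorted_patches.size) - first
    buf[sorted_patches, slot] = sorted_singles
    buf_n = np.bincount(patch_s, minlength=n_patches).astype(np.int32)

    h = np.zeros(len(species_list), float)
    for sp in species_list:
        h[sp.tag] = sp.hybridization

    all_species = np.concatenate([pop.species, cohort.species])
    all_sex = np.concatenate([pop.sex, cohort.sex])
    all_reserved = np.concatenate([pop.reserved, np.zeros(nj, bool)])

    natal = cohort.natal_row.astype(np.int64) * n_cols + cohort.natal_col
    out_patch = np.empty(nj, np.int64)
    out_mode = np.empty(nj, np.int8)
    out_partner = np.empty(nj, np.int64)
    out_dist = np.empty(nj, np.float64)
    out_steps = np.empty(nj, np.int32)

    args = (
        order, natal, maxdist,
        np.ascontiguousarray(cohort.traits[:, 0]),
        np.ascontiguousarray(cohort.traits[:, 1]),
        cohort.species, cohort.sex,
        u, u_off,
        all_species, all_sex, all_reserved,
        buf, buf_n,
        np.ascontiguousarray(grid.agc, dtype=np.float64).ravel(),
        np.ascontiguousarray(~grid.nodata_mask).ravel(),
        np.ascontiguousarray(grid.capacity, dtype=np.int32).ravel(),
        occ, res, h,
        n_rows, n_cols, n_adults,
        out_patch, out_mode, out_partner, out_dist, out_steps,
    )
    outs = (out_patch, out_mode, out_partner, out_dist, out_steps, maxdist, all_reserved)
    return args, outs


def disperse_cohort(
    pop: Population,
    cohort: JuvenileCohort,
    grid: LandscapeGrid,
    species_list: Sequence[SpeciesParams],
    rng: np.random.Generator,
    compiled: bool = True,
) -> DispersalResult:
    """Disperse one year's juveniles in random order and settle them.

    Mutates ``pop``: settled juveniles are appended as adults at their
    settlement patch, joiners are pair-linked to their residents, and slot
    reservations are updated. Returns the per-juvenile outcomes.
    """
    nj = len(cohort)
    n_cols = grid.n_cols
    if nj == 0:
        empty = DispersalResult(*(np.empty(0, dt) for dt in
                                  (bool, np.int64, np.int8, np.int64, float, np.int32, float)))
        return empty
    n_adults = len(pop)
    args, outs = _kernel_args(pop, cohort, grid, species_list, rng)
    kernel = disperse_cohort_kernel if compiled else _disperse_cohort_impl
    kernel(*args)
    out_patch, out_mode, out_partner, out_dist, out_steps, maxdist, all_reserved = outs

    settled = out_patch >= 0
    result = DispersalResult(
        settled=settled, patch=out_patch, mode=out_mode, partner_gid=out_partner,
        distance=out_dist, steps=out_steps, max_distance=maxdist,
    )

    # apply outcomes: reservations consumed by joiners, then append settlers
    pop.reserved = all_reserved[:n_adults].copy()
    new_rank = np.cumsum(settled) - 1  # settlement order == juvenile index order
    pop.add(
        species=cohort.species[settled],
        sex=cohort.sex[settled],
        row=(out_patch[settled] // n_cols).astype(np.int32),
        col=(out_patch[settled] % n_cols).astype(np.int32),
        alleles=cohort.alleles[settled],
        origins=cohort.origins[settled],
        reserved=all_reserved[n_adults:][settled],
    )
    joiners = np.flatnonzero(settled & (out_partner >= 0))
    if joiners.size:
        gid = out_partner[joiners]
        partner_idx = np.where(gid < n_adults, gid, n_adults + new_rank[np.maximum(gid - n_adults, 0)])
        self_idx = n_adults + new_rank[joiners]
        pop.partner[self_idx] = partner_idx
        pop.partner[partner_idx] = self_idx
    return result


def disperse_juvenile(
    bird: Bird,
    pop: Population,
    grid: LandscapeGrid,
    species_list: Sequence[SpeciesParams],
    rng: np.random.Generator,
) -> tuple[str, Optional[tuple[int, int]]]:
    """Single-bird dispersal against the current population state.

    Runs the interpreted kernel on a one-juvenile cohort. Returns
    ("settled", (row, col)) or ("dead", None). Mutates ``pop`` exactly as
    the cohort driver would.
    """
    cohort = JuvenileCohort(
        species=np.array([bird.species], np.int8),
        sex=np.array([bird.sex], np.int8),
        natal_row=np.array([bird.row], np.int32),
        natal_col=np.array([bird.col], np.int32),
        alleles=bird.genome.alleles[None, :, :],
        origins=bird.genome.origins[None, :, :],
        traits=bird.traits.as_array()[None, :],
    )
    result = disperse_cohort(pop, cohort, grid, species_list, rng, compiled=False)
    if result.settled[0]:
        p = int(result.patch[0])
        return "settled", (p // grid.n_cols, p % grid.n_cols)
    return "dead", None
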