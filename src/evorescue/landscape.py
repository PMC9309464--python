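"""Raster landscape of 1-ha patches described by above-ground carbon (AGC).

The single habitat descriptor is AGC in Mg C ha^-1 per one-hectare grid
cell ("patch"). AGC maps onto coarse habitat classes via a breakpoint
table; montane forest is AGC >= 90. A "fragment" is a contiguous
(8-neighbour) component of montane-forest patches. Carrying capacity — the
number of adult birds that may breed in a patch — is a per-habitat-class
density. Habitat-change scenarios are pure raster transforms: a named set
of target patches whose AGC is replaced by a scenario-specific value.

Rasters are read and written as whitespace-delimited text grids with an
optional ESRI-ASCII style header; one cell = 1 ha, row 0 is the
northernmost row, coordinates are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

FOREST_THRESHOLD = 90.0  # Mg C ha^-1; montane forest iff AGC >= this

#: Habitat-class breakpoints below the forest threshold: class c applies on
#: [lower, upper). Calibration knobs, not empirical values.
DEFAULT_BREAKPOINTS: tuple[tuple[str, float], ...] = (
    ("cropland", 10.0),
    ("woodland", 40.0),
    ("bushland", 90.0),
)

#: Adults per hectare by habitat class. Even values only: capacity is
#: consumed in breeding-pair territories of two slots.
DEFAULT_DENSITY_TABLE: dict[str, int] = {
    "montane_forest": 8,
    "bushland": 6,
    "woodland": 4,
    "cropland": 2,
}

HABITAT_CLASSES = ("cropland", "woodland", "bushland", "montane_forest")

# 8-neighbour (queen) connectivity: a bird that can step diagonally
# experiences diagonal forest as contiguous.
_QUEEN = np.ones((3, 3), dtype=bool)

_SCENARIO_NAMES = (
    "control",
    "edge_depletion",
    "fragment_clearing",
    "corridor_planting",
    "plantation_conversion",
)
_SCENARIO_DEFAULT_AGC: dict[str, float | None] = {
    "control": None,
    "edge_depletion": 20.0,
    "fragment_clearing": 20.0,
    "corridor_planting": 100.0,
    "plantation_conversion": 100.0,
}


def classify_habitat(
    agc: float, breakpoints: Sequence[tuple[str, float]] = DEFAULT_BREAKPOINTS
) -> str:
    """Habitat class of a patch: montane_forest iff AGC >= 90, else by table."""
    if agc < 0:
        raise ValueError(f"AGC must be non-negative, got {agc}")
    if agc >= FOREST_THRESHOLD:
        return "montane_forest"
    for name, upper in breakpoints:
        if agc < upper:
            return name
    return breakpoints[-1][0]


def carrying_capacity(
    agc: float,
    density_table: Mapping[str, int] = DEFAULT_DENSITY_TABLE,
    breakpoints: Sequence[tuple[str, float]] = DEFAULT_BREAKPOINTS,
) -> int:
    """Adults a patch can hold, from its habitat class. Deterministic."""
    cls = classify_habitat(agc, breakpoints)
    try:
        cap = density_table[cls]
    except KeyError as exc:
        raise KeyError(f"density table has no entry for habitat class {cls!r}") from exc
    if cap < 0:
        raise ValueError(f"capacity for {cls!r} must be >= 0")
    return int(cap)


@dataclass(frozen=True)
class Patch:
    """View of one 1-ha grid cell."""

    row: int
    col: int
    agc: float
    capacity: int
    occupants: tuple[int, ...] = ()


@dataclass(frozen=True)
class Fragment:
    """Connected component of montane-forest patches; area in ha = patch count."""

    id: int
    patch_set: frozenset[tuple[int, int]]
    area: int

    @property
    def centroid(self) -> tuple[float, float]:
        rows = [r for r, _ in self.patch_set]
        cols = [c for _, c in self.patch_set]
        return (float(np.mean(rows)), float(np.mean(cols)))


@dataclass(frozen=True)
class ScenarioSpec:
    """A named landscape transform: set ``target_patches`` to ``new_agc``."""

    name: str
    target_patches: tuple[tuple[int, int], ...] = ()
    new_agc: float | None = None

    def __post_init__(self) -> None:
        if self.name not in _SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; expected one of {_SCENARIO_NAMES}")
        if self.name == "control" and self.target_patches:
            raise ValueError("control scenario must have no target patches")
        if self.new_agc is None:
            object.__setattr__(self, "new_agc", _SCENARIO_DEFAULT_AGC[self.name])
        object.__setattr__(self, "target_patches", tuple(map(tuple, self.target_patches)))


class LandscapeGrid:
    """Rectangular raster of patches with AGC, nodata mask and capacities."""

    def __init__(
        self,
        agc: np.ndarray,
        nodata_mask: np.ndarray | None = None,
        density_table: Mapping[str, int] = DEFAULT_DENSITY_TABLE,
        breakpoints: Sequence[tuple[str, float]] = DEFAULT_BREAKPOINTS,
    ) -> None:
        agc = np.asarray(agc, dtype=float)
        if agc.ndim != 2:
            raise ValueError("AGC raster must be 2-D")
        if nodata_mask is None:
            nodata_mask = np.zeros(agc.shape, dtype=bool)
        nodata_mask = np.asarray(nodata_mask, dtype=bool)
        if nodata_mask.shape != agc.shape:
            raise ValueError("nodata mask shape must match the raster")
        if np.any(agc[~nodata_mask] < 0):
            raise ValueError("AGC values must be non-negative")
        self.agc = agc
        self.nodata_mask = nodata_mask
        self.density_table = dict(density_table)
        self.breakpoints = tuple(breakpoints)
        self.capacity = self._compute_capacity()

    # -- derived rasters ----------------------------------------------------

    def _compute_capacity(self) -> np.ndarray:
        cap = np.zeros(self.agc.shape, dtype=np.int32)
        edges = [upper for _, upper in self.breakpoints]
        names = [name for name, _ in self.breakpoints]
        valid = ~self.nodata_mask
        cls_idx = np.digitize(self.agc, edges)  # last bin = >= last breakpoint
        for i, name in enumerate(names):
            cap[valid & (cls_idx == i) & (self.agc < FOREST_THRESHOLD)] = self.density_table[name]
        cap[valid & (self.agc >= FOREST_THRESHOLD)] = self.density_table["montane_forest"]
        return cap

    @property
    def n_rows(self) -> int:
        return self.agc.shape[0]

    @property
    def n_cols(self) -> int:
        return self.agc.shape[1]

    @property
    def forest_mask(self) -> np.ndarray:
        return (~self.nodata_mask) & (self.agc >= FOREST_THRESHOLD)

    def habitable_patches(self) -> int:
        return int(np.count_nonzero(~self.nodata_mask))

    def patch(self, row: int, col: int) -> Patch:
        if self.nodata_mask[row, col]:
            raise ValueError(f"patch ({row}, {col}) is outside the study area")
        return Patch(row, col, float(self.agc[row, col]), int(self.capacity[row, col]))

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(
            self.agc.copy(), self.nodata_mask.copy(), self.density_table, self.breakpoints
        )


# ---------------------------------------------------------------------------
# Raster IO
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def load_landscape(
    path: str | FsPath,
    nodata_value: float = -9999.0,
    density_table: Mapping[str, int] = DEFAULT_DENSITY_TABLE,
    breakpoints: Sequence[tuple[str, float]] = DEFAULT_BREAKPOINTS,
) -> LandscapeGrid:
    """Read a whitespace-delimited AGC grid, optionally with an ASCII-grid header."""
    lines = FsPath(path).read_text().splitlines()
    header: dict[str, float] = {}
    data_rows: list[list[float]] = []
    for line in lines:
        tokens = line.split()
        if not tokens:
            continue
        if not data_rows and len(tokens) == 2 and tokens[0].lower() in _HEADER_KEYS:
            header[tokens[0].lower()] = float(tokens[1])
            continue
        try:
            data_rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell in row {len(data_rows)}") from exc
    if not data_rows:
        raise ValueError(f"{path}: no raster data")
    width = len(data_rows[0])
    if any(len(r) != width for r in data_rows):
        raise ValueError(f"{path}: ragged rows (expected width {width})")
    agc = np.array(data_rows, dtype=float)
    if "nodata_value" in header:
        nodata_value = header["nodata_value"]
    if "ncols" in header and int(header["ncols"]) != agc.shape[1]:
        raise ValueError(f"{path}: header ncols does not match data")
    if "nrows" in header and int(header["nrows"]) != agc.shape[0]:
        raise ValueError(f"{path}: header nrows does not match data")
    mask = agc == nodata_value
    agc = np.where(mask, 0.0, agc)
    if np.any(agc[~mask] < 0):
        raise ValueError(f"{path}: negative AGC values present")
    return LandscapeGrid(agc, mask, density_table, breakpoints)


def save_landscape(
    grid: LandscapeGrid, path: str | FsPath, nodata_value: float = -9999.0, header: bool = True
) -> None:
    """Write the AGC raster in the same text dialect ``load_landscape`` reads."""
    out = np.where(grid.nodata_mask, nodata_value, grid.agc)
    with open(path, "w") as fh:
        if header:
            fh.write(f"ncols {grid.n_cols}\n")
            fh.write(f"nrows {grid.n_rows}\n")
            fh.write(f"nodata_value {nodata_value:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Fragments and scenarios
# ---------------------------------------------------------------------------

def identify_fragments(grid: LandscapeGrid) -> list[Fragment]:
    """Connected components (8-neighbour) of montane-forest patches.

    Returned sorted by decreasing area, ids 0..n-1 in that order.
    """
    labels, n = ndimage.label(grid.forest_mask, structure=_QUEEN)
    frags = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        patch_set = frozenset(zip(rows.tolist(), cols.tolist()))
        frags.append((len(patch_set), patch_set))
    frags.sort(key=lambda t: (-t[0], min(t[1]) if t[1] else (0, 0)))
    return [Fragment(i, ps, area) for i, (area, ps) in enumerate(frags)]


def fragment_table(fragments: Sequence[Fragment]) -> pd.DataFrame:
    rows = []
    for f in fragments:
        cr, cc = f.centroid
        rows.append({"id": f.id, "area_ha": f.area, "centroid_row": cr, "centroid_col": cc})
    return pd.DataFrame(rows, columns=["id", "area_ha", "centroid_row", "centroid_col"])


def apply_scenario(grid: LandscapeGrid, spec: ScenarioSpec) -> LandscapeGrid:
    """Copy of ``grid`` with each target patch's AGC replaced by ``spec.new_agc``."""
    out = grid.copy()
    for row, col in spec.target_patches:
        if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
            raise ValueError(f"target patch ({row}, {col}) outside the grid")
        if grid.nodata_mask[row, col]:
            raise ValueError(f"target patch ({row}, {col}) is a nodata cell")
        out.agc[row, col] = float(spec.new_agc)
    out.capacity = out._compute_capacity()
    return out


# ---------------------------------------------------------------------------
# Synthetic landscape generation
# ---------------------------------------------------------------------------

#: Synthetic-landscape AGC levels. ``forest_edge`` is the contact zone: the
#: outermost cells of each fragment sit at low forest AGC (>= 90 but inside
#: the lowland generalist's band, which tops out just above 90), so both
#: species can settle there — without such cells the two species never share
#: a patch and hybridization is structurally impossible. ``edge`` is the
#: non-forest transition ring (bushland) surrounding each fragment.
DEFAULT_AGC_LEVELS: dict[str, float] = {
    "matrix": 20.0,
    "edge": 60.0,
    "forest": 150.0,
    "forest_edge": 93.0,
}


def _blob_cells(area: int) -> np.ndarray:
    """Roughly square, 8-connected blob footprint of exactly ``area`` cells."""
    w = max(1, int(math.isqrt(area)))
    h = math.ceil(area / w)
    cells = [(r, c) for r in range(h) for c in range(w)][:area]
    return np.array(cells, dtype=int)


def _bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """8-connected raster line from (r0,c0) to (r1,c1), inclusive."""
    cells = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        cells.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return cells


def _ring(mask: np.ndarray, width: int) -> np.ndarray:
    grown = ndimage.binary_dilation(mask, structure=_QUEEN, iterations=width)
    return grown & ~mask


def generate_synthetic_landscape(
    n_rows: int,
    n_cols: int,
    fragment_areas: Sequence[int],
    edge_width: int = 1,
    agc_levels: Mapping[str, float] = DEFAULT_AGC_LEVELS,
    seed: int | np.random.Generator = 0,
    plantation_area: int = 64,
    forest_edge_width: int = 2,
    n_clusters: int = 3,
    cluster_gap: int = 2,
    max_tries: int = 2000,
    density_table: Mapping[str, int] = DEFAULT_DENSITY_TABLE,
    breakpoints: Sequence[tuple[str, float]] = DEFAULT_BREAKPOINTS,
) -> tuple[LandscapeGrid, list[Fragment], dict[str, ScenarioSpec]]:
    """Random fragmented landscape emulating a montane-forest archipelago.

    Compact high-AGC forest blobs of the requested areas are grouped into
    ``n_clusters`` massif-like clusters in a low-AGC matrix. Within a
    cluster, fragments sit ``cluster_gap`` cells apart (default 2), so
    their ``edge_width`` transition rings of intermediate AGC merge into a
    connected bushland web — mirroring real massifs, where continuous
    scrub links neighbouring fragments. This web is what carries
    generalist-leaning birds between fragments: the greedy movement rule
    confines each phenotype to its preferred habitat component, so
    without a connected transition network there is no inter-fragment
    gene flow at all. Fragments themselves stay distinct (a 2-cell gap is
    never 8-adjacent). Ground-truth fragments and auto-derived
    habitat-change scenarios are returned alongside:

    - ``edge_depletion``: the outer forest ring of the three largest
      fragments -> 20
    - ``fragment_clearing``: the four smallest fragments -> 20
    - ``corridor_planting``: a 1-patch-wide bridge between the two largest
      fragments -> 100
    - ``plantation_conversion``: a new ``plantation_area``-cell block -> 100

    Reproducible under ``seed``; raises ``RuntimeError`` if the areas cannot
    be packed after bounded retries.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    areas = sorted((int(a) for a in fragment_areas), reverse=True)
    if any(a < 1 for a in areas):
        raise ValueError("fragment areas must be >= 1 ha")
    n_clusters = max(1, min(n_clusters, len(areas)))
    agc = np.full((n_rows, n_cols), float(agc_levels["matrix"]))
    forest = np.zeros((n_rows, n_cols), dtype=bool)
    margin = edge_width + 1
    # cluster webs must stay apart: rings of different clusters never touch
    inter_cluster_gap = 2 * edge_width + 2
    cluster_foot: list[np.ndarray] = [
        np.zeros((n_rows, n_cols), dtype=bool) for _ in range(n_clusters)
    ]
    placements: list[np.ndarray] = []

    def try_place(cells, ok_mask, near_mask=None):
        bh, bw = cells[:, 0].max() + 1, cells[:, 1].max() + 1
        lo_r, hi_r = margin, n_rows - bh - margin
        lo_c, hi_c = margin, n_cols - bw - margin
        if hi_r < lo_r or hi_c < lo_c:
            return None
        if near_mask is not None and near_mask.any():
            anchors = np.argwhere(near_mask)
        else:
            anchors = None
        for _ in range(max_tries):
            if anchors is None:
                r0 = int(rng.integers(lo_r, hi_r + 1))
                c0 = int(rng.integers(lo_c, hi_c + 1))
            else:
                ar, ac = anchors[int(rng.integers(anchors.shape[0]))]
                r0 = int(ar) - int(rng.integers(bh))
                c0 = int(ac) - int(rng.integers(bw))
                if not (lo_r <= r0 <= hi_r and lo_c <= c0 <= hi_c):
                    continue
            rr, cc = cells[:, 0] + r0, cells[:, 1] + c0
            if not ok_mask[rr, cc].all():
                continue
            if anchors is not None and near_mask is not None and not near_mask[rr, cc].any():
                continue
            return rr, cc
        return None

    for i, area in enumerate(areas):
        cells = _blob_cells(area)
        cluster = i % n_clusters
        others = np.zeros((n_rows, n_cols), dtype=bool)
        for c, foot in enumerate(cluster_foot):
            if c != cluster:
                others |= foot
        own = cluster_foot[cluster]
        # keep >= cluster_gap from own cluster, >= inter_cluster_gap from others
        ok = np.ones((n_rows, n_cols), dtype=bool)
        if own.any():
            ok &= ~ndimage.binary_dilation(own, _QUEEN, iterations=cluster_gap - 1)
        if others.any():
            ok &= ~ndimage.binary_dilation(others, _QUEEN, iterations=inter_cluster_gap - 1)
        near = None
        if own.any():
            # attach at exactly cluster_gap: footprint must touch the band
            near = ndimage.binary_dilation(own, _QUEEN, iterations=cluster_gap)
        placed = try_place(cells, ok, near)
        if placed is None and near is not None:
            placed = try_place(cells, ok)  # fall back to anywhere valid
        if placed is None:
            raise RuntimeError(
                f"could not place a {area}-ha fragment after {max_tries} tries; "
                "grid too small or too crowded"
            )
        rr, cc = placed
        forest[rr, cc] = True
        cluster_foot[cluster][rr, cc] = True
        placements.append(np.stack([rr, cc], axis=1))
    blocked = ndimage.binary_dilation(forest, _QUEEN, iterations=margin + 1)
    agc[forest] = float(agc_levels["forest"])
    # Contact zone: the outermost forest_edge_width cells of each fragment
    # sit at low forest AGC inside both species' bands. A rim at least two
    # cells wide holds a self-sustaining mixed population (its inner cells
    # have only in-rim or forest neighbours), which is what keeps the two
    # species in contact; fragments smaller than the rim are all contact.
    contact_agc = float(agc_levels.get("forest_edge", agc_levels["forest"]))
    if contact_agc < FOREST_THRESHOLD:
        raise ValueError("forest_edge AGC must stay in the montane-forest class (>= 90)")
    for placed in placements:
        foot = np.zeros_like(forest)
        foot[placed[:, 0], placed[:, 1]] = True
        interior = ndimage.binary_erosion(foot, structure=_QUEEN, iterations=forest_edge_width)
        agc[foot & ~interior] = contact_agc
    edge = _ring(forest, edge_width)
    agc[edge] = float(agc_levels["edge"])

    grid = LandscapeGrid(agc, None, density_table, breakpoints)
    fragments = identify_fragments(grid)

    scenarios = {"control": ScenarioSpec("control")}
    # Edge depletion: deforest the outermost forest ring of the three
    # largest fragments (strictly reduces montane-forest area).
    targets: list[tuple[int, int]] = []
    for frag in fragments[:3]:
        fmask = np.zeros_like(forest)
        rows, cols = zip(*frag.patch_set)
        fmask[list(rows), list(cols)] = True
        boundary = fmask & ~ndimage.binary_erosion(fmask, structure=_QUEEN)
        targets.extend(zip(*np.nonzero(boundary)))
    targets = [(int(r), int(c)) for r, c in targets]
    scenarios["edge_depletion"] = ScenarioSpec("edge_depletion", tuple(targets))
    # Fragment clearing: the four smallest fragments.
    targets = []
    for frag in fragments[-4:]:
        targets.extend(frag.patch_set)
    scenarios["fragment_clearing"] = ScenarioSpec("fragment_clearing", tuple(targets))
    # Corridor: 1-wide bridge between the two largest fragments.
    if len(fragments) >= 2:
        a, b = fragments[0], fragments[1]
        (ar, ac), (br, bc) = a.centroid, b.centroid
        line = _bresenham(int(round(ar)), int(round(ac)), int(round(br)), int(round(bc)))
        targets = [(r, c) for r, c in line if not forest[r, c]]
        scenarios["corridor_planting"] = ScenarioSpec("corridor_planting", tuple(targets))
    # Plantation conversion: a brand-new forest block in free matrix. On
    # cramped grids the block shrinks (halving) until it can be placed.
    placed = False
    area = int(plantation_area)
    while not placed and area >= 1:
        cells = _blob_cells(area)
        bh, bw = cells[:, 0].max() + 1, cells[:, 1].max() + 1
        for _ in range(max_tries):
            r0 = int(rng.integers(margin, max(margin + 1, n_rows - bh - margin)))
            c0 = int(rng.integers(margin, max(margin + 1, n_cols - bw - margin)))
            rr, cc = cells[:, 0] + r0, cells[:, 1] + c0
            if rr.max() >= n_rows or cc.max() >= n_cols or blocked[rr, cc].any():
                continue
            scenarios["plantation_conversion"] = ScenarioSpec(
                "plantation_conversion", tuple(zip(rr.tolist(), cc.tolist()))
            )
            placed = True
            break
        area //= 2
    if not placed:
        raise RuntimeError("could not place the plantation-conversion block")
    return grid, fragments, scenarios
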