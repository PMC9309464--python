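"""Census statistics, spatial maps and the fragment-area analysis.

Central statistic: *population heterozygosity* H, the percentage of
chromosomes in a species' gene pool whose founder origin is the other
species. It is an admixture measure (distinct from locus-level
heterozygosity) and decomposes exactly: the global H equals the
chromosome-count-weighted mean of per-patch H values.

The fragment-area analysis regresses mean fragment H (%) on the natural
log of fragment area (ha) by ordinary least squares, reporting the slope
(% per ln-ha) and adjusted R^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genetics import species_index
from .landscape import Fragment, LandscapeGrid, save_landscape
from .population import Population

YEAR_RECORD_COLUMNS = (
    "experiment", "scenario", "h", "replicate", "year",
    "n_silvanus", "heterozygosity", "mean_agc_optimum", "mean_agc_tolerance",
    "n_flavilateralis",
)


def population_summary(pop: Population, species: int | str) -> dict[str, float]:
    """Adult count, gene-pool heterozygosity and trait means for one species.

    An empty species pool yields N=0 with the other statistics missing
    (NaN), since they are undefined there.
    """
    sp = species_index(species)
    mask = pop.species == sp
    n = int(np.count_nonzero(mask))
    if n == 0:
        return {
            "n": 0, "heterozygosity": float("nan"),
            "mean_agc_optimum": float("nan"), "mean_agc_tolerance": float("nan"),
        }
    origins = pop.origins[mask]
    het = 100.0 * np.count_nonzero(origins != sp) / origins.size
    return {
        "n": n,
        "heterozygosity": float(het),
        "mean_agc_optimum": float(pop.traits[mask, 0].mean()),
        "mean_agc_tolerance": float(pop.traits[mask, 1].mean()),
    }


def density_map(pop: Population, grid: LandscapeGrid, species: int | str) -> np.ndarray:
    """Adult counts per patch; sums to the species' global N."""
    sp = species_index(species)
    mask = pop.species == sp
    counts = np.bincount(
        pop.patch_index(grid.n_cols)[mask], minlength=grid.n_rows * grid.n_cols
    )
    return counts.reshape(grid.n_rows, grid.n_cols).astype(np.int64)


def patch_heterozygosity(
    pop: Population, grid: LandscapeGrid, species: int | str
) -> np.ndarray:
    """Per-patch H (%) over the species' residents; NaN where none live."""
    sp = species_index(species)
    mask = pop.species == sp
    n_patches = grid.n_rows * grid.n_cols
    pidx = pop.patch_index(grid.n_cols)[mask]
    per_bird_extra = np.count_nonzero(pop.origins[mask] != sp, axis=(1, 2))
    chrom_per_bird = pop.origins.shape[1] * 2
    extra = np.bincount(pidx, weights=per_bird_extra, minlength=n_patches)
    total = np.bincount(pidx, minlength=n_patches) * chrom_per_bird
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 100.0 * extra / total
    return h.reshape(grid.n_rows, grid.n_cols)


def fragment_heterozygosity(
    pop: Population,
    grid: LandscapeGrid,
    fragments: Sequence[Fragment],
    species: int | str,
) -> pd.DataFrame:
    """Per-fragment H of the species' residents at census time.

    Fragment membership is residence in one of the fragment's patches.
    Uninhabited fragments report NaN (the statistic is undefined), mirroring
    how missing fragments are excluded from the area regression.
    """
    sp = species_index(species)
    patch_h_counts = {}
    mask = pop.species == sp
    pidx = pop.patch_index(grid.n_cols)[mask]
    per_bird_extra = np.count_nonzero(pop.origins[mask] != sp, axis=(1, 2))
    chrom_per_bird = pop.origins.shape[1] * 2
    rows = []
    for frag in fragments:
        flat = np.array(
            [r * grid.n_cols + c for r, c in frag.patch_set], dtype=np.int64
        )
        member = np.isin(pidx, flat)
        n = int(member.sum())
        if n == 0:
            h = float("nan")
        else:
            h = 100.0 * float(per_bird_extra[member].sum()) / (n * chrom_per_bird)
        rows.append({"id": frag.id, "area_ha": frag.area, "n": n, "heterozygosity": h})
    return pd.DataFrame(rows, columns=["id", "area_ha", "n", "heterozygosity"])


def fragment_regression(
    areas: Sequence[float], heterozygosity: Sequence[float]
) -> tuple[float, float]:
    """OLS of fragment H (%) on ln(area in ha) -> (slope, adjusted R^2).

    Fragments with missing H are excluded; fewer than 3 defined points
    raise ``ValueError`` (the fit is undefined).
    """
    areas = np.asarray(areas, dtype=float)
    h = np.asarray(heterozygosity, dtype=float)
    if areas.shape != h.shape:
        raise ValueError("areas and heterozygosity must align")
    keep = np.isfinite(h) & np.isfinite(areas) & (areas > 0)
    if keep.sum() < 3:
        raise ValueError("fragment regression needs >= 3 fragments with defined H")
    x = sm.add_constant(np.log(areas[keep]))
    fit = sm.OLS(h[keep], x).fit()
    return float(fit.params[1]), float(fit.rsquared_adj)


@dataclass(frozen=True)
class FragmentStat:
    """Across-scenario summary of one fragment's heterozygosity."""

    id: int
    area_ha: int
    per_scenario: Mapping[str, float]

    @property
    def mean(self) -> float:
        vals = [v for v in self.per_scenario.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd(self) -> float:
        vals = [v for v in self.per_scenario.values() if np.isfinite(v)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


def write_outputs(
    records: pd.DataFrame,
    maps: Mapping[str, np.ndarray],
    out_dir: str | Path,
    grid: LandscapeGrid | None = None,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Serialize per-year records (CSV), maps (text grids) and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    path = out / "records.csv"
    records.to_csv(path, index=False)
    written["records"] = path
    for name, arr in maps.items():
        path = out / f"{name}.txt"
        arr = np.asarray(arr)
        with open(path, "w") as fh:
            fh.write(f"ncols {arr.shape[1]}\n")
            fh.write(f"nrows {arr.shape[0]}\n")
            for row in arr:
                fh.write(" ".join("nan" if not np.isfinite(v) else f"{v:g}" for v in row) + "\n")
        written[name] = path
    if grid is not None:
        path = out / "landscape.txt"
        save_landscape(grid, path)
        written["landscape"] = path
    if manifest is not None:
        path = out / "manifest.json"
        path.write_text(json.dumps(dict(manifest), indent=2, default=str))
        written["manifest"] = path
    return written
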