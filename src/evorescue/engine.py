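"""Simulation orchestration: annual cycles, replicates and experiments.

One iteration is one year, in which every bird passes through the three
life-history processes in order: survival, reproduction, natal dispersal.
Censuses are taken at the end of each year, after dispersal. Replicate r
of a run with base seed b uses an independent generator seeded b + r; the
landscape is generated (or loaded) once per run from its own seed so that
sweeps over the hybridization propensity or over habitat scenarios share
the identical map.

Two standard experiments are provided: a hybridization-propensity sweep
at fixed landscape, and a habitat-scenario sweep at fixed propensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .data import TAITA_FRAGMENT_AREAS
from .dispersal import disperse_cohort
from .genetics import FLAVILATERALIS, SILVANUS
from .landscape import (
    Fragment,
    LandscapeGrid,
    ScenarioSpec,
    apply_scenario,
    generate_synthetic_landscape,
    identify_fragments,
    load_landscape,
)
from .population import (
    Population,
    SpeciesParams,
    annual_survival,
    default_species,
    initialize_population,
    repair_pairs,
    reproduce_all,
    trait_scale,
)

HYBRIDIZATION_PROPENSITIES = (0.0, 0.01, 0.05, 0.10, 0.50, 1.0)
SCENARIO_SWEEP = (
    "control", "edge_depletion", "fragment_clearing",
    "corridor_planting", "plantation_conversion",
)


@dataclass(frozen=True)
class SyntheticLandscapeSpec:
    """Parameters of the synthetic fragmented landscape."""

    n_rows: int = 150
    n_cols: int = 150
    fragment_areas: tuple[int, ...] = TAITA_FRAGMENT_AREAS
    edge_width: int = 1
    agc_matrix: float = 20.0
    agc_edge: float = 60.0
    agc_forest: float = 150.0
    agc_forest_edge: float = 93.0  # contact zone: forest cells both species tolerate
    forest_edge_width: int = 2
    plantation_area: int = 64
    seed: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one experiment arm."""

    landscape_file: str | None = None
    synthetic: SyntheticLandscapeSpec = field(default_factory=SyntheticLandscapeSpec)
    scenario: str = "control"
    scenario_spec: ScenarioSpec | None = None  # explicit targets (file landscapes)
    h: float = 0.0
    years: int = 300
    replicates: int = 50
    genes_per_chromosome: int = 1
    mutation_enabled: bool = False
    mutation_rate: float = 1e-3
    mutation_sd: tuple[float, ...] | float | None = None  # default: 5% of founder gap
    seed: int = 1
    species: tuple[SpeciesParams, SpeciesParams] | None = None
    experiment: str = ""
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.years < 0 or self.replicates < 1:
            raise ValueError("years must be >= 0 and replicates >= 1")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0, 1]")

    def species_params(self) -> tuple[SpeciesParams, SpeciesParams]:
        if self.species is not None:
            return tuple(replace(sp, hybridization=self.h) for sp in self.species)
        return default_species(self.h)

    def resolved_mutation_sd(self) -> np.ndarray:
        if self.mutation_sd is not None:
            return np.broadcast_to(np.asarray(self.mutation_sd, float), (4,)).copy()
        return 0.05 * trait_scale(self.species_params())

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            syn = dict(raw["synthetic"])
            if "fragment_areas" in syn:
                syn["fragment_areas"] = tuple(syn["fragment_areas"])
            raw["synthetic"] = SyntheticLandscapeSpec(**syn)
        raw.update(overrides)
        return cls(**raw)


def build_landscape(
    config: SimConfig,
) -> tuple[LandscapeGrid, list[Fragment], dict[str, ScenarioSpec]]:
    """Base landscape plus scenario transforms for one run (pre-scenario)."""
    if config.landscape_file is not None:
        grid = load_landscape(config.landscape_file)
        scenarios: dict[str, ScenarioSpec] = {"control": ScenarioSpec("control")}
        if config.scenario_spec is not None:
            scenarios[config.scenario_spec.name] = config.scenario_spec
        return grid, identify_fragments(grid), scenarios
    syn = config.synthetic
    grid, fragments, scenarios = generate_synthetic_landscape(
        syn.n_rows, syn.n_cols, syn.fragment_areas, syn.edge_width,
        {"matrix": syn.agc_matrix, "edge": syn.agc_edge, "forest": syn.agc_forest,
         "forest_edge": syn.agc_forest_edge},
        seed=syn.seed, plantation_area=syn.plantation_area,
        forest_edge_width=syn.forest_edge_width,
    )
    return grid, fragments, scenarios


@dataclass
class SimState:
    """Mutable state of one replicate."""

    grid: LandscapeGrid
    pop: Population
    rng: np.random.Generator
    species: tuple[SpeciesParams, SpeciesParams]
    year: int = 0


@dataclass
class RunResult:
    """Outputs of one run (all replicates of one configuration)."""

    config: SimConfig
    records: pd.DataFrame
    grid: LandscapeGrid
    fragments: list[Fragment]
    final_populations: list[Population]

    def final_record(self) -> pd.DataFrame:
        last = self.records["year"] == self.records["year"].max()
        return self.records[last].reset_index(drop=True)


def _census(state: SimState, config: SimConfig, replicate: int) -> dict:
    summary = metrics.population_summary(state.pop, SILVANUS)
    n_flav = int(np.count_nonzero(state.pop.species == FLAVILATERALIS))
    return {
        "experiment": config.experiment,
        "scenario": config.scenario,
        "h": config.h,
        "replicate": replicate,
        "year": state.year,
        "n_silvanus": summary["n"],
        "heterozygosity": summary["heterozygosity"],
        "mean_agc_optimum": summary["mean_agc_optimum"],
        "mean_agc_tolerance": summary["mean_agc_tolerance"],
        "n_flavilateralis": n_flav,
    }


def run_year(state: SimState, config: SimConfig, validate: bool = False) -> None:
    """Advance one year: survival -> reproduction -> dispersal.

    Birds that die do not reproduce or disperse that year; juveniles
    disperse (and may settle) in their natal year. Dispersal processes
    juveniles in a fresh random order each year.
    """
    sp = state.species
    s = np.zeros(len(sp))
    for p in sp:
        s[p.tag] = p.survival
    annual_survival(state.pop, s, state.rng)
    repair_pairs(state.pop)
    mut_rate = config.mutation_rate if config.mutation_enabled else 0.0
    mut_sd = config.resolved_mutation_sd() if config.mutation_enabled else 0.0
    cohort = reproduce_all(state.pop, sp, state.rng, mut_rate, mut_sd if np.any(mut_sd) else 0.0)
    disperse_cohort(state.pop, cohort, state.grid, sp, state.rng)
    state.pop.age += 1
    state.year += 1
    if validate:
        _validate_state(state)


def _validate_state(state: SimState) -> None:
    pop, grid = state.pop, state.grid
    occ = np.bincount(pop.patch_index(grid.n_cols), minlength=grid.n_rows * grid.n_cols)
    cap = grid.capacity.ravel()
    if np.any(occ > cap):
        raise AssertionError("patch occupancy exceeds carrying capacity")
    p = pop.partner
    paired = np.flatnonzero(p >= 0)
    if paired.size and not np.array_equal(p[p[paired]], paired):
        raise AssertionError("partner relation is not symmetric")
    if paired.size:
        if np.any(pop.row[p[paired]] != pop.row[paired]) or np.any(
            pop.col[p[paired]] != pop.col[paired]
        ):
            raise AssertionError("partners are not co-located")


def run_replicate(
    config: SimConfig,
    grid: LandscapeGrid,
    replicate: int,
    validate: bool = False,
) -> tuple[list[dict], Population]:
    """One replicate on a prepared (post-scenario) landscape."""
    rng = np.random.default_rng(config.seed + replicate)
    species = config.species_params()
    pop = initialize_population(grid, species, rng, config.genes_per_chromosome)
    state = SimState(grid=grid, pop=pop, rng=rng, species=species)
    records = [_census(state, config, replicate)]
    for _ in range(config.years):
        run_year(state, config, validate=validate)
        records.append(_census(state, config, replicate))
    return records, state.pop


def run_simulation(config: SimConfig, validate: bool = False) -> RunResult:
    """Run all replicates of one configuration.

    The landscape is built once, the scenario transform applied, and each
    replicate simulated with its derived seed. Streams per-year census
    records into a tidy table.
    """
    base, fragments, scenarios = build_landscape(config)
    if config.scenario == "control":
        grid = base
    else:
        if config.scenario not in scenarios:
            raise ValueError(f"no targets known for scenario {config.scenario!r}")
        grid = apply_scenario(base, scenarios[config.scenario])
    records: list[dict] = []
    finals: list[Population] = []
    for r in range(config.replicates):
        rec, pop = run_replicate(config, grid, r, validate=validate)
        records.extend(rec)
        finals.append(pop)
    frame = pd.DataFrame(records, columns=list(metrics.YEAR_RECORD_COLUMNS))
    return RunResult(config, frame, grid, identify_fragments(grid), finals)


def run_experiment(sweep: Sequence[SimConfig], validate: bool = False) -> pd.DataFrame:
    """Run several configurations and concatenate their per-year records.

    The result is keyed by (experiment, scenario, h, replicate, year) and
    is independent of the order in which configurations are listed, since
    every replicate derives its generator from the configuration alone.
    """
    frames = []
    failures = []
    for config in sweep:
        try:
            frames.append(run_simulation(config, validate=validate).records)
        except Exception as exc:  # preserve completed runs, report failures
            failures.append((config, exc))
    if failures and not frames:
        raise failures[0][1]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(metrics.YEAR_RECORD_COLUMNS)
    )
    out.attrs["failures"] = [(repr(c), str(e)) for c, e in failures]
    return out.sort_values(["experiment", "scenario", "h", "replicate", "year"]).reset_index(
        drop=True
    )


def hybridization_sweep(
    base: SimConfig, propensities: Sequence[float] = HYBRIDIZATION_PROPENSITIES
) -> list[SimConfig]:
    """Propensity sweep on a fixed landscape (scenario held at control)."""
    return [
        replace(base, h=h, scenario="control", experiment="hybridization")
        for h in propensities
    ]


def habitat_sweep(base: SimConfig, h: float = 0.01) -> list[SimConfig]:
    """Scenario sweep at fixed propensity (default 1%)."""
    return [
        replace(base, h=h, scenario=name, experiment="habitat")
        for name in SCENARIO_SWEEP
    ]
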