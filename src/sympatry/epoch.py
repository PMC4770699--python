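"""Evolutionary epoch driver: ecology within generations, reproduction between.

One generation = the population placed uniformly at random on a freshly
uniform resource landscape, 100 ecological time steps of foraging, then soft
selection and mate choice to build the next generation (non-overlapping
generations).  One epoch = ``generations`` such cycles from 100 founders,
with the mutation magnitude annealed over the epoch.  Every source of
randomness in an epoch derives from a single seed via numpy SeedSequence
spawning (one child stream per generation), so runs are reproducible and
partial reruns of a generation are possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .foraging import ForagingState, ecological_step
from .genetics import FounderRanges, MutationSchedule, founder_genomes
from .landscape import EcoParams, Landscape
from .mating import MatingConfig, next_generation
from .population import Population, SNAPSHOT_COLUMNS

__all__ = [
    "EpochConfig",
    "GenerationRecord",
    "EpochResult",
    "run_generation",
    "run_epoch",
    "run_batch",
    "write_snapshot_csv",
    "read_snapshot_csv",
    "write_generation_log",
]


@dataclass(frozen=True)
class EpochConfig:
    """Everything needed to reproduce one evolutionary run bit-for-bit."""

    generations: int = 250
    steps_per_generation: int = 100
    founders: int = 100
    seed: int = 0
    mode: str = "m_trait"
    width: int = 50
    height: int = 50
    eco: EcoParams = field(default_factory=EcoParams)
    mating: MatingConfig = field(default_factory=MatingConfig)
    founder_ranges: FounderRanges = field(default_factory=FounderRanges)
    s_start: float = 0.10
    s_end: float = 0.001
    keep_tables: bool = False
    use_kernel: bool = True

    def __post_init__(self) -> None:
        for name in ("generations", "steps_per_generation", "founders", "width", "height"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        object.__setattr__(
            self, "mating", replace(self.mating, mode=self.mode)
        )

    @property
    def schedule(self) -> MutationSchedule:
        return MutationSchedule(self.s_start, self.s_end, self.generations)


@dataclass
class GenerationRecord:
    """End-of-generation summary of the population that foraged."""

    g: int
    n: int
    mean_alpha: float
    sd_alpha: float
    mean_delta: float
    sd_delta: float
    mean_rho: float
    sd_rho: float
    mean_m: float
    sd_m: float
    total_biomass: float
    table: pd.DataFrame | None = None


@dataclass
class EpochResult:
    """All per-generation records plus the final per-individual snapshot."""

    config: EpochConfig
    records: list[GenerationRecord]
    final_snapshot: pd.DataFrame | None
    status: str  # "ok" | "extinct"

    @property
    def n_trajectory(self) -> np.ndarray:
        return np.array([rec.n for rec in self.records])

    @property
    def final_mean_m(self) -> float:
        return self.records[-1].mean_m


def _record(g: int, pop: Population, keep_table: bool) -> GenerationRecord:
    phen = pop.phenotypes
    means = phen.mean(axis=0)
    sds = phen.std(axis=0, ddof=1) if pop.n > 1 else np.zeros(4)
    return GenerationRecord(
        g=g,
        n=pop.n,
        mean_alpha=float(means[0]), sd_alpha=float(sds[0]),
        mean_delta=float(means[1]), sd_delta=float(sds[1]),
        mean_rho=float(means[2]), sd_rho=float(sds[2]),
        mean_m=float(means[3]), sd_m=float(sds[3]),
        total_biomass=float(pop.biomass.sum()),
        table=pop.snapshot_frame() if keep_table else None,
    )


def run_generation(
    population: Population,
    landscape: Landscape,
    config: EpochConfig,
    g: int,
    rng: np.random.Generator,
) -> tuple[Population | None, GenerationRecord]:
    """One full generational cycle; returns (next population | None, record).

    The landscape is reset to its uniform initial state and the population
    peppered uniformly at random over it before the ecological steps run.
    """
    if population.n == 0:
        raise ValueError("population must be nonempty")
    landscape.reset()
    pos = np.column_stack(
        [
            rng.integers(0, landscape.width, size=population.n),
            rng.integers(0, landscape.height, size=population.n),
        ]
    )
    phen = population.phenotypes
    state = ForagingState(
        landscape=landscape,
        pos=pos,
        biomass=population.biomass,
        alpha=phen[:, 0].copy(),
        delta=phen[:, 1].copy(),
        rho=phen[:, 2].copy(),
    )
    for _ in range(config.steps_per_generation):
        ecological_step(state, config.eco, rng, kernel=config.use_kernel)

    end_pop = Population(
        genomes=population.genomes,
        biomass=state.biomass,
        pos=state.pos,
        ids=population.ids,
    )
    record = _record(g, end_pop, config.keep_tables)
    progeny, _ = next_generation(end_pop, g, config.mating, config.schedule, rng)
    return progeny, record


def run_epoch(config: EpochConfig, out_dir: str | Path | None = None) -> EpochResult:
    """Run a full evolutionary epoch from 100 founders.

    On extinction the records accumulated so far are returned with status
    "extinct".  When ``out_dir`` is given, the per-generation log and the
    final snapshot CSV are written there.
    """
    root = np.random.SeedSequence(config.seed)
    gen_seeds = root.spawn(config.generations + 1)
    founder_rng = np.random.Generator(np.random.PCG64(gen_seeds[0]))
    population: Population | None = Population(
        genomes=founder_genomes(config.founders, founder_rng, config.founder_ranges),
        biomass=np.full(config.founders, config.mating.offspring_initial_biomass),
    )
    landscape = Landscape(config.width, config.height, params=config.eco)

    records: list[GenerationRecord] = []
    final_table: pd.DataFrame | None = None
    status = "ok"
    for g in range(config.generations):
        rng = np.random.Generator(np.random.PCG64(gen_seeds[g + 1]))
        # the table of the last completed generation is always kept
        keep = config.keep_tables or g == config.generations - 1
        cfg = config if keep == config.keep_tables else replace(config, keep_tables=True)
        population, record = run_generation(population, landscape, cfg, g, rng)
        records.append(record)
        final_table = record.table if record.table is not None else final_table
        if population is None:
            status = "extinct"
            break

    result = EpochResult(config, records, final_table, status)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_generation_log(records, out / "generations.tsv")
        if final_table is not None:
            write_snapshot_csv(final_table, out / "final_snapshot.csv")
    return result


def run_batch(
    config: EpochConfig, n_runs: int, base_seed: int | None = None
) -> list["RunSummary"]:  # noqa: F821 - see runstats
    """Independent epochs with seeds base_seed + i, summarized for cross-run stats."""
    from .runstats import summarize_run

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    base = config.seed if base_seed is None else base_seed
    summaries = []
    for i in range(n_runs):
        result = run_epoch(replace(config, seed=base + i))
        summaries.append(summarize_run(result))
    return summaries


def write_snapshot_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Final per-individual table: comma-separated, ASCII headers, LF endings."""
    frame = frame[list(SNAPSHOT_COLUMNS)]
    frame.to_csv(path, index=False, lineterminator="\n")


def read_snapshot_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(SNAPSHOT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"snapshot is missing columns: {sorted(missing)}")
    return frame


def write_generation_log(records: list[GenerationRecord], path: str | Path) -> None:
    """Per-generation summary log as tab-delimited text."""
    rows = [
        {
            "g": rec.g,
            "N": rec.n,
            "mean_m": rec.mean_m,
            "sd_m": rec.sd_m,
            "mean_alpha": rec.mean_alpha,
            "mean_delta": rec.mean_delta,
            "mean_rho": rec.mean_rho,
            "total_biomass": rec.total_biomass,
        }
        for rec in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
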