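"""Diploid four-locus genetics: codominant expression, segregation, annealed mutation.

Each individual carries two allelic values at each of four unlinked loci: the
three foraging-strategy loci alpha (two-step lookahead weight), delta
(competition tradeoff) and rho (movement threshold), plus the mate-choice
"magic trait" locus m.  Traits are expressed codominantly as the arithmetic
mean of the two alleles.  Offspring receive one allele per locus from each
parent (free recombination), after which every allele is perturbed
multiplicatively by a relative amount drawn from a symmetric uniform kernel
whose half-width anneals geometrically from 10% down to 0.1% over the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LOCI",
    "Genome",
    "MutationSchedule",
    "FounderRanges",
    "express_phenotype",
    "express_phenotypes",
    "mendelian_offspring",
    "mendelian_offspring_batch",
    "mutation_scale",
    "mutate",
    "mutate_batch",
    "founder_genomes",
]

#: Locus order used throughout; genome arrays have columns
#: (alpha1, alpha2, delta1, delta2, rho1, rho2, m1, m2).
LOCI: tuple[str, ...] = ("alpha", "delta", "rho", "m")

_M_SLICE = slice(6, 8)  # m-allele columns, bounded to [0, 1]


@dataclass(frozen=True)
class Genome:
    """Allelic values at the four diploid loci."""

    alpha1: float
    alpha2: float
    delta1: float
    delta2: float
    rho1: float
    rho2: float
    m1: float
    m2: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha1, self.alpha2, self.delta1, self.delta2,
             self.rho1, self.rho2, self.m1, self.m2]
        )

    @classmethod
    def from_array(cls, values: np.ndarray) -> "Genome":
        return cls(*(float(v) for v in np.asarray(values, dtype=float)))


@dataclass(frozen=True)
class MutationSchedule:
    """Simulated-annealing schedule for the relative mutation magnitude."""

    s_start: float = 0.10
    s_end: float = 0.001
    epoch_length: int = 250

    def __post_init__(self) -> None:
        if not (self.s_start >= self.s_end > 0):
            raise ValueError("require s_start >= s_end > 0")
        if self.epoch_length < 1:
            raise ValueError("epoch_length must be >= 1")


@dataclass(frozen=True)
class FounderRanges:
    """Uniform ranges from which founder foraging alleles are drawn.

    Founder m alleles are not drawn: they all start at exactly 0.5, so
    non-random mate choice is initially inert.
    """

    alpha: tuple[float, float] = (0.0, 1.5)
    delta: tuple[float, float] = (0.0, 2.0)
    rho: tuple[float, float] = (0.0, 1.0)
    m_init: float = 0.5


def express_phenotype(genome: Genome) -> tuple[float, float, float, float]:
    """Codominant expression: each trait is the mean of its two alleles."""
    return (
        (genome.alpha1 + genome.alpha2) / 2.0,
        (genome.delta1 + genome.delta2) / 2.0,
        (genome.rho1 + genome.rho2) / 2.0,
        (genome.m1 + genome.m2) / 2.0,
    )


def express_phenotypes(genomes: np.ndarray) -> np.ndarray:
    """Vectorized codominant expression: (N, 8) alleles -> (N, 4) traits."""
    g = np.asarray(genomes, dtype=float)
    return (g[..., 0::2] + g[..., 1::2]) / 2.0


def mendelian_offspring(
    genome_a: Genome, genome_b: Genome, rng: np.random.Generator
) -> Genome:
    """One offspring genome under Mendelian random segregation.

    At each locus independently, one allele is drawn uniformly from each
    parent's pair (loci are unlinked, i.e. free recombination).
    """
    child = mendelian_offspring_batch(
        genome_a.as_array()[None, :], genome_b.as_array()[None, :], rng
    )[0]
    return Genome.from_array(child)


def mendelian_offspring_batch(
    parents_a: np.ndarray, parents_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized segregation for paired parental genome rows (k, 8) -> (k, 8)."""
    a = np.asarray(parents_a, dtype=float)
    b = np.asarray(parents_b, dtype=float)
    k = a.shape[0]
    pick_a = rng.integers(0, 2, size=(k, 4))
    pick_b = rng.integers(0, 2, size=(k, 4))
    cols = np.arange(4) * 2
    rows = np.arange(k)[:, None]
    out = np.empty((k, 8))
    out[:, cols] = a[rows, cols + pick_a]
    out[:, cols + 1] = b[rows, cols + pick_b]
    return out


def mutation_scale(g: int, schedule: MutationSchedule) -> float:
    """Relative perturbation magnitude at generation ``g`` of the epoch.

    Geometric interpolation s(g) = s_start * (s_end/s_start)^(g/(G-1)); the
    printed endpoints (10% at g=0, 0.1% at g=G-1) are hit exactly and the
    schedule is monotone non-increasing.
    """
    G = schedule.epoch_length
    if not 0 <= g < G:
        raise ValueError(f"generation index {g} outside [0, {G})")
    if G == 1:
        return schedule.s_start
    frac = g / (G - 1)
    return float(schedule.s_start * (schedule.s_end / schedule.s_start) ** frac)


def mutate(
    genome: Genome, g: int, schedule: MutationSchedule, rng: np.random.Generator
) -> Genome:
    """Perturb every allele multiplicatively by (1 + u), u ~ U(-s(g), s(g))."""
    out = mutate_batch(genome.as_array()[None, :], g, schedule, rng)[0]
    return Genome.from_array(out)


def mutate_batch(
    genomes: np.ndarray, g: int, schedule: MutationSchedule, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized mutation of (k, 8) genome rows; bounds re-enforced by clipping.

    Foraging alleles are clipped below at 0; m alleles to [0, 1] so the mating
    deviation D = 2|m - 0.5| stays a valid probability base.
    """
    s = mutation_scale(g, schedule)
    arr = np.asarray(genomes, dtype=float)
    out = arr * (1.0 + rng.uniform(-s, s, size=arr.shape))
    np.clip(out, 0.0, None, out=out)
    np.clip(out[:, _M_SLICE], 0.0, 1.0, out=out[:, _M_SLICE])
    return out


def founder_genomes(
    n: int, rng: np.random.Generator, ranges: FounderRanges | None = None
) -> np.ndarray:
    """Founding population genomes: variable foraging alleles, m fixed at 0.5."""
    if n < 1:
        raise ValueError("need at least one founder")
    ranges = ranges or FounderRanges()
    out = np.empty((n, 8))
    for i, (lo, hi) in enumerate((ranges.alpha, ranges.delta, ranges.rho)):
        out[:, 2 * i : 2 * i + 2] = rng.uniform(lo, hi, size=(n, 2))
    out[:, _M_SLICE] = ranges.m_init
    return out
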