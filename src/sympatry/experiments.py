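"""Canned experiments: the scaled-down random vs m-trait mating comparison.

The full-scale campaigns behind the published tables ran hundreds of epochs
of 250-500 generations; the desk-scale experiment here keeps the protocol —
independent replicate epochs per mating treatment, compared on within-run
mean m with a two-tailed Mann-Whitney U test — at a reduced size: a 25x25
grid, 150 generations and >= 8 epochs per arm, which one CPU completes in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epoch import EpochConfig, run_epoch
from .landscape import EcoParams
from .runstats import BatchComparison, RunSummary, compare_arms, summarize_run

__all__ = ["ArmResults", "headline_experiment", "mtrait_survey", "derive_seeds"]


@dataclass
class ArmResults:
    """Both arms of a mating-mode comparison plus the rank test between them."""

    random: list[RunSummary]
    m_trait: list[RunSummary]
    comparison: BatchComparison

    @property
    def random_means(self) -> np.ndarray:
        return np.array([s.mean_m for s in self.random])

    @property
    def mtrait_means(self) -> np.ndarray:
        return np.array([s.mean_m for s in self.m_trait])


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Independent 31-bit epoch seeds derived from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def headline_experiment(
    base_seed: int = 0,
    n_runs: int = 8,
    generations: int = 150,
    width: int = 25,
    height: int = 25,
    eco: EcoParams | None = None,
    progress: bool = False,
) -> ArmResults:
    """Replicate epochs per arm under identical ecology, then compare arms.

    Epoch seeds are derived from ``base_seed`` (disjoint between arms), so
    the two arms are fully independent replicate sets.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs per arm")
    config = EpochConfig(
        generations=generations,
        width=width,
        height=height,
        eco=eco if eco is not None else EcoParams(),
    )
    seeds = derive_seeds(base_seed, 2 * n_runs)
    arms: dict[str, list[RunSummary]] = {"random": [], "m_trait": []}
    for a, mode in enumerate(("random", "m_trait")):
        for i in range(n_runs):
            cfg = replace(config, mode=mode, seed=seeds[a * n_runs + i])
            result = run_epoch(cfg)
            arms[mode].append(summarize_run(result))
            if progress:
                print(
                    f"{mode} run {i}: status={result.status} "
                    f"mean m={arms[mode][-1].mean_m:.3f}",
                    flush=True,
                )
    comparison = compare_arms(arms["random"], arms["m_trait"])
    return ArmResults(arms["random"], arms["m_trait"], comparison)


def mtrait_survey(
    base_seed: int = 0,
    n_runs: int = 16,
    generations: int = 150,
    width: int = 25,
    height: int = 25,
    eco: EcoParams | None = None,
) -> list[RunSummary]:
    """Additional independent m-trait epochs at the desk-scale conditions.

    Used to enlarge the sample of m-trait runs when studying conditional
    patterns (e.g. the heterozygote deficit among runs that evolved low m).
    Seeds come from a stream disjoint from ``headline_experiment``'s.
    """
    state = np.random.SeedSequence([base_seed, 104729]).generate_state(
        n_runs, dtype=np.uint32
    )
    config = EpochConfig(
        generations=generations,
        width=width,
        height=height,
        mode="m_trait",
        eco=eco if eco is not None else EcoParams(),
    )
    out = []
    for s in state:
        result = run_epoch(replace(config, seed=int(s & 0x7FFFFFFF)))
        out.append(summarize_run(result))
    return out
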