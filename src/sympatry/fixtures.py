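"""Tiny deterministic worlds for tests and demonstrations."""

from __future__ import annotations

import numpy as np

from .foraging import ForagingState
from .landscape import EcoParams, Landscape
from .population import Population

__all__ = ["FIXTURES", "make_fixture"]

FIXTURES = ("lone-forager", "two-cluster-maters", "hwe-exact")


def make_fixture(name: str):
    """Construct one of the documented deterministic scenarios.

    * ``lone-forager`` — a single agent in the middle of a uniform 5x5 world;
      by symmetry (and the stay-on-tie rule) it never moves.  Returns
      ``(ForagingState, EcoParams)``.
    * ``two-cluster-maters`` — 20 individuals in two well-separated
      (alpha, delta, rho) clusters, all with m phenotype 0.1, so every forced
      non-random choice is assortative and within-cluster.  Returns a
      ``Population``.
    * ``hwe-exact`` — a two-allele diploid genotype table at exact
      Hardy-Weinberg counts (25 AA / 50 Aa / 25 aa), so the heterozygote
      deviance is exactly zero.  Returns an (N, 2) allele-value array.
    """
    if name == "lone-forager":
        params = EcoParams()
        landscape = Landscape(5, 5, params=params)
        state = ForagingState(
            landscape=landscape,
            pos=np.array([[2, 2]]),
            biomass=np.array([1.0]),
            alpha=np.array([0.5]),
            delta=np.array([1.0]),
            rho=np.array([1.0]),
        )
        return state, params

    if name == "two-cluster-maters":
        n_per = 10
        genomes = np.zeros((2 * n_per, 8))
        # cluster A at (alpha, delta, rho) = (0.2, 0.2, 0.2); cluster B at (1.2, 1.6, 0.8)
        genomes[:n_per, 0:6] = [0.2, 0.2, 0.2, 0.2, 0.2, 0.2]
        genomes[n_per:, 0:6] = [1.2, 1.2, 1.6, 1.6, 0.8, 0.8]
        genomes[:, 6:8] = 0.1  # strongly assortative m phenotype
        biomass = 1.0 + 0.01 * np.arange(2 * n_per)
        return Population(genomes=genomes, biomass=biomass)

    if name == "hwe-exact":
        aa = np.tile([0.2, 0.2], (25, 1))
        ab = np.tile([0.2, 0.8], (50, 1))
        bb = np.tile([0.8, 0.8], (25, 1))
        return np.vstack([aa, ab, bb])

    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
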