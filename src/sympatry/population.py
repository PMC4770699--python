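"""Array-backed population container shared by the mating and epoch drivers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import express_phenotypes

__all__ = ["Population", "SNAPSHOT_COLUMNS"]

#: Column order of the per-individual snapshot table (phenotype then genotype).
SNAPSHOT_COLUMNS: tuple[str, ...] = (
    "individual", "biomass",
    "alpha", "delta", "rho", "m",
    "alpha1", "alpha2", "delta1", "delta2", "rho1", "rho2", "m1", "m2",
)


@dataclass
class Population:
    """A generation's individuals: ids, genomes, biomass and positions."""

    genomes: np.ndarray            # (N, 8) allelic values
    biomass: np.ndarray            # (N,)
    pos: np.ndarray | None = None  # (N, 2) cell coordinates, set when placed
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genomes = np.asarray(self.genomes, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.ids is None:
            self.ids = np.arange(len(self.biomass), dtype=np.int64)
        if self.genomes.shape != (len(self.biomass), 8):
            raise ValueError("genomes must have shape (N, 8)")

    @property
    def n(self) -> int:
        return len(self.biomass)

    @property
    def phenotypes(self) -> np.ndarray:
        """Expressed traits, columns (alpha, delta, rho, m)."""
        return express_phenotypes(self.genomes)

    def snapshot_frame(self) -> pd.DataFrame:
        """The per-individual table in the canonical 14-column layout."""
        phen = self.phenotypes
        data = np.column_stack([self.biomass, phen, self.genomes])
        frame = pd.DataFrame(data, columns=SNAPSHOT_COLUMNS[1:])
        frame.insert(0, "individual", self.ids)
        return frame
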