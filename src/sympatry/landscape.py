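"""Toroidal resource lattice with logistic regrowth and a below-ground refuge.

The world is a rectangular grid of resource cells with periodic (toroidal)
boundaries, so the landscape has no edges and starts perfectly homogeneous.
Each cell carries an above-ground biomass that grows logistically toward a
carrying capacity ``K`` and is depleted by foragers.  A constant below-ground
``refuge`` (root reserve) contributes to regrowth, which guarantees recovery
even after a cell has been grazed to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "EcoParams",
    "Landscape",
    "MOORE_OFFSETS",
    "TWO_STEP_OFFSETS",
    "TWO_STEP_COUNTS",
    "grow_resources",
    "extract",
    "neighborhoods",
]


# The eight movement directions (Moore neighborhood), E, NE, N, NW, W, SW, S, SE.
MOORE_OFFSETS: np.ndarray = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=np.int64,
)


def _two_step_tables() -> tuple[np.ndarray, np.ndarray]:
    """Outer-ring cells of the 5x5 neighborhood reachable via each direction.

    For direction ``d`` with one-step offset ``v``, the two-step set is every
    cell of the 16-cell outer ring (Chebyshev radius 2) that lies within one
    move of the neighbor cell ``v``: 3 cells for a cardinal direction, 5 for
    a diagonal.  Adjacent directions share corner cells; together the sets
    cover the whole outer ring.
    """
    ring = [
        (dx, dy)
        for dx in range(-2, 3)
        for dy in range(-2, 3)
        if max(abs(dx), abs(dy)) == 2
    ]
    offsets = np.zeros((8, 5, 2), dtype=np.int64)
    counts = np.zeros(8, dtype=np.int64)
    for d, (vx, vy) in enumerate(MOORE_OFFSETS):
        members = [
            (cx, cy)
            for cx, cy in ring
            if max(abs(cx - vx), abs(cy - vy)) <= 1
        ]
        counts[d] = len(members)
        for t, cell in enumerate(members):
            offsets[d, t] = cell
    return offsets, counts


TWO_STEP_OFFSETS, TWO_STEP_COUNTS = _two_step_tables()


@dataclass(frozen=True)
class EcoParams:
    """Ecological parameters of the resource and intake model.

    All quantities are per time step and in biomass units.  ``i_max``, ``h``,
    ``w`` and ``q`` parameterize the Beddington-DeAngelis style intake
    response ``i_max * R^q / (R^q + [h (1 + w C)]^q)`` where ``C`` counts
    same-cell competitors; ``q`` interpolates between scramble-like (q near 1)
    and contest-like (large q) competition.
    """

    r: float = 0.05            # logistic regrowth rate
    k: float = 5.0             # per-cell carrying capacity
    refuge: float = 0.25       # below-ground reserve feeding regrowth (0.05 K)
    i_max: float = 1.0         # maximum intake per agent per step
    h: float = 2.0             # half-saturation biomass
    w: float = 0.5             # interference weight per competitor
    q: float = 2.0             # abruptness exponent (>= 1)
    conversion: float = 0.5    # intake -> consumer biomass efficiency
    metabolic_cost: float = 0.2
    move_cost: float = 0.2
    b_floor: float = 1e-3      # consumer biomass floor (no within-generation death)
    movers_feed: bool = False  # a moving agent forfeits intake that step

    def __post_init__(self) -> None:
        numeric = {k: v for k, v in asdict(self).items() if k != "movers_feed"}
        for name, value in numeric.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"EcoParams.{name} must be finite and >= 0, got {value!r}")
        if self.q < 1:
            raise ValueError("abruptness exponent q must be >= 1")
        if not 0 < self.conversion <= 1:
            raise ValueError("conversion efficiency must lie in (0, 1]")
        if self.b_floor <= 0:
            raise ValueError("b_floor must be positive")


@dataclass
class Landscape:
    """Toroidal grid of resource cells.

    ``above_ground[x, y]`` is the edible biomass of cell (x, y); indexing
    wraps modulo the grid dimensions.  Cells all start at the same value
    (``initial``, defaulting to the carrying capacity), making the initial
    landscape structureless.
    """

    width: int = 50
    height: int = 50
    initial: float | None = None
    params: EcoParams = field(default_factory=EcoParams)
    above_ground: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.initial is None:
            self.initial = self.params.k
        if not np.isfinite(self.initial) or self.initial < 0:
            raise ValueError("initial resource level must be finite and >= 0")
        self.above_ground = np.full((self.width, self.height), float(self.initial))

    @property
    def shape(self) -> tuple[int, int]:
        return self.width, self.height

    def reset(self) -> None:
        """Restore the uniform initial state (used at each generation start)."""
        self.above_ground.fill(float(self.initial))

    def wrap(self, x: int, y: int) -> tuple[int, int]:
        return x % self.width, y % self.height

    def total(self) -> float:
        return float(self.above_ground.sum())

    def write_snapshot(self, path: str | Path, sep: str = ",") -> None:
        """Write one row per cell: x, y, above_ground (0-based coordinates)."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(sep.join(("x", "y", "above_ground")) + "\n")
            for x in range(self.width):
                for y in range(self.height):
                    fh.write(f"{x}{sep}{y}{sep}{self.above_ground[x, y]:.10g}\n")


def grow_resources(landscape: Landscape, params: EcoParams | None = None) -> Landscape:
    """Apply one step of logistic regrowth with the below-ground refuge.

    R' = R + r (R + refuge) (1 - R/K), clipped to [0, K].  The refuge term
    keeps the growth rate positive at R = 0 so fully grazed cells recover.
    """
    p = params if params is not None else landscape.params
    if not all(np.isfinite(v) for v in (p.r, p.k, p.refuge)):
        raise ValueError("non-finite regrowth parameter")
    r_grid = landscape.above_ground
    r_grid += p.r * (r_grid + p.refuge) * (1.0 - r_grid / p.k)
    np.clip(r_grid, 0.0, p.k, out=r_grid)
    return landscape


def extract(landscape: Landscape, cell: tuple[int, int], amount: float) -> Landscape:
    """Remove ``amount`` of above-ground biomass from ``cell``.

    The caller must cap demand first: extracting more than is available is a
    contract violation, not a silent clip.
    """
    x, y = landscape.wrap(*cell)
    available = landscape.above_ground[x, y]
    if amount < 0 or amount > available + 1e-12:
        raise ValueError(
            f"cannot extract {amount} from cell {cell!r} holding {available}"
        )
    landscape.above_ground[x, y] = max(0.0, available - amount)
    return landscape


def neighborhoods(
    landscape: Landscape, position: tuple[int, int]
) -> tuple[tuple[int, int], list[tuple[int, int]], list[list[tuple[int, int]]]]:
    """Self cell, the 8 Moore neighbors, and each direction's two-step cells.

    Returns ``(self_cell, neighbors, two_step_sets)`` where ``neighbors[d]``
    is the cell one move in direction ``d`` and ``two_step_sets[d]`` the
    outer-ring cells reachable in a second move continuing in that direction
    (3 for cardinal, 5 for diagonal directions), all with toroidal wrap.
    """
    x, y = landscape.wrap(*position)
    neighbors = [landscape.wrap(x + dx, y + dy) for dx, dy in MOORE_OFFSETS]
    two_step: list[list[tuple[int, int]]] = []
    for d in range(8):
        cells = [
            landscape.wrap(x + TWO_STEP_OFFSETS[d, t, 0], y + TWO_STEP_OFFSETS[d, t, 1])
            for t in range(TWO_STEP_COUNTS[d])
        ]
        two_step.append(cells)
    return (x, y), neighbors, two_step
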