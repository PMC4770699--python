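"""Within-generation ecological engine: perception, movement, intake.

One generation comprises 100 discrete time steps.  In each step agents, in a
freshly shuffled random order, evaluate their current cell and the eight
Moore directions and either stay or move one cell (paying a biomass cost);
agents that stayed then feed, with per-cell demand capped at the available
resource; finally the whole landscape regrows logistically.

The decision rules per agent with strategy phenotype (alpha, delta, rho):

* competitors of a cell are the agents that could occupy it next step, i.e.
  everyone currently in the cell or its 8 neighbors, excluding the focal
  agent itself;
* a cell's value is max(0, R - delta * C) — resource discounted linearly by
  the competition-tradeoff parameter delta;
* a direction's value is the neighbor cell's value plus alpha times the mean
  value of the outer-ring cells reachable in a second move that way; the
  current cell's weighted value analogously adds alpha times the mean value
  of its own 8 neighbors, so on a featureless landscape staying and moving
  are valued identically;
* the agent moves to the best direction iff current_value < rho * best_value;
  rho near 1 makes agents restless, rho = 0 makes them sessile.

Intake in a cell with resource R and C same-cell competitors follows a
Beddington-DeAngelis style saturating response with abruptness exponent q:
``i_max R^q / (R^q + [h (1 + w C)]^q)``.

A fast numba kernel executes the same rules for production runs; the
pure-Python path below is the readable reference and the two are tested to
agree bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import (
    EcoParams,
    Landscape,
    MOORE_OFFSETS,
    TWO_STEP_COUNTS,
    TWO_STEP_OFFSETS,
    grow_resources,
)

__all__ = [
    "Phenotype",
    "Agent",
    "ForagingState",
    "competitor_count",
    "cell_value",
    "direction_value",
    "current_cell_value",
    "movement_decision",
    "intake",
    "ecological_step",
]


@dataclass(frozen=True)
class Phenotype:
    """Expressed (codominant) trait values of one agent."""

    alpha: float
    delta: float
    rho: float
    m: float

    def __post_init__(self) -> None:
        vals = (self.alpha, self.delta, self.rho, self.m)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("phenotype values must be finite")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m phenotype must lie in [0, 1]")


@dataclass
class Agent:
    """One forager: identity, location, biomass and strategy."""

    id: int
    position: tuple[int, int]
    biomass: float
    genome: np.ndarray  # 8 allelic values
    phenotype: Phenotype


@dataclass
class ForagingState:
    """Array-of-fields state of one within-generation simulation."""

    landscape: Landscape
    pos: np.ndarray        # (N, 2) int cell coordinates
    biomass: np.ndarray    # (N,) float
    alpha: np.ndarray
    delta: np.ndarray
    rho: np.ndarray
    occ: np.ndarray = field(init=False)   # per-cell occupant counts
    o3: np.ndarray = field(init=False)    # occupants within each cell's 3x3 block
    moved: np.ndarray = field(init=False)  # which agents moved last step

    def __post_init__(self) -> None:
        w, h = self.landscape.shape
        self.pos = np.asarray(self.pos, dtype=np.int64).reshape(-1, 2) % [w, h]
        self.biomass = np.asarray(self.biomass, dtype=float).copy()
        self.occ = np.zeros((w, h), dtype=np.int64)
        np.add.at(self.occ, (self.pos[:, 0], self.pos[:, 1]), 1)
        self.o3 = _occupancy_3x3(self.occ)
        self.moved = np.zeros(len(self.biomass), dtype=np.bool_)

    @property
    def n(self) -> int:
        return self.pos.shape[0]


def _occupancy_3x3(occ: np.ndarray) -> np.ndarray:
    """Toroidal 3x3 box sum of the occupancy grid."""
    out = np.zeros_like(occ)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            out += np.roll(np.roll(occ, dx, axis=0), dy, axis=1)
    return out


def competitor_count(
    state: ForagingState, cell: tuple[int, int], focal: int | None = None
) -> int:
    """Agents able to occupy ``cell`` next step (its 3x3 block), excluding focal.

    The focal agent is subtracted only if it currently sits within one move of
    the cell — i.e. it could itself be there next step.
    """
    x, y = state.landscape.wrap(*cell)
    count = int(state.o3[x, y])
    if focal is not None:
        fx, fy = state.pos[focal]
        w, h = state.landscape.shape
        dx = min((fx - x) % w, (x - fx) % w)
        dy = min((fy - y) % h, (y - fy) % h)
        if max(dx, dy) <= 1:
            count -= 1
    return count


def cell_value(R: float, C: float, delta: float) -> float:
    """Weighted worth of a cell: resource minus delta per competitor, floored at 0."""
    if R < 0 or C < 0 or delta < 0:
        raise ValueError("cell_value arguments must be non-negative")
    return max(0.0, R - delta * C)


def direction_value(
    state: ForagingState, focal: int, direction: int, alpha: float, delta: float
) -> float:
    """Value of moving one cell in ``direction``: neighbor value plus the
    alpha-discounted mean value of that direction's two-step cells."""
    x, y = state.pos[focal]
    grid = state.landscape.above_ground
    w, h = state.landscape.shape
    dx, dy = MOORE_OFFSETS[direction]
    nx, ny = (x + dx) % w, (y + dy) % h
    v1 = cell_value(grid[nx, ny], competitor_count(state, (nx, ny), focal), delta)
    total = 0.0
    cnt = int(TWO_STEP_COUNTS[direction])
    for t in range(cnt):
        tx = (x + TWO_STEP_OFFSETS[direction, t, 0]) % w
        ty = (y + TWO_STEP_OFFSETS[direction, t, 1]) % h
        total += cell_value(grid[tx, ty], competitor_count(state, (tx, ty), focal), delta)
    return v1 + alpha * total / cnt


def current_cell_value(state: ForagingState, focal: int, alpha: float, delta: float) -> float:
    """Weighted value of staying put: own cell plus alpha-discounted mean of
    its 8 neighbors (the cells reachable two steps ahead when staying)."""
    x, y = state.pos[focal]
    grid = state.landscape.above_ground
    w, h = state.landscape.shape
    v0 = cell_value(grid[x, y], competitor_count(state, (x, y), focal), delta)
    total = 0.0
    for dx, dy in MOORE_OFFSETS:
        nx, ny = (x + dx) % w, (y + dy) % h
        total += cell_value(grid[nx, ny], competitor_count(state, (nx, ny), focal), delta)
    return v0 + alpha * total / 8.0


def movement_decision(
    current_value: float,
    direction_values: np.ndarray,
    rho: float,
    tie_u: float,
) -> int:
    """Stay (-1) or the chosen best direction (0..7).

    Moves iff current_value < rho * best; equality stays.  Ties among
    equally-best directions are broken uniformly via ``tie_u`` in [0, 1).
    """
    vals = np.asarray(direction_values, dtype=float)
    best = float(vals.max())
    if not current_value < rho * best:
        return -1
    ties = np.flatnonzero(vals == best)
    return int(ties[min(int(tie_u * len(ties)), len(ties) - 1)])


def intake(R: float, C: float, params: EcoParams) -> float:
    """Per-step intake demand under interference competition.

    ``i_max R^q / (R^q + [h (1 + w C)]^q)``; increasing and saturating in the
    resource R, decreasing in the number of same-cell competitors C.
    """
    if R <= 0:
        return 0.0
    denom_scale = params.h * (1.0 + params.w * C)
    rq = R ** params.q
    return params.i_max * rq / (rq + denom_scale ** params.q)


def _step_python(
    state: ForagingState,
    params: EcoParams,
    perm: np.ndarray,
    tie_u: np.ndarray,
) -> float:
    """Reference implementation of one ecological step; returns total extraction."""
    grid = state.landscape.above_ground
    w, h = state.landscape.shape
    state.moved[:] = False

    # movement phase: sequential, in this step's shuffled order
    for i in perm:
        a, d, rho = state.alpha[i], state.delta[i], state.rho[i]
        v_cur = current_cell_value(state, i, a, d)
        dir_vals = np.array(
            [direction_value(state, i, dd, a, d) for dd in range(8)]
        )
        choice = movement_decision(v_cur, dir_vals, rho, tie_u[i])
        if choice >= 0:
            x, y = state.pos[i]
            nx = (x + MOORE_OFFSETS[choice, 0]) % w
            ny = (y + MOORE_OFFSETS[choice, 1]) % h
            state.occ[x, y] -= 1
            state.occ[nx, ny] += 1
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    state.o3[(x + dx) % w, (y + dy) % h] -= 1
                    state.o3[(nx + dx) % w, (ny + dy) % h] += 1
            state.pos[i] = nx, ny
            state.biomass[i] -= params.move_cost
            state.moved[i] = True

    # feeding phase: per-cell demand capped at what the cell holds
    feeds = np.ones(state.n, dtype=bool) if params.movers_feed else ~state.moved
    demand = np.zeros((w, h))
    want = np.zeros(state.n)
    for i in range(state.n):
        if feeds[i]:
            x, y = state.pos[i]
            want[i] = intake(grid[x, y], state.occ[x, y] - 1, params)
            demand[x, y] += want[i]
    extracted_total = 0.0
    eaten = np.zeros(state.n)
    for i in range(state.n):
        if feeds[i] and want[i] > 0:
            x, y = state.pos[i]
            scale = 1.0 if demand[x, y] <= grid[x, y] else grid[x, y] / demand[x, y]
            eaten[i] = want[i] * scale
    taken = np.minimum(demand, grid)
    extracted_total = float(taken.sum())
    grid -= taken

    state.biomass += params.conversion * eaten - params.metabolic_cost
    np.maximum(state.biomass, params.b_floor, out=state.biomass)

    grow_resources(state.landscape, params)
    return extracted_total


def ecological_step(
    state: ForagingState,
    params: EcoParams,
    rng: np.random.Generator,
    kernel: bool = True,
) -> float:
    """Advance the world one time step; returns total biomass extracted.

    Both execution paths consume exactly the same random draws (one
    permutation plus one tie-break uniform per agent), so trajectories are
    reproducible by seed and identical across paths.
    """
    perm = rng.permutation(state.n)
    tie_u = rng.random(state.n)
    if not kernel:
        return _step_python(state, params, perm, tie_u)
    from ._kernels import step_kernel

    extracted = step_kernel(
        state.landscape.above_ground,
        params.r, params.k, params.refuge,
        params.i_max, params.h, params.w, params.q,
        params.conversion, params.metabolic_cost, params.move_cost,
        params.b_floor, params.movers_feed,
        state.pos, state.biomass, state.alpha, state.delta, state.rho,
        state.occ, state.o3, state.moved,
        perm, tie_u,
        MOORE_OFFSETS, TWO_STEP_OFFSETS, TWO_STEP_COUNTS,
    )
    return float(extracted)
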