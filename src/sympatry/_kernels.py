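"""Numba kernel for the within-generation ecological step.

Mirrors ``foraging._step_python`` operation-for-operation (same arithmetic
order, same RNG consumption) so the two paths produce bit-identical
trajectories; the agreement is asserted by the test suite.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def step_kernel(
    grid,
    r, k, refuge,
    i_max, h_half, w_int, q,
    conversion, metabolic_cost, move_cost,
    b_floor, movers_feed,
    pos, biomass, alpha, delta, rho,
    occ, o3, moved,
    perm, tie_u,
    moore, two_off, two_cnt,
):  # pragma: no cover - exercised via foraging.ecological_step
    w, h = grid.shape
    n = pos.shape[0]
    for i in range(n):
        moved[i] = False

    # ---- movement phase (sequential, shuffled order) ----
    vals = np.empty(8)
    for pi in range(n):
        i = perm[pi]
        a = alpha[i]
        d = delta[i]
        x = pos[i, 0]
        y = pos[i, 1]

        # current cell's weighted value
        c0 = o3[x, y] - 1
        v0 = grid[x, y] - d * c0
        if v0 < 0.0:
            v0 = 0.0
        total = 0.0
        for dd in range(8):
            nx = (x + moore[dd, 0]) % w
            ny = (y + moore[dd, 1]) % h
            c = o3[nx, ny] - 1
            v = grid[nx, ny] - d * c
            if v < 0.0:
                v = 0.0
            total += v
        v_cur = v0 + a * total / 8.0

        # the eight direction values
        for dd in range(8):
            nx = (x + moore[dd, 0]) % w
            ny = (y + moore[dd, 1]) % h
            c = o3[nx, ny] - 1
            v1 = grid[nx, ny] - d * c
            if v1 < 0.0:
                v1 = 0.0
            cnt = two_cnt[dd]
            tsum = 0.0
            for t in range(cnt):
                tx = (x + two_off[dd, t, 0]) % w
                ty = (y + two_off[dd, t, 1]) % h
                c2 = o3[tx, ty]  # focal is two cells away: not a competitor there
                v2 = grid[tx, ty] - d * c2
                if v2 < 0.0:
                    v2 = 0.0
                tsum += v2
            vals[dd] = v1 + a * tsum / cnt

        best = vals[0]
        for dd in range(1, 8):
            if vals[dd] > best:
                best = vals[dd]

        if v_cur < rho[i] * best:
            nties = 0
            for dd in range(8):
                if vals[dd] == best:
                    nties += 1
            pick = int(tie_u[i] * nties)
            if pick > nties - 1:
                pick = nties - 1
            choice = -1
            seen = 0
            for dd in range(8):
                if vals[dd] == best:
                    if seen == pick:
                        choice = dd
                        break
                    seen += 1
            nx = (x + moore[choice, 0]) % w
            ny = (y + moore[choice, 1]) % h
            occ[x, y] -= 1
            occ[nx, ny] += 1
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    o3[(x + dx) % w, (y + dy) % h] -= 1
                    o3[(nx + dx) % w, (ny + dy) % h] += 1
            pos[i, 0] = nx
            pos[i, 1] = ny
            biomass[i] -= move_cost
            moved[i] = True

    # ---- feeding phase ----
    demand = np.zeros((w, h))
    want = np.zeros(n)
    for i in range(n):
        feeds = movers_feed or (not moved[i])
        if feeds:
            x = pos[i, 0]
            y = pos[i, 1]
            res = grid[x, y]
            if res > 0.0:
                c = occ[x, y] - 1
                scale = h_half * (1.0 + w_int * c)
                rq = res ** q
                want[i] = i_max * rq / (rq + scale ** q)
                demand[x, y] += want[i]

    eaten = np.zeros(n)
    for i in range(n):
        if want[i] > 0.0:
            x = pos[i, 0]
            y = pos[i, 1]
            if demand[x, y] <= grid[x, y]:
                eaten[i] = want[i]
            else:
                eaten[i] = want[i] * (grid[x, y] / demand[x, y])

    extracted = 0.0
    for x in range(w):
        for y in range(h):
            taken = demand[x, y]
            if taken > grid[x, y]:
                taken = grid[x, y]
            grid[x, y] -= taken
            extracted += taken

    for i in range(n):
        biomass[i] += conversion * eaten[i] - metabolic_cost
        if biomass[i] < b_floor:
            biomass[i] = b_floor

    # ---- logistic regrowth with refuge ----
    for x in range(w):
        for y in range(h):
            rg = grid[x, y]
            rg = rg + r * (rg + refuge) * (1.0 - rg / k)
            if rg < 0.0:
                rg = 0.0
            elif rg > k:
                rg = k
            grid[x, y] = rg

    return extracted
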