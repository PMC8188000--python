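"""Independent brute-force settlement simulator used as a test oracle.

A deliberately naive re-implementation of the settlement rules over plain
Python dicts and sets: no occupancy grids, no component labelling, no
caching.  It consumes random draws through the same documented protocol as
the engine (row-major candidate ordering, one ``integers`` draw per roost
and per forage seed), so with equal seeds it must reproduce the engine's
claims pixel for pixel.  Kept free of any engine internals.
"""

from __future__ import annotations

import math

import numpy as np

# resource codes (mirrors the package constants by value, on purpose)
OTHER, WOODLAND, ROUGH, MEADOW, WATER = 0, 1, 2, 3, 4


def _row_major(pixels):
    return sorted(pixels, key=lambda p: (p[1], p[0]))


def _neighbours(c, r, n_cols, n_rows, connectivity):
    if connectivity == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for dc, dr in offs:
        nc, nr = c + dc, r + dr
        if 0 <= nc < n_cols and 0 <= nr < n_rows:
            yield nc, nr


def _flood(grid, owned, start, code, connectivity):
    """Connected component of free `code` pixels containing start (BFS)."""
    n_rows, n_cols = grid.shape
    comp = {start}
    queue = [start]
    while queue:
        c, r = queue.pop(0)
        for nc, nr in _neighbours(c, r, n_cols, n_rows, connectivity):
            if (nc, nr) not in comp and grid[nr, nc] == code and (nc, nr) not in owned:
                comp.add((nc, nr))
                queue.append((nc, nr))
    return comp


def simulate_oracle(grid, pixel_size, params, seed):
    """Run the full settlement process by brute force.

    ``params`` is any object with the five requirement/distance attributes
    plus ``connectivity``.  Returns (birds, owned, tried) where birds is a
    list of dicts with keys roost / rgr / mead.
    """
    grid = np.asarray(grid)
    n_rows, n_cols = grid.shape
    rng = np.random.default_rng(seed)
    pixel_area = (pixel_size / 100.0) ** 2
    owned: dict[tuple[int, int], int] = {}
    tried: set[tuple[int, int]] = set()
    birds = []
    bird_id = 0
    while True:
        roost_candidates = _row_major(
            (c, r)
            for r in range(n_rows)
            for c in range(n_cols)
            if grid[r, c] == WOODLAND and (c, r) not in owned and (c, r) not in tried
        )
        if not roost_candidates:
            break
        roost = roost_candidates[int(rng.integers(len(roost_candidates)))]
        owned[roost] = bird_id
        mine: dict[int, set] = {ROUGH: set(), MEADOW: set()}
        ok = True
        for code, req_ha, dist_m in (
            (ROUGH, params.rgr_area_ha, params.rgr_dist_m),
            (MEADOW, params.mead_area_ha, params.mead_dist_m),
        ):
            rad_px = dist_m / pixel_size
            while True:
                if len(mine[code]) * pixel_area >= req_ha:
                    break
                cands = _row_major(
                    (c, r)
                    for r in range(n_rows)
                    for c in range(n_cols)
                    if grid[r, c] == code
                    and (c, r) not in owned
                    and (c - roost[0]) ** 2 + (r - roost[1]) ** 2 <= rad_px**2
                )
                if not cands:
                    ok = False
                    break
                seed_px = cands[int(rng.integers(len(cands)))]
                comp = _flood(grid, owned, seed_px, code, params.connectivity)
                for p in comp:
                    owned[p] = bird_id
                mine[code] |= comp
            if not ok:
                break
        if ok:
            birds.append({"roost": roost, "rgr": frozenset(mine[ROUGH]),
                          "mead": frozenset(mine[MEADOW])})
            bird_id += 1
        else:
            for p in mine[ROUGH] | mine[MEADOW]:
                del owned[p]
            del owned[roost]
            tried.add(roost)
    return birds, owned, tried
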