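"""Synthetic landscape generation.

The land-cover raster the model was built for (a 25 m categorical map of
lowland UK) is not distributable, so tests, examples and the acceptance
pipeline run on synthetic rasters that emulate its structure: scattered
woodland copses, small rough-ground patches and meadow fields whose sizes
span sub-viable slivers to fields well above the 20 ha economic-conversion
threshold, embedded in non-resource "other" land.

Two generator modes exist:

* **explicit territory kits** — each kit is one woodland roost pixel plus a
  rough-ground patch and a meadow patch of stated pixel counts placed within
  stated radii of the roost.  Kits separated by more than twice the meadow
  search distance are mutually unreachable, so a kit landscape with K viable
  kits supports exactly K territories; this gives constructions with known
  ground truth.
* **stochastic landscapes** — patches of each resource are grown from random
  seeds until target cover fractions are met, with patch sizes drawn
  log-uniformly between per-resource bounds.

Both modes are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from buteo_abm.landscape import InvalidInputError, Resource, ResourceMap


class PlacementError(RuntimeError):
    """Raised when a kit specification cannot be placed in the world."""


@dataclass
class TerritoryKit:
    """One roost-centred resource kit.

    Defaults make the kit *exactly* viable under the default simulation
    parameters at 25 m pixels: 9 rough-ground pixels = 0.5625 ha >= 0.56 ha
    and 216 meadow pixels = 13.5 ha.
    """

    roost: tuple[int, int] | None = None  # (col, row); None = auto-place
    rough_pixels: int = 9
    rough_radius_m: float = 500.0
    meadow_pixels: int = 216
    meadow_radius_m: float = 1200.0


@dataclass
class KitLandscapeSpec:
    """World of explicitly placed territory kits on an "other" background."""

    n_cols: int
    n_rows: int
    kits: list[TerritoryKit] = field(default_factory=list)
    pixel_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)
    min_gap_m: float = 2500.0  # > 2 x default mead_dist: kits mutually unreachable
    background: Resource = Resource.OTHER


@dataclass
class StochasticLandscapeSpec:
    """Randomly structured landscape with target cover fractions.

    Cover fractions are targets, reached to within one patch.  Patch areas
    are drawn log-uniformly between the stated bounds (ha); meadow bounds
    deliberately straddle the 20 ha conversion threshold.
    """

    n_cols: int
    n_rows: int
    pixel_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)
    woodland_fraction: float = 0.12
    rough_fraction: float = 0.08
    meadow_fraction: float = 0.30
    woodland_patch_ha: tuple[float, float] = (0.25, 8.0)
    rough_patch_ha: tuple[float, float] = (0.25, 2.0)
    meadow_patch_ha: tuple[float, float] = (1.0, 45.0)


def _grow_blob(
    occupied: np.ndarray,
    start: tuple[int, int],
    n_pixels: int,
    rng: np.random.Generator,
    centre: tuple[int, int] | None = None,
    radius_px: float | None = None,
) -> list[tuple[int, int]] | None:
    """Grow a connected blob of ``n_pixels`` free cells from ``start``.

    Randomized breadth-first growth; when a centre/radius is given, growth
    never leaves the disc.  Returns None if the blob cannot reach the target
    size (caller may retry elsewhere).
    """
    n_rows, n_cols = occupied.shape
    c0, r0 = start
    if occupied[r0, c0]:
        return None

    def in_disc(c: int, r: int) -> bool:
        if radius_px is None:
            return True
        cc, cr = centre  # type: ignore[misc]
        return math.hypot(c - cc, r - cr) <= radius_px

    if not in_disc(c0, r0):
        return None
    blob = [(c0, r0)]
    member = {(c0, r0)}
    frontier = [(c0, r0)]
    while len(blob) < n_pixels and frontier:
        i = int(rng.integers(len(frontier)))
        c, r = frontier[i]
        nbrs = [
            (c + dc, r + dr)
            for dc in (-1, 0, 1)
            for dr in (-1, 0, 1)
            if not (dc == 0 and dr == 0)
        ]
        rng.shuffle(nbrs)
        grew = False
        for nc, nr in nbrs:
            if 0 <= nc < n_cols and 0 <= nr < n_rows and (nc, nr) not in member:
                if not occupied[nr, nc] and in_disc(nc, nr):
                    blob.append((nc, nr))
                    member.add((nc, nr))
                    frontier.append((nc, nr))
                    grew = True
                    if len(blob) >= n_pixels:
                        break
        if not grew:
            frontier.pop(i)
    if len(blob) < n_pixels:
        return None
    return blob


def _auto_roosts(spec: KitLandscapeSpec) -> list[tuple[int, int]]:
    """Deterministic lattice of roost positions honouring radii and gap."""
    px = spec.pixel_size
    r_max = max((max(k.rough_radius_m, k.meadow_radius_m) for k in spec.kits), default=0.0)
    pitch_m = spec.min_gap_m + 2.0 * r_max
    pitch = int(math.ceil(pitch_m / px)) + 1
    margin = int(math.ceil(r_max / px)) + 1
    cols = list(range(margin, spec.n_cols - margin, pitch))
    rows = list(range(margin, spec.n_rows - margin, pitch))
    slots = [(c, r) for r in rows for c in cols]
    if len(slots) < len(spec.kits):
        raise PlacementError(
            f"world {spec.n_cols}x{spec.n_rows} px fits only {len(slots)} kits "
            f"at gap {spec.min_gap_m} m; {len(spec.kits)} requested"
        )
    return slots[: len(spec.kits)]


def _generate_kits(spec: KitLandscapeSpec, rng: np.random.Generator) -> ResourceMap:
    grid = np.full((spec.n_rows, spec.n_cols), int(spec.background), dtype=np.int8)
    occupied = np.zeros_like(grid, dtype=bool)
    auto = _auto_roosts(spec) if any(k.roost is None for k in spec.kits) else []
    auto_i = 0
    for kit in spec.kits:
        if kit.roost is None:
            roost = auto[auto_i]
            auto_i += 1
        else:
            roost = kit.roost
        c, r = roost
        if not (0 <= c < spec.n_cols and 0 <= r < spec.n_rows) or occupied[r, c]:
            raise PlacementError(f"roost {roost} outside world or occupied")
        grid[r, c] = int(Resource.WOODLAND)
        occupied[r, c] = True
        for n_px, radius_m, code in (
            (kit.rough_pixels, kit.rough_radius_m, Resource.ROUGH),
            (kit.meadow_pixels, kit.meadow_radius_m, Resource.MEADOW),
        ):
            if n_px <= 0:
                continue
            radius_px = radius_m / spec.pixel_size
            blob = None
            for _ in range(200):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(1.0, max(1.5, radius_px * 0.5))
                start = (int(round(c + rad * math.cos(ang))), int(round(r + rad * math.sin(ang))))
                if not (0 <= start[0] < spec.n_cols and 0 <= start[1] < spec.n_rows):
                    continue
                blob = _grow_blob(occupied, start, n_px, rng, centre=roost, radius_px=radius_px)
                if blob is not None:
                    break
            if blob is None:
                raise PlacementError(
                    f"could not place {n_px} {code.name} pixels within "
                    f"{radius_m} m of roost {roost}"
                )
            for bc, br in blob:
                grid[br, bc] = int(code)
                occupied[br, bc] = True
    return ResourceMap(grid, pixel_size=spec.pixel_size, origin=spec.origin)


def _generate_stochastic(spec: StochasticLandscapeSpec, rng: np.random.Generator) -> ResourceMap:
    grid = np.full((spec.n_rows, spec.n_cols), int(Resource.OTHER), dtype=np.int8)
    occupied = np.zeros_like(grid, dtype=bool)
    pixel_area_ha = (spec.pixel_size / 100.0) ** 2
    total = grid.size
    # Meadow first: large fields need contiguous room.
    plan = [
        (Resource.MEADOW, spec.meadow_fraction, spec.meadow_patch_ha),
        (Resource.WOODLAND, spec.woodland_fraction, spec.woodland_patch_ha),
        (Resource.ROUGH, spec.rough_fraction, spec.rough_patch_ha),
    ]
    for code, fraction, (lo_ha, hi_ha) in plan:
        if fraction <= 0:
            continue
        target_px = int(round(fraction * total))
        placed = 0
        failures = 0
        while placed < target_px and failures < 500:
            size_ha = math.exp(rng.uniform(math.log(lo_ha), math.log(hi_ha)))
            n_px = max(1, int(round(size_ha / pixel_area_ha)))
            n_px = min(n_px, target_px - placed + n_px // 4)  # mild overshoot allowed
            start = (int(rng.integers(spec.n_cols)), int(rng.integers(spec.n_rows)))
            blob = _grow_blob(occupied, start, n_px, rng)
            if blob is None:
                failures += 1
                continue
            for bc, br in blob:
                grid[br, bc] = int(code)
                occupied[br, bc] = True
            placed += len(blob)
    return ResourceMap(grid, pixel_size=spec.pixel_size, origin=spec.origin)


def kit_landscape(
    n_kits: int,
    seed: int = 0,
    kit: TerritoryKit | None = None,
    pixel_size: float = 25.0,
    min_gap_m: float = 2500.0,
) -> ResourceMap:
    """Convenience constructor: the smallest near-square world holding
    ``n_kits`` identical auto-placed kits at the required separation."""
    kit = kit or TerritoryKit()
    r_max_px = max(kit.rough_radius_m, kit.meadow_radius_m) / pixel_size
    pitch = int(math.ceil((min_gap_m + 2 * max(kit.rough_radius_m, kit.meadow_radius_m)) / pixel_size)) + 1
    margin = int(math.ceil(r_max_px)) + 1
    if n_kits == 0:
        spec = KitLandscapeSpec(n_cols=50, n_rows=50, kits=[], pixel_size=pixel_size)
        return generate_synthetic_landscape(spec, seed)
    n_x = int(math.ceil(math.sqrt(n_kits)))
    n_y = int(math.ceil(n_kits / n_x))
    n_cols = 2 * margin + (n_x - 1) * pitch + 2
    n_rows = 2 * margin + (n_y - 1) * pitch + 2
    spec = KitLandscapeSpec(
        n_cols=n_cols, n_rows=n_rows, kits=[kit] * n_kits,
        pixel_size=pixel_size, min_gap_m=min_gap_m,
    )
    return generate_synthetic_landscape(spec, seed)


def generate_synthetic_landscape(
    spec: KitLandscapeSpec | StochasticLandscapeSpec, seed: int
) -> ResourceMap:
    """Generate a synthetic resource map; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    if isinstance(spec, KitLandscapeSpec):
        return _generate_kits(spec, rng)
    if isinstance(spec, StochasticLandscapeSpec):
        return _generate_stochastic(spec, rng)
    raise InvalidInputError(f"unknown landscape spec type: {type(spec).__name__}")
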