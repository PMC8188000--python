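"""The territory-settlement engine.

Sequential virtual buzzards colonize the resource map.  Each bird:

1. draws a roost uniformly at random among the free, untried woodland pixels
   and defends it;
2. acquires rough-ground: repeatedly draws a *seed* pixel uniformly among
   the free rough-ground pixels whose centres lie within ``rgr_dist_m`` of
   the roost centre, and claims the entire connected component of free
   rough-ground containing the seed (the claim may extend beyond the search
   distance — only the seed is distance-constrained), until the defended
   rough-ground area reaches ``rgr_area_ha`` or no eligible seed remains;
3. acquires meadow the same way with ``mead_area_ha`` / ``mead_dist_m``.

A bird that cannot meet a requirement emigrates: every pixel it defended is
released except its roost pixel, which is permanently marked *tried* so that
no later bird wastes the same roost — this blocking is what guarantees the
run terminates.  The run stops when no free, untried woodland pixel remains;
the surviving set of territories is the model's prediction of maximum
distribution and abundance.

RNG protocol (one ``numpy`` Generator per run, relied on by the
brute-force oracle in the test suite):

* every candidate list (roost pixels, forage seed pixels) is ordered
  row-major, i.e. sorted by ``(row, col)``;
* one ``rng.integers(len(candidates))`` draw selects each roost and each
  forage seed; no other draws are consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from buteo_abm.landscape import (
    InvalidInputError,
    Resource,
    ResourceMap,
    StudyMask,
    _structure,
    full_mask,
)

log = logging.getLogger(__name__)

_FREE = -1  # owner value of an unclaimed pixel


@dataclass
class SimulationParams:
    """Resource-area requirements and forage search distances.

    Defaults are the field-estimated values for pre-breeding common buzzards
    in lowland UK at 25 m pixels: a one-pixel roost (0.06 ha), 0.56 ha of
    rough-ground found within 500 m of the roost, and 13.5 ha of meadow
    found within 1200 m.
    """

    roost_area_ha: float = 0.06
    rgr_area_ha: float = 0.56
    rgr_dist_m: float = 500.0
    mead_area_ha: float = 13.5
    mead_dist_m: float = 1200.0
    connectivity: int = 8
    #: claim whole patches (overshoot allowed); False stops a claim mid-patch
    whole_patch: bool = True

    def __post_init__(self) -> None:
        for name in ("roost_area_ha", "rgr_area_ha", "rgr_dist_m", "mead_area_ha", "mead_dist_m"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "SimulationParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class RunConfig:
    """Seeding of one run; with ``seed_on`` the run is fully deterministic."""

    seed: int = 0
    seed_on: bool = True


@dataclass
class Claim:
    """One atomic patch claim: which seed started it and what it took."""

    resource: Resource
    seed_pixel: tuple[int, int]
    cols: np.ndarray
    rows: np.ndarray

    @property
    def pixels(self) -> frozenset[tuple[int, int]]:
        return frozenset(zip(self.cols.tolist(), self.rows.tolist()))

    def __len__(self) -> int:
        return len(self.cols)


@dataclass
class Buzzard:
    """A settled bird: roost pixel, defended pixel sets and territory coordinates."""

    name: int
    my_roost: tuple[int, int]
    my_rgr: set[tuple[int, int]] = field(default_factory=set)
    my_mead: set[tuple[int, int]] = field(default_factory=set)
    X: list[float] = field(default_factory=list)
    Y: list[float] = field(default_factory=list)
    claims: list[Claim] = field(default_factory=list)
    #: full defended roost patch; {my_roost} unless roost_area_ha > one pixel
    roost_patch: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.roost_patch:
            self.roost_patch = {self.my_roost}

    @property
    def territory_pixels(self) -> set[tuple[int, int]]:
        return self.roost_patch | self.my_rgr | self.my_mead

    def locations(self) -> np.ndarray:
        """Territory pixel centres as an (n, 2) eastings/northings array."""
        return np.column_stack([self.X, self.Y])


class WorldState:
    """Mutable per-pixel occupancy state over a resource map.

    Tracks, per pixel, whether it is free or defended (``owner``) and — for
    woodland — whether it has been used up as a roost attempt (``tried``).
    Free connected components of each forage resource are pre-labelled; while
    claims stay whole-patch (the default), a component is claimed atomically,
    so the labels stay exact and a claim is a label lookup.  Partial claims
    fall back to breadth-first flood fill over free pixels only.
    """

    def __init__(self, rmap: ResourceMap, connectivity: int = 8) -> None:
        self.rmap = rmap
        self.connectivity = connectivity
        self.resource = rmap.grid
        self.owner = np.full(rmap.grid.shape, _FREE, dtype=np.int32)
        self.tried = np.zeros(rmap.grid.shape, dtype=bool)
        self._structure = _structure(connectivity)
        self._labels: dict[Resource, np.ndarray] = {}
        self._label_cols: dict[Resource, list[np.ndarray]] = {}
        self._label_rows: dict[Resource, list[np.ndarray]] = {}
        self._label_free: dict[Resource, np.ndarray] = {}
        for res in (Resource.ROUGH, Resource.MEADOW):
            labels, n = ndimage.label(self.resource == int(res), structure=self._structure)
            self._labels[res] = labels
            rows, cols = np.nonzero(labels)
            labs = labels[rows, cols]
            order = np.argsort(labs, kind="stable")
            rows, cols, labs = rows[order], cols[order], labs[order]
            bounds = np.searchsorted(labs, np.arange(1, n + 2))
            col_lists, row_lists = [np.empty(0, int)], [np.empty(0, int)]
            for k in range(n):
                lo, hi = bounds[k], bounds[k + 1]
                col_lists.append(cols[lo:hi])
                row_lists.append(rows[lo:hi])
            self._label_cols[res] = col_lists
            self._label_rows[res] = row_lists
            self._label_free[res] = np.array([len(p) for p in col_lists], dtype=np.int64)
        self._wood_cache: list[tuple[int, int]] | None = None
        self._wood_dirty = True

    # -- bookkeeping -------------------------------------------------------

    def is_free(self, col: int, row: int) -> bool:
        return self.owner[row, col] == _FREE

    def _pixel_arrays(self, pixels) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(list(pixels), dtype=np.intp).reshape(-1, 2)
        return arr[:, 0], arr[:, 1]  # cols, rows

    def claim_pixels(self, pixels, bird_id: int) -> None:
        if not pixels:
            return
        cols, rows = self._pixel_arrays(pixels)
        if (self.owner[rows, cols] != _FREE).any():
            raise InvalidInputError("claim includes already-defended pixels")
        self.owner[rows, cols] = bird_id
        self._adjust_free(cols, rows, -1)

    def release_pixels(self, pixels) -> None:
        if not pixels:
            return
        cols, rows = self._pixel_arrays(pixels)
        self.release_arrays(cols, rows)

    def release_arrays(self, cols: np.ndarray, rows: np.ndarray) -> None:
        self.owner[rows, cols] = _FREE
        self._adjust_free(cols, rows, +1)

    def _adjust_free(self, cols: np.ndarray, rows: np.ndarray, sign: int) -> None:
        res_arr = self.resource[rows, cols]
        for res in self._labels:
            sel = res_arr == int(res)
            if sel.any():
                labs = self._labels[res][rows[sel], cols[sel]]
                np.add.at(self._label_free[res], labs, sign)
        if (res_arr == int(Resource.WOODLAND)).any():
            self._wood_dirty = True

    def free_untried_woodland(self) -> list[tuple[int, int]]:
        """Row-major list of woodland pixels that are free and not yet tried.

        Cached between settlement attempts; the cache is invalidated whenever
        a woodland pixel changes hands and maintained in place when a roost
        is consumed (:meth:`take_roost` / :meth:`fail_roost`), which keeps
        the list identical to a full recomputation at every draw.
        """
        if self._wood_dirty or self._wood_cache is None:
            mask = (self.resource == int(Resource.WOODLAND)) & (self.owner == _FREE) & ~self.tried
            rows, cols = np.nonzero(mask)
            self._wood_cache = list(zip(cols.tolist(), rows.tolist()))
            self._wood_dirty = False
        return self._wood_cache

    def take_roost(self, index: int, bird_id: int) -> tuple[int, int]:
        """Claim the cached roost candidate at ``index`` without invalidating
        the candidate cache (the pixel is simply removed from it)."""
        assert self._wood_cache is not None and not self._wood_dirty
        c, r = self._wood_cache.pop(index)
        self.owner[r, c] = bird_id
        return (c, r)

    def fail_roost(self, roost: tuple[int, int]) -> None:
        """Release a failed roost and permanently mark it tried."""
        c, r = roost
        self.owner[r, c] = _FREE
        self.tried[r, c] = True

    def free_seeds_within(
        self, resource: Resource, roost: tuple[int, int], dist_m: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Free pixels of ``resource`` whose centres lie within ``dist_m`` of
        the roost centre, as row-major ``(cols, rows)`` index arrays."""
        px = self.rmap.pixel_size
        rad_px = dist_m / px
        c0, r0 = roost
        lo_r = max(0, int(np.floor(r0 - rad_px)))
        hi_r = min(self.resource.shape[0], int(np.ceil(r0 + rad_px)) + 1)
        lo_c = max(0, int(np.floor(c0 - rad_px)))
        hi_c = min(self.resource.shape[1], int(np.ceil(c0 + rad_px)) + 1)
        window_res = self.resource[lo_r:hi_r, lo_c:hi_c]
        window_own = self.owner[lo_r:hi_r, lo_c:hi_c]
        cc = np.arange(lo_c, hi_c) - c0
        rr = np.arange(lo_r, hi_r) - r0
        dist2 = rr[:, None] ** 2 + cc[None, :] ** 2
        mask = (window_res == int(resource)) & (window_own == _FREE) & (dist2 <= rad_px**2)
        rows, cols = np.nonzero(mask)
        return cols + lo_c, rows + lo_r


def _claim_component(
    state: WorldState, seed_pixel: tuple[int, int], resource: Resource, bird_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """Claim the free connected component containing ``seed_pixel``; returns
    the claimed ``(cols, rows)`` index arrays (internal fast path)."""
    c0, r0 = seed_pixel
    if state.resource[r0, c0] != int(resource):
        raise InvalidInputError(f"seed pixel ({c0},{r0}) is not {resource.name}")
    if not state.is_free(c0, r0):
        raise InvalidInputError(f"seed pixel ({c0},{r0}) is not free")
    res = Resource(resource)
    if res in state._labels:
        lab = state._labels[res][r0, c0]
        cols = state._label_cols[res][lab]
        rows = state._label_rows[res][lab]
        if state._label_free[res][lab] == len(cols):
            # component fully free: claim by label lookup
            state.owner[rows, cols] = bird_id
            state._label_free[res][lab] = 0
            return cols, rows
    # partial component: flood fill over free pixels
    if state.connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n_rows, n_cols = state.resource.shape
    component = {seed_pixel}
    stack = [seed_pixel]
    while stack:
        c, r = stack.pop()
        for dc, dr in offsets:
            nc, nr = c + dc, r + dr
            if 0 <= nc < n_cols and 0 <= nr < n_rows and (nc, nr) not in component:
                if state.resource[nr, nc] == int(resource) and state.is_free(nc, nr):
                    component.add((nc, nr))
                    stack.append((nc, nr))
    state.claim_pixels(component, bird_id)
    arr = np.asarray(sorted(component, key=lambda p: (p[1], p[0])), dtype=np.intp)
    return arr[:, 0], arr[:, 1]


def claim_patch(
    state: WorldState, seed_pixel: tuple[int, int], resource: Resource, bird_id: int
) -> set[tuple[int, int]]:
    """Claim the entire connected component of free same-resource pixels
    containing ``seed_pixel`` for ``bird_id`` and return it.

    The component is computed over *free* pixels only: a pixel defended by
    another bird splits the component (and may split the claim).
    """
    cols, rows = _claim_component(state, seed_pixel, resource, bird_id)
    return set(zip(cols.tolist(), rows.tolist()))


def acquire_resource(
    state: WorldState,
    bird: Buzzard,
    resource: Resource,
    area_req_ha: float,
    search_dist_m: float,
    rng: np.random.Generator,
    whole_patch: bool = True,
) -> bool:
    """Acquire one forage resource for a bird; True on success.

    Seeds are drawn uniformly at random among the free pixels of the
    resource within ``search_dist_m`` of the roost; each draw claims the
    whole free patch reachable from the seed.  Acquisition stops as soon as
    the defended area meets ``area_req_ha`` (overshoot from whole-patch
    claims is kept), and fails when the requirement is unmet and no eligible
    seed remains.
    """
    if resource not in (Resource.ROUGH, Resource.MEADOW):
        raise InvalidInputError(f"cannot acquire resource {resource.name}")
    pixel_area = state.rmap.pixel_area_ha
    acquired_ha = sum(len(cl) for cl in bird.claims if cl.resource == resource) * pixel_area
    cand_cols, cand_rows = state.free_seeds_within(resource, bird.my_roost, search_dist_m)
    while True:
        if acquired_ha >= area_req_ha:
            return True
        if cand_cols.size == 0:
            return False
        i = int(rng.integers(cand_cols.size))
        seed = (int(cand_cols[i]), int(cand_rows[i]))
        if whole_patch:
            cols, rows = _claim_component(state, seed, resource, bird.name)
        else:
            patch = _claim_up_to(state, seed, resource, bird.name, area_req_ha - acquired_ha, pixel_area)
            arr = np.asarray(sorted(patch, key=lambda p: (p[1], p[0])), dtype=np.intp)
            cols, rows = arr[:, 0], arr[:, 1]
        bird.claims.append(Claim(resource, seed, cols, rows))
        acquired_ha += cols.size * pixel_area
        still_free = state.owner[cand_rows, cand_cols] == _FREE
        cand_cols, cand_rows = cand_cols[still_free], cand_rows[still_free]


def _claim_up_to(
    state: WorldState,
    seed_pixel: tuple[int, int],
    resource: Resource,
    bird_id: int,
    need_ha: float,
    pixel_area: float,
) -> set[tuple[int, int]]:
    """Mid-patch variant: flood fill stops once the remaining need is met."""
    need_px = int(np.ceil(need_ha / pixel_area - 1e-12))
    if state.connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n_rows, n_cols = state.resource.shape
    component = {seed_pixel}
    queue = [seed_pixel]
    qi = 0
    while qi < len(queue) and len(component) < need_px:
        c, r = queue[qi]
        qi += 1
        for dc, dr in offsets:
            nc, nr = c + dc, r + dr
            if 0 <= nc < n_cols and 0 <= nr < n_rows and (nc, nr) not in component:
                if state.resource[nr, nc] == int(resource) and state.is_free(nc, nr):
                    component.add((nc, nr))
                    queue.append((nc, nr))
                    if len(component) >= need_px:
                        break
    # the seed may already be owned (roost-extension path): claim free pixels only
    state.claim_pixels({p for p in component if state.is_free(*p)}, bird_id)
    return component


@dataclass
class FailureRecord:
    """A settlement attempt that ended in emigration."""

    roost: tuple[int, int]
    missing: Resource  # which requirement could not be met


def settle_one(
    state: WorldState,
    params: SimulationParams,
    rng: np.random.Generator,
    bird_id: int,
) -> Buzzard | FailureRecord:
    """Run one settlement attempt; returns the settled bird or a failure record.

    On failure every pixel the bird defended is released except the roost
    pixel, which is marked tried and stays unavailable to later birds.
    """
    candidates = state.free_untried_woodland()
    if not candidates:
        raise InvalidInputError("no free untried woodland pixel (caller must stop)")
    i = int(rng.integers(len(candidates)))
    roost = state.take_roost(i, bird_id)
    bird = Buzzard(name=bird_id, my_roost=roost)
    roost_pixels = {roost}
    pixel_area = state.rmap.pixel_area_ha
    ok = True
    if params.roost_area_ha > pixel_area:
        # larger roost requirement: extend into the containing woodland patch
        extra = _claim_up_to(
            state, roost, Resource.WOODLAND, bird_id,
            params.roost_area_ha, pixel_area,
        ) - {roost}
        roost_pixels |= extra
        ok = len(roost_pixels) * pixel_area >= params.roost_area_ha
        missing = Resource.WOODLAND
    if ok:
        ok = acquire_resource(
            state, bird, Resource.ROUGH, params.rgr_area_ha, params.rgr_dist_m, rng,
            whole_patch=params.whole_patch,
        )
        missing = Resource.ROUGH
    if ok:
        ok = acquire_resource(
            state, bird, Resource.MEADOW, params.mead_area_ha, params.mead_dist_m, rng,
            whole_patch=params.whole_patch,
        )
        missing = Resource.MEADOW
    bird.roost_patch = roost_pixels
    if not ok:
        if bird.claims:
            state.release_arrays(
                np.concatenate([cl.cols for cl in bird.claims]),
                np.concatenate([cl.rows for cl in bird.claims]),
            )
        state.release_pixels(roost_pixels - {roost})
        state.fail_roost(roost)
        return FailureRecord(roost=roost, missing=missing)
    for cl in bird.claims:
        target = bird.my_rgr if cl.resource == Resource.ROUGH else bird.my_mead
        target.update(zip(cl.cols.tolist(), cl.rows.tolist()))
    # coordinates in claim order: roost, then rough-ground, then meadow
    ordered = [roost] + sorted(roost_pixels - {roost}) + [
        (int(c), int(r)) for cl in bird.claims for c, r in zip(cl.cols, cl.rows)
    ]
    coords = state.rmap.centres(ordered)
    bird.X = coords[:, 0].tolist()
    bird.Y = coords[:, 1].tolist()
    return bird


@dataclass
class SimulationResult:
    """Outcome of one run: settled birds, final world state and metadata."""

    buzzards: list[Buzzard]
    state: WorldState
    seed: int | None
    n_failed: int
    params: SimulationParams

    @property
    def n_settled(self) -> int:
        return len(self.buzzards)


def run_simulation(
    rmap: ResourceMap,
    mask: StudyMask | None,
    params: SimulationParams | None = None,
    config: RunConfig | None = None,
) -> SimulationResult:
    """Settle birds until free woodland is exhausted everywhere in the world.

    Birds may roost in the boundary strip (outside ``mask.core``); they are
    simulated in full but excluded from abundance by
    :func:`buteo_abm.ranges.abundance`.
    """
    params = params or SimulationParams()
    config = config or RunConfig()
    if mask is None:
        mask = full_mask(rmap)
    if mask.core.shape != rmap.grid.shape:
        raise InvalidInputError("mask and map shapes disagree")
    seed = config.seed if config.seed_on else None
    rng = np.random.default_rng(seed)
    state = WorldState(rmap, connectivity=params.connectivity)
    birds: list[Buzzard] = []
    n_failed = 0
    bird_id = 0
    while True:
        if not state.free_untried_woodland():
            break
        outcome = settle_one(state, params, rng, bird_id)
        if isinstance(outcome, Buzzard):
            birds.append(outcome)
            bird_id += 1
        else:
            n_failed += 1
    return SimulationResult(buzzards=birds, state=state, seed=seed, n_failed=n_failed, params=params)


def validate_result(result: SimulationResult) -> None:
    """Assert the structural invariants every run must satisfy.

    Exclusivity (no pixel defended twice), per-bird sufficiency (roost on
    woodland, rough-ground and meadow requirements met), seed-distance
    soundness (every claim's seed within the search distance of the roost)
    and owner-grid consistency.  Raises AssertionError on violation.
    """
    state = result.state
    params = result.params
    pa = state.rmap.pixel_area_ha
    seen: dict[tuple[int, int], int] = {}
    for bird in result.buzzards:
        for px in bird.territory_pixels:
            assert px not in seen, f"pixel {px} defended by {seen[px]} and {bird.name}"
            seen[px] = bird.name
            assert state.owner[px[1], px[0]] == bird.name
        c, r = bird.my_roost
        assert state.resource[r, c] == int(Resource.WOODLAND), "roost not on woodland"
        assert len(bird.my_rgr) * pa >= params.rgr_area_ha - 1e-9, "rough-ground deficit"
        assert len(bird.my_mead) * pa >= params.mead_area_ha - 1e-9, "meadow deficit"
        assert len(bird.X) == len(bird.territory_pixels) == len(bird.Y)
        for cl in bird.claims:
            dist = params.rgr_dist_m if cl.resource == Resource.ROUGH else params.mead_dist_m
            sc, sr = cl.seed_pixel
            d = np.hypot(sc - c, sr - r) * state.rmap.pixel_size
            assert d <= dist + 1e-9, "claim seed beyond search distance"
            assert cl.seed_pixel in cl.pixels
    owned = np.nonzero(result.state.owner != _FREE)
    owned_px = set(zip(owned[1].tolist(), owned[0].tolist()))
    assert owned_px == set(seen), "owner grid disagrees with bird pixel sets"


@dataclass
class ReplicateSummary:
    """Abundance statistics over replicate runs plus pooled per-bird metrics."""

    abundances: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    min: int
    max: int
    seeds: list[int]
    birds_per_run: list[int]
    mean_territory_ha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"seed": self.seeds, "abundance": self.abundances})


def run_replicates(
    rmap: ResourceMap,
    mask: StudyMask | None,
    params: SimulationParams | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
    keep_results: bool = False,
) -> ReplicateSummary | tuple[ReplicateSummary, list[SimulationResult]]:
    """Run ``n_runs`` independent replicates and summarize abundance.

    Reports the mean, its 95% t-interval, and the min-max range, plus the
    pooled mean territory area per bird.  Per-run seeds are spawned
    reproducibly from ``base_seed``.
    """
    from buteo_abm.ranges import abundance  # local import avoids a cycle

    if n_runs < 1:
        raise InvalidInputError("n_runs must be >= 1")
    if mask is None:
        mask = full_mask(rmap)
    seeds = derive_seeds(base_seed, n_runs)
    counts = np.empty(n_runs, dtype=int)
    per_run_birds: list[int] = []
    areas: list[float] = []
    results: list[SimulationResult] = []
    for k, seed in enumerate(seeds):
        res = run_simulation(rmap, mask, params, RunConfig(seed=seed))
        counts[k] = abundance(res, mask)
        per_run_birds.append(res.n_settled)
        areas.extend(len(b.territory_pixels) * rmap.pixel_area_ha for b in res.buzzards)
        if keep_results:
            results.append(res)
    mean = float(counts.mean())
    if n_runs > 1 and counts.std(ddof=1) > 0:
        sem = counts.std(ddof=1) / np.sqrt(n_runs)
        tcrit = stats.t.ppf(0.975, n_runs - 1)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
    else:
        ci = (mean, mean)
    summary = ReplicateSummary(
        abundances=counts,
        mean=mean,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        min=int(counts.min()),
        max=int(counts.max()),
        seeds=seeds,
        birds_per_run=per_run_birds,
        mean_territory_ha=float(np.mean(areas)) if areas else float("nan"),
    )
    return (summary, results) if keep_results else summary


def derive_seeds(base_seed: int, n: int, *extra: int) -> list[int]:
    """Derive ``n`` reproducible sub-seeds from a base seed (and context ints)."""
    ss = np.random.SeedSequence([int(base_seed), *[int(e) for e in extra]])
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]
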