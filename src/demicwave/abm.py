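"""Agent-based simulation of village-led demographic expansion.

Each agent is a village on an equal-area grid of 10 × 10 km cells. One
step is one year, counted in "sim BP" from a start date down to 500 sim
BP (≈ European arrival). Every year each active village, in seeded
random order:

1. *grows* exponentially (``N ← N(1 + a)``, a = 0.025 yr⁻¹ fixed). When
   the population exceeds its ceiling — the observed maximum density K*
   (individuals per 100 km²) times the cells it has claimed — it claims
   one more unclaimed settleable cell within its catchment radius
   (highest suitability first), raising the ceiling; with no cell to
   claim, the population is clamped back to the ceiling.
2. *fissions* once its population reaches the fission threshold,
   provided it has at most 6 neighbors (≈ hexagonal packing): a daughter
   settles the best free cell in the ring just beyond the catchment,
   taking half the population. Failing that, a *leapfrog* daughter may
   settle at the leap distance if the distant cell is more attractive
   than home. With nowhere to go the population simply keeps growing.
3. *relocates* after sitting in place longer than the permanence time,
   searching the same adjacency ring and then the leap annulus; moving
   releases all claimed cells.

Villages that are clamped at their ceiling and have no adjacent or leap
destination become inactive; the expansion front therefore carries all
the activity. The run's product is the first-arrival raster: the sim BP
year each cell was first occupied, whether settled as a village home or
claimed into a village's catchment territory. Arrival is recorded once
and never overwritten — the raster describes first colonization.

Internally the grid is padded with an unsettleable border and addressed
by flat indices, so neighborhood searches are single fancy-indexing
operations; a neighbor-count field and a free-cell mask are maintained
incrementally. None of this changes the model's semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from demicwave.landscape import Grid

__all__ = [
    "Params",
    "Village",
    "SimState",
    "ConfigurationError",
    "init_run",
    "grow",
    "find_cell",
    "try_fission",
    "try_relocate",
    "step",
    "run_simulation",
    "front_trajectory",
    "front_speed",
]

#: Simulation stops when the clock reaches this year (sim BP).
END_YEAR = 500

#: Maximum number of neighbors before adjacent fission is blocked.
MAX_NEIGHBORS = 6

#: Reference cell area (km²) for which K* densities are quoted.
K_STAR_AREA_KM2 = 100.0


class ConfigurationError(ValueError):
    """Invalid simulation setup (unsettleable origin, too-late start)."""


@dataclass(frozen=True)
class Params:
    """Demographic parameters of one simulation (the GA's search space).

    ``a`` is fixed at 0.025 yr⁻¹ in all runs; the remaining fields are
    bounded by the ethnographically derived ranges used to initialize
    the genetic algorithm.
    """

    k_star: float = 60.0  # individuals per 100 km² cell, 20–100
    catchment_km: float = 20.0  # 10–30
    fission_threshold: float = 150.0  # individuals, 50–300
    leap_km: float = 0.0  # 0 (disabled) or 150–250
    permanence: float = 20.0  # years, 10–30
    a: float = 0.025  # yr⁻¹, constant

    def __post_init__(self) -> None:
        if not 20.0 <= self.k_star <= 100.0:
            raise ValueError(f"k_star out of range [20, 100]: {self.k_star}")
        if not 10.0 <= self.catchment_km <= 30.0:
            raise ValueError(f"catchment_km out of range [10, 30]: {self.catchment_km}")
        if not 50.0 <= self.fission_threshold <= 300.0:
            raise ValueError(f"fission_threshold out of range [50, 300]: {self.fission_threshold}")
        if self.leap_km != 0.0 and not 150.0 <= self.leap_km <= 250.0:
            raise ValueError(f"leap_km must be 0 or in [150, 250]: {self.leap_km}")
        if not 10.0 <= self.permanence <= 30.0:
            raise ValueError(f"permanence out of range [10, 30]: {self.permanence}")


@dataclass
class Village:
    id: int
    population: float
    home: tuple[int, int]  # (row, col) in grid coordinates
    claimed: list[int] = field(default_factory=list)  # padded flat indices
    years_in_place: int = 0
    active: bool = True
    ceiling: float = 0.0  # cached K* × claimed cells × cell area / 100


def _ring_offsets(r_min_km: float, r_max_km: float, cell_km: float) -> np.ndarray:
    """(dr, dc) offsets whose center distance d satisfies r_min < d ≤ r_max."""
    r = int(np.ceil(r_max_km / cell_km)) + 1
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(dr, dc) * cell_km
    mask = (d > r_min_km) & (d <= r_max_km)
    return np.column_stack([dr[mask], dc[mask]])


class _Offsets:
    """Per-run precomputed neighborhoods as padded flat-index offsets."""

    def __init__(self, params: Params, cell_km: float, row_stride: int) -> None:
        def flat(offsets: np.ndarray) -> np.ndarray:
            return offsets[:, 0] * row_stride + offsets[:, 1]

        catchment = _ring_offsets(-1.0, params.catchment_km, cell_km)
        ring = _ring_offsets(params.catchment_km, params.catchment_km + cell_km, cell_km)
        neighbors = _ring_offsets(0.0, 2.0 * params.catchment_km, cell_km)
        if params.leap_km > 0:
            leap = _ring_offsets(params.leap_km - cell_km, params.leap_km + cell_km, cell_km)
        else:
            leap = np.empty((0, 2), dtype=int)
        self.pad = int(
            max(
                (np.abs(o).max() if o.size else 0)
                for o in (catchment, ring, neighbors, leap)
            )
        )
        self.catchment = flat(catchment)
        self.ring = flat(ring)
        self.neighbors = flat(neighbors)
        self.leap = flat(leap)


@dataclass
class SimState:
    """Mutable world state: the village roster plus per-cell ownership layers."""

    year: int  # sim BP, decreasing
    grid: Grid
    params: Params
    villages: dict[int, Village]
    rng: np.random.Generator
    next_id: int = 0
    pop_history: list[float] = field(default_factory=list)

    # padded internal layers (set by init_run)
    _pad: int = 0
    _shape_pad: tuple[int, int] = (0, 0)
    _suit: np.ndarray | None = None  # padded flat suitability
    _free: np.ndarray | None = None  # padded flat: settleable and unclaimed
    _claimed_pad: np.ndarray | None = None  # padded 2-d village id or -1
    _nbr_count: np.ndarray | None = None  # padded flat count of homes within 2×catchment
    _arrival: np.ndarray | None = None  # unpadded 2-d, sim BP or NaN
    _offsets: _Offsets | None = None
    _active_ids: set[int] = field(default_factory=set)

    @property
    def arrival(self) -> np.ndarray:
        return self._arrival

    @property
    def claimed_by(self) -> np.ndarray:
        p = self._pad
        return self._claimed_pad[p:-p, p:-p]

    def total_population(self) -> float:
        return sum(v.population for v in self.villages.values())

    def active_villages(self) -> list[Village]:
        return [self.villages[i] for i in sorted(self._active_ids)]

    # -- coordinate helpers -------------------------------------------------
    def _flat(self, row: int, col: int) -> int:
        return (row + self._pad) * self._shape_pad[1] + (col + self._pad)

    def _unflat(self, idx: int) -> tuple[int, int]:
        r, c = divmod(int(idx), self._shape_pad[1])
        return r - self._pad, c - self._pad


def _ceiling_of(n_claimed: int, params: Params, grid: Grid) -> float:
    return params.k_star * n_claimed * grid.cell_area_km2 / K_STAR_AREA_KM2


def init_run(
    params: Params,
    grid: Grid,
    origin_cell: tuple[int, int],
    start_year: int,
    seed: int | np.random.Generator,
) -> SimState:
    """Create the initial state: one village at the origin, at fission threshold.

    Starting at the fission threshold makes the founding village fission
    immediately on the first step, launching the expansion.
    """
    r, c = origin_cell
    if not grid.in_bounds(r, c) or not grid.settleable[r, c]:
        raise ConfigurationError(f"origin cell {origin_cell} is not settleable")
    if not start_year > END_YEAR:
        raise ConfigurationError(f"start_year must be > {END_YEAR}, got {start_year}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    probe = _Offsets(params, grid.cell_km, 1)
    pad = probe.pad
    shape_pad = (grid.n_rows + 2 * pad, grid.n_cols + 2 * pad)
    offsets = _Offsets(params, grid.cell_km, shape_pad[1])

    suit_pad = np.full(shape_pad, -np.inf)
    suit_pad[pad:-pad, pad:-pad] = np.where(
        np.isfinite(grid.suitability), grid.suitability, -np.inf
    )
    free_pad = np.zeros(shape_pad, dtype=bool)
    free_pad[pad:-pad, pad:-pad] = grid.settleable

    state = SimState(
        year=int(start_year),
        grid=grid,
        params=params,
        villages={},
        rng=rng,
        _pad=pad,
        _shape_pad=shape_pad,
        _suit=suit_pad.ravel(),
        _free=free_pad.ravel(),
        _claimed_pad=np.full(shape_pad, -1, dtype=np.int32),
        _nbr_count=np.zeros(shape_pad[0] * shape_pad[1], dtype=np.int32),
        _arrival=np.full((grid.n_rows, grid.n_cols), np.nan),
        _offsets=offsets,
    )
    v = Village(id=0, population=float(params.fission_threshold), home=(r, c))
    _settle(state, v)
    state.next_id = 1
    return state


def _claim(state: SimState, v: Village, flat: int) -> None:
    """Take ownership of one free cell, recording first occupation."""
    state._free[flat] = False
    state._claimed_pad.ravel()[flat] = v.id
    v.claimed.append(flat)
    r, c = state._unflat(flat)
    if np.isnan(state._arrival[r, c]):
        state._arrival[r, c] = state.year


def _settle(state: SimState, v: Village) -> None:
    """Register a village at its home cell, claiming it and recording arrival."""
    f = state._flat(*v.home)
    state.villages[v.id] = v
    state._active_ids.add(v.id)
    v.claimed = []
    _claim(state, v, f)
    v.ceiling = _ceiling_of(1, state.params, state.grid)
    state._nbr_count[f + state._offsets.neighbors] += 1


def _vacate_home(state: SimState, v: Village) -> None:
    """Release all claimed cells and withdraw the home's neighbor footprint."""
    claimed = np.asarray(v.claimed, dtype=np.intp)
    state._free[claimed] = True
    state._claimed_pad.ravel()[claimed] = -1
    f = state._flat(*v.home)
    state._nbr_count[f + state._offsets.neighbors] -= 1
    v.claimed = []


def _search(
    state: SimState, home_flat: int, offs: np.ndarray, require_better: bool
) -> int | None:
    """Best free settleable cell at ``home + offs`` (padded flat index), or None."""
    if offs.size == 0:
        return None
    idx = home_flat + offs
    m = state._free[idx]
    if require_better:
        m &= state._suit[idx] > state._suit[home_flat]
    if not m.any():
        return None
    cand = idx[m]
    vals = state._suit[cand]
    best = vals.max()
    ties = np.flatnonzero(vals == best)
    i = ties[state.rng.integers(len(ties))] if len(ties) > 1 else ties[0]
    return int(cand[i])


def find_cell(state: SimState, v: Village, mode: str) -> tuple[int, int] | None:
    """Best free cell for a daughter/relocation; ``mode`` is 'adjacent' or 'leap'.

    Adjacent candidates lie in the ring just beyond the catchment
    (distance in ``(catchment, catchment + cell]``). Leap candidates lie
    in the annulus ``[leap − cell, leap + cell]`` and must be strictly
    more suitable than the current home (the attractiveness condition
    for long-distance migration). Returns None when no candidate exists.
    """
    f = state._flat(*v.home)
    if mode == "adjacent":
        hit = _search(state, f, state._offsets.ring, require_better=False)
    elif mode == "leap":
        if state.params.leap_km <= 0:
            return None
        hit = _search(state, f, state._offsets.leap, require_better=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return None if hit is None else state._unflat(hit)


def grow(state: SimState, v: Village) -> bool:
    """Exponential growth with density ceiling; returns True if clamped.

    Over-ceiling villages claim one unclaimed settleable catchment cell
    per year (highest suitability first), raising the ceiling; when no
    cell is claimable the population is cut back to the ceiling.
    """
    v.population *= 1.0 + state.params.a
    if v.population <= v.ceiling:
        return False
    f = state._flat(*v.home)
    hit = _search(state, f, state._offsets.catchment, require_better=False)
    if hit is not None:
        # claiming raises the ceiling; the population is left untouched even
        # if still above it — territory expands one cell per year and the
        # ceiling catches up, it is saturation (no claimable cell) that cuts
        # the population back
        _claim(state, v, hit)
        v.ceiling = _ceiling_of(len(v.claimed), state.params, state.grid)
        return False
    v.population = v.ceiling
    return True


def _neighbor_count(state: SimState, v: Village) -> int:
    """Villages with home cells within 2 × catchment of this home (itself excluded)."""
    return int(state._nbr_count[state._flat(*v.home)])


def try_fission(state: SimState, v: Village) -> Village | None:
    """Split off a daughter village when at the fission threshold.

    Adjacent fission requires at most 6 neighbors (hexagonal-packing
    bound); otherwise, or when the adjacency is full, a leapfrog
    daughter is attempted. Parent and daughter each keep half the
    population. With no destination, growth simply continues past the
    threshold.
    """
    if v.population < state.params.fission_threshold:
        return None
    target = None
    if _neighbor_count(state, v) <= MAX_NEIGHBORS:
        target = find_cell(state, v, "adjacent")
    if target is None:
        target = find_cell(state, v, "leap")
    if target is None:
        return None
    half = v.population / 2.0
    v.population = half
    daughter = Village(id=state.next_id, population=half, home=target)
    state.next_id += 1
    _settle(state, daughter)
    return daughter


def try_relocate(state: SimState, v: Village) -> bool:
    """Move the village once it has stayed longer than the permanence time.

    The search mirrors fission (adjacency ring, then leap annulus). On a
    move all claimed cells are released, the residence clock resets, and
    arrival is recorded at the new home if unreached. Returns True if
    moved.
    """
    if v.years_in_place <= state.params.permanence:
        return False
    target = find_cell(state, v, "adjacent")
    if target is None:
        target = find_cell(state, v, "leap")
    if target is None:
        return False
    _move_home(state, v, target)
    return True


def _move_home(state: SimState, v: Village, target: tuple[int, int]) -> None:
    _vacate_home(state, v)
    v.home = target
    v.years_in_place = 0
    f = state._flat(*target)
    _claim(state, v, f)
    v.ceiling = _ceiling_of(1, state.params, state.grid)
    state._nbr_count[f + state._offsets.neighbors] += 1


def step(state: SimState) -> SimState:
    """Advance one year: grow/fission/relocate each active village, then age.

    Villages are processed in seeded random order to avoid systematic
    agent-ordering bias. A village that is clamped at its ceiling and
    has no adjacent or leap destination becomes inactive. The clock
    decrements by one at the end.

    Within one village's turn, a failed neighborhood search cannot
    succeed later in the same turn (the village only removes free cells
    during its turn), so negative search results are reused instead of
    re-scanned.
    """
    params = state.params
    thr = params.fission_threshold
    leap_enabled = params.leap_km > 0
    ids = np.fromiter(state._active_ids, dtype=np.int64, count=len(state._active_ids))
    ids.sort()  # set order is not deterministic across processes
    order = state.rng.permutation(ids)
    for vid in order:
        v = state.villages[vid]
        clamped = grow(state, v)
        no_adj = False
        no_leap = not leap_enabled

        if v.population >= thr:
            target = None
            if _neighbor_count(state, v) <= MAX_NEIGHBORS:
                target = find_cell(state, v, "adjacent")
                if target is None:
                    no_adj = True
            if target is None and leap_enabled:
                target = find_cell(state, v, "leap")
                if target is None:
                    no_leap = True
            if target is not None:
                half = v.population / 2.0
                v.population = half
                daughter = Village(id=state.next_id, population=half, home=target)
                state.next_id += 1
                _settle(state, daughter)

        moved = False
        if v.years_in_place > params.permanence:
            target = None if no_adj else find_cell(state, v, "adjacent")
            if target is None:
                no_adj = True
                if not no_leap:
                    target = find_cell(state, v, "leap")
                    if target is None:
                        no_leap = True
            if target is not None:
                _move_home(state, v, target)
                moved = True

        if clamped and not moved:
            if not no_adj:
                no_adj = find_cell(state, v, "adjacent") is None
            if no_adj and not no_leap:
                no_leap = find_cell(state, v, "leap") is None
            if no_adj and no_leap:
                v.active = False
                state._active_ids.discard(v.id)

    for vid in state._active_ids:
        state.villages[vid].years_in_place += 1
    state.year -= 1
    state.pop_history.append(state.total_population())
    return state


def run_simulation(
    params: Params,
    grid: Grid,
    origin_cell: tuple[int, int],
    start_year: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, list[float], SimState]:
    """Run from ``start_year`` down to 500 sim BP.

    Returns ``(arrival, pop_history, final_state)``: the first-arrival
    raster (sim BP, NaN where never settled) and the total-population
    series, one entry per completed year.
    """
    state = init_run(params, grid, origin_cell, start_year, seed)
    while state.year > END_YEAR:
        step(state)
    return state.arrival, state.pop_history, state


def front_trajectory(
    arrival: np.ndarray, origin_cell: tuple[int, int], cell_km: float
) -> tuple[np.ndarray, np.ndarray]:
    """Front radius (km) as a function of elapsed time since the start.

    For each simulated year, the front position is the maximum distance
    from the origin among cells already settled by that year. Returns
    ``(elapsed_years, front_km)``.
    """
    reached = np.argwhere(np.isfinite(arrival))
    if reached.size == 0:
        raise ValueError("no settled cells")
    years = arrival[reached[:, 0], reached[:, 1]]
    d = np.hypot(reached[:, 0] - origin_cell[0], reached[:, 1] - origin_cell[1]) * cell_km
    start = years.max()
    order = np.argsort(-years)  # chronological (years decrease with time)
    front = np.maximum.accumulate(d[order])
    elapsed = start - years[order]
    # one entry per year: latest front value of that year
    uniq, last = np.unique(elapsed[::-1], return_index=True)
    front_per_year = front[::-1][last]
    return uniq, front_per_year


def front_speed(
    arrival: np.ndarray,
    origin_cell: tuple[int, int],
    cell_km: float,
    max_radius_km: float | None = None,
    burn_in_km: float = 100.0,
) -> float:
    """Realized front speed (km yr⁻¹): slope of front radius over elapsed time.

    Fitted by least squares on the window after the front clears
    ``burn_in_km`` and before it reaches ``max_radius_km`` (defaults to
    the largest radius fully inside the grid, where edge effects begin).
    """
    if max_radius_km is None:
        n_rows, n_cols = arrival.shape
        max_radius_km = cell_km * min(
            origin_cell[0], origin_cell[1], n_rows - 1 - origin_cell[0], n_cols - 1 - origin_cell[1]
        )
    t, f = front_trajectory(arrival, origin_cell, cell_km)
    m = (f >= burn_in_km) & (f <= max_radius_km)
    if m.sum() < 3:
        raise ValueError("front trajectory window too short to fit")
    slope = np.polyfit(t[m], f[m], 1)[0]
    return float(slope)
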