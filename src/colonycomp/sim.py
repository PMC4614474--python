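"""Event-driven lattice simulator of clonal microcolonies competing for space.

The habitat is a two-dimensional square lattice in which each site holds at
most one cell.  Founder cells are scattered at random, wait out an optional
lag time, and then divide at intervals drawn uniformly from a configurable
range (default 18-22 min).  A daughter cell is placed on a uniformly chosen
empty site of the mother's Moore (8-connected) neighbourhood; positions just
beyond the lattice edge count as available but the daughter is not tracked,
so the boundary is open.  What happens when the Moore neighbourhood is full
distinguishes the two growth regimes:

``exponential_area``
    the daughter is placed on a uniformly chosen empty site of the colony's
    perimeter (mimicking cells deep in a microcolony pushing the colony
    outward), so every cell keeps dividing and colony area grows
    exponentially until space runs out;

``perimeter``
    the enclosed mother is permanently retired, so only cells with empty
    neighbours reproduce and growth is boundary-limited.

Both regimes are special cases of a placement threshold: perimeter sites
within Euclidean distance ``threshold`` of the mother qualify for fallback
placement.  ``threshold = inf`` gives exponential-area growth and
``threshold = sqrt(2)`` restricts placement to the Moore neighbourhood.

The simulation is a discrete-event loop that jumps from one division to the
next; the state between divisions is frozen.  All randomness flows through a
single :class:`numpy.random.Generator` seeded from the config, and ties in
division times are broken first-scheduled-first-served, so runs are exactly
reproducible.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .synth import LagModel, sample_lag_times

EMPTY = 0

#: placement outcomes that are not lattice sites
BLOCKED = "BLOCKED"
OFF_LATTICE = "OFF_LATTICE"

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


class InternalConsistencyError(RuntimeError):
    """Raised when the lattice bookkeeping is found to be inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one simulation run.

    ``regime`` may be ``"exponential_area"`` or ``"perimeter"``; an explicit
    ``threshold`` (lattice units, Euclidean, measured from the mother's site)
    overrides the regime preset.
    """

    width: int = 500
    height: int = 500
    n_seeds: int = 400
    lag_model: Optional[LagModel] = None
    division_range: tuple[float, float] = (18.0, 22.0)
    regime: str = "exponential_area"
    threshold: Optional[float] = None
    rng_seed: int = 0
    max_events: Optional[int] = None

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ConfigurationError("lattice must be at least 2x2")
        if not (0 < self.n_seeds <= self.width * self.height):
            raise ConfigurationError(
                f"n_seeds={self.n_seeds} must be in (0, {self.width * self.height}]"
            )
        t_min, t_max = self.division_range
        if t_min > t_max or t_min < 0:
            raise ConfigurationError("division_range must satisfy 0 <= t_min <= t_max")
        if self.regime not in ("exponential_area", "perimeter"):
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.threshold is not None and self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")

    @property
    def effective_threshold(self) -> float:
        """Fallback-placement distance implied by regime/threshold."""
        if self.threshold is not None:
            return self.threshold
        return math.inf if self.regime == "exponential_area" else math.sqrt(2.0)


class _IndexedSet:
    """Set of ints with O(1) add/discard and O(1) uniform sampling."""

    __slots__ = ("_items", "_pos")

    def __init__(self) -> None:
        self._items: list[int] = []
        self._pos: dict[int, int] = {}

    def add(self, x: int) -> None:
        if x not in self._pos:
            self._pos[x] = len(self._items)
            self._items.append(x)

    def discard(self, x: int) -> None:
        i = self._pos.pop(x, None)
        if i is None:
            return
        last = self._items.pop()
        if i < len(self._items):
            self._items[i] = last
            self._pos[last] = i

    def sample(self, rng: np.random.Generator) -> int:
        return self._items[rng.integers(len(self._items))]

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, x: int) -> bool:
        return x in self._pos

    def __iter__(self):
        return iter(self._items)


class LatticeState:
    """One-cell-per-site occupancy grid with per-lineage perimeter sets.

    ``occupancy[r, c]`` is a lineage id or :data:`EMPTY`.  For each lineage
    the perimeter set holds the empty sites that are 8-adjacent to at least
    one of that lineage's occupied sites; it is maintained incrementally as
    sites are occupied (a brute-force recomputation is available for
    verification).  Sites are stored internally as flat ``r * width + c``
    indices.
    """

    def __init__(self, width: int, height: int) -> None:
        self.width = width
        self.height = height
        self.occupancy = np.zeros((height, width), dtype=np.int32)
        self.perimeter: dict[int, _IndexedSet] = {}
        self.n_occupied = 0

    def neighbors(self, flat: int) -> list[int]:
        """On-lattice Moore neighbours of a flat site index."""
        r, c = divmod(flat, self.width)
        out = []
        for dr, dc in _MOORE:
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.height and 0 <= cc < self.width:
                out.append(rr * self.width + cc)
        return out

    def occupy(self, flat: int, lineage: int) -> None:
        """Occupy an empty site and update all perimeter bookkeeping."""
        occ = self.occupancy.ravel()
        if occ[flat] != EMPTY:
            raise InternalConsistencyError(f"site {flat} already occupied")
        occ[flat] = lineage
        self.n_occupied += 1
        per = self.perimeter.setdefault(lineage, _IndexedSet())
        per.discard(flat)
        for nb in self.neighbors(flat):
            owner = occ[nb]
            if owner == EMPTY:
                per.add(nb)
            elif owner != lineage:
                self.perimeter[owner].discard(flat)

    def brute_force_perimeters(self) -> dict[int, set[int]]:
        """Recompute perimeter sets from scratch (oracle for the incremental ones)."""
        occ = self.occupancy.ravel()
        out: dict[int, set[int]] = {lin: set() for lin in self.perimeter}
        for flat in range(occ.size):
            lin = occ[flat]
            if lin == EMPTY:
                continue
            out.setdefault(int(lin), set())
            for nb in self.neighbors(flat):
                if occ[nb] == EMPTY:
                    out[int(lin)].add(nb)
        return out


@dataclass
class CellEvent:
    """A scheduled division: (time, insertion order, cell id)."""

    time: float
    seq: int
    cell: int

    def astuple(self) -> tuple[float, int, int]:
        return (self.time, self.seq, self.cell)


@dataclass
class SimResult:
    """Outcome of one run: final label map plus per-lineage bookkeeping."""

    label_map: np.ndarray
    founders: pd.DataFrame  # lineage_id, row, col, lag_min
    areas: pd.Series  # sites per lineage id
    touches_edge: pd.Series  # bool per lineage id
    event_count: int
    elapsed_min: float
    occupancy_fraction: float
    truncated: bool = False

    @property
    def n_lineages(self) -> int:
        return len(self.founders)


class _Run:
    """Mutable state shared by the stepping functions."""

    __slots__ = ("cells", "queue", "seq", "events", "off_lattice_births", "time")

    def __init__(self) -> None:
        self.cells: list[tuple[int, int] | None] = []  # (flat site, lineage) or None
        self.queue: list[tuple[float, int, int]] = []
        self.seq = 0
        self.events = 0
        self.off_lattice_births = 0
        self.time = 0.0

    def push(self, time: float, cell: int) -> None:
        heapq.heappush(self.queue, (time, self.seq, cell))
        self.seq += 1


def seed_lattice(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, LatticeState]:
    """Scatter founder cells on distinct random sites.

    Returns the founder table (lineage ids 1..n_seeds, in placement order)
    and the seeded lattice.
    """
    n_sites = config.width * config.height
    flats = rng.choice(n_sites, size=config.n_seeds, replace=False)
    state = LatticeState(config.width, config.height)
    rows, cols = np.divmod(flats, config.width)
    for i, flat in enumerate(flats):
        state.occupy(int(flat), i + 1)
    founders = pd.DataFrame(
        {
            "lineage_id": np.arange(1, config.n_seeds + 1),
            "row": rows.astype(int),
            "col": cols.astype(int),
            "lag_min": np.zeros(config.n_seeds),
        }
    )
    return founders, state


def schedule_initial_events(
    founders: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    lags: Optional[np.ndarray] = None,
) -> _Run:
    """Assign each founder its first division time and build the event queue.

    With a lag model (or an explicit ``lags`` array) the founder's first
    division fires at its lag time (lag is the waiting time before a founder
    starts to divide); without one it fires after a fresh uniform division
    interval.  Founders are entered in lineage-id order, so equal times
    resolve first-come-first-served.
    """
    run = _Run()
    n = len(founders)
    if lags is not None:
        first = np.asarray(lags, dtype=float)
        if len(first) != n:
            raise ConfigurationError("need one lag per founder")
        founders["lag_min"] = first
    elif config.lag_model is not None and config.lag_model.kind != "none":
        first = sample_lag_times(config.lag_model, n, rng)
        founders["lag_min"] = first
    else:
        t_min, t_max = config.division_range
        first = rng.uniform(t_min, t_max, size=n)
    width = config.width
    for i in range(n):
        flat = int(founders["row"].iat[i]) * width + int(founders["col"].iat[i])
        run.cells.append((flat, int(founders["lineage_id"].iat[i])))
        run.push(float(first[i]), i)
    return run


def place_daughter(
    state: LatticeState,
    mother_flat: int,
    lineage: int,
    threshold: float,
    rng: np.random.Generator,
):
    """Pick the site for a daughter of the cell at ``mother_flat``.

    Returns a flat site index, :data:`OFF_LATTICE` (an open-boundary Moore
    position beyond the lattice edge was drawn), or :data:`BLOCKED` (no
    qualifying site).  Moore positions are tried first, uniformly over the
    empty ones; if the whole neighbourhood is occupied, a uniform draw is
    made from the lineage's perimeter sites within ``threshold`` of the
    mother.
    """
    occ = state.occupancy.ravel()
    if occ[mother_flat] != lineage:
        raise InternalConsistencyError(
            f"site {mother_flat} not owned by lineage {lineage}"
        )
    r, c = divmod(mother_flat, state.width)
    candidates: list[int] = []  # -1 encodes an off-lattice position
    for dr, dc in _MOORE:
        rr, cc = r + dr, c + dc
        if 0 <= rr < state.height and 0 <= cc < state.width:
            flat = rr * state.width + cc
            if occ[flat] == EMPTY:
                candidates.append(flat)
        else:
            candidates.append(-1)
    if candidates:
        choice = candidates[rng.integers(len(candidates))]
        return OFF_LATTICE if choice == -1 else choice
    per = state.perimeter.get(lineage)
    if per is None or len(per) == 0:
        return BLOCKED
    if math.isinf(threshold):
        return per.sample(rng)
    thr2 = threshold * threshold
    width = state.width
    eligible = [
        f
        for f in per
        if (f // width - r) ** 2 + (f % width - c) ** 2 <= thr2
    ]
    if not eligible:
        return BLOCKED
    return eligible[rng.integers(len(eligible))]


def step(state: LatticeState, run: _Run, config: SimConfig, rng: np.random.Generator) -> None:
    """Process the earliest division event.

    On a successful on-lattice placement the daughter becomes a new tracked
    cell and both mother and daughter are rescheduled with fresh uniform
    division intervals.  An off-lattice placement reschedules the mother
    only.  A blocked mother is retired permanently.
    """
    t, _, cell = heapq.heappop(run.queue)
    run.time = t
    run.events += 1
    rec = run.cells[cell]
    if rec is None:  # retired cell; defensive, retired cells are never requeued
        return
    flat, lineage = rec
    site = place_daughter(state, flat, lineage, config.effective_threshold, rng)
    t_min, t_max = config.division_range
    if site == BLOCKED:
        run.cells[cell] = None
        return
    if site == OFF_LATTICE:
        run.off_lattice_births += 1
        run.push(t + rng.uniform(t_min, t_max), cell)
        return
    state.occupy(site, lineage)
    daughter = len(run.cells)
    run.cells.append((site, lineage))
    run.push(t + rng.uniform(t_min, t_max), cell)
    run.push(t + rng.uniform(t_min, t_max), daughter)


def run(config: SimConfig) -> SimResult:
    """Run a simulation to completion.

    Terminates when every site is occupied, when the event queue empties
    (possible only when blocked mothers are retired faster than space fills),
    or when ``max_events`` is exceeded (the result is then flagged
    truncated).
    """
    rng = np.random.default_rng(config.rng_seed)
    founders, state = seed_lattice(config, rng)
    r = schedule_initial_events(founders, config, rng)
    n_sites = config.width * config.height
    truncated = False
    while r.queue and state.n_occupied < n_sites:
        if config.max_events is not None and r.events >= config.max_events:
            truncated = True
            break
        step(state, r, config, rng)
    return _build_result(state, founders, r, truncated)


def _build_result(
    state: LatticeState, founders: pd.DataFrame, r: _Run, truncated: bool
) -> SimResult:
    ids = founders["lineage_id"].to_numpy()
    counts = np.bincount(state.occupancy.ravel(), minlength=ids.max() + 1)
    areas = pd.Series(counts[ids], index=ids, name="area_sites")
    edge = np.zeros(ids.max() + 1, dtype=bool)
    occ = state.occupancy
    for border in (occ[0, :], occ[-1, :], occ[:, 0], occ[:, -1]):
        edge[np.unique(border[border != EMPTY])] = True
    touches = pd.Series(edge[ids], index=ids, name="touches_edge")
    return SimResult(
        label_map=state.occupancy,
        founders=founders,
        areas=areas,
        touches_edge=touches,
        event_count=r.events,
        elapsed_min=r.time,
        occupancy_fraction=state.n_occupied / occ.size,
        truncated=truncated,
    )
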