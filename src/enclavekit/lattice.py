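"""Coarse-grained square-lattice model of colony growth and enclave formation.

Two founder daughters (chains 1 and 2) sit on adjacent sites of a square
lattice; every cell carries an absolute division timestamp drawn from a
log-normal clock.  At each event the earliest-dividing cell splits: one
daughter keeps the mother's site, the other takes a random empty site within
the placement range (Moore neighborhood by default), shoving a contiguous run
of cells outward by one site when the neighborhood is full.  Shove direction
is sampled with weight inversely proportional to the run length (fewer cells
to push is preferred), or uniformly in the alternative variant.

On-lattice demixing metrics (inter-enclave contact fraction, moving-box
Shannon entropy) mirror the off-lattice analytics in
:mod:`enclavekit.geometry`.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np

from ._utils import lognormal_params

# the 8 Moore directions, row-major order
_DIRECTIONS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class DivisionTimeModel:
    """Log-normal division-duration model parameterized by its arithmetic
    mean and SD (minutes).

    The defaults are the 25 C statistics (48 +- 13 min); the 37 C
    parameterization is (21 +- 6 min).  Both share a coefficient of
    variation of ~0.27-0.29.
    """

    mean: float = 48.0
    sd: float = 13.0

    def __post_init__(self):
        lognormal_params(self.mean, self.sd)  # validates

    @property
    def mu_sigma(self) -> tuple[float, float]:
        return lognormal_params(self.mean, self.sd)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw positive division durations (minutes)."""
        if self.sd == 0:
            return np.full(size, self.mean) if size is not None else self.mean
        mu, sigma = self.mu_sigma
        out = rng.lognormal(mu, sigma, size=size)
        return out if size is not None else float(out)


def sample_division_time(model: DivisionTimeModel, rng: np.random.Generator) -> float:
    """One division duration (min) from the log-normal clock."""
    return model.sample(rng)


@dataclass(frozen=True)
class SimVariant:
    """Simulation variant switches.

    placement_range   1 = Moore neighborhood; 2 = daughter may land up to two
                      lattice steps away (weakened sister adhesion variant).
    shove_weighting   "inverse_run" (weight ~ 1/run length) or "uniform".
    chain_rate_factor multiplier >= 1 applied to chain 2's mean division time
                      (SD scaled with it, preserving the CV), making chain 1
                      the faster-dividing lineage when > 1.
    """

    placement_range: int = 1
    shove_weighting: str = "inverse_run"
    chain_rate_factor: float = 1.0

    def __post_init__(self):
        if self.placement_range not in (1, 2):
            raise ValueError("placement_range must be 1 or 2")
        if self.shove_weighting not in ("inverse_run", "uniform"):
            raise ValueError("shove_weighting must be 'inverse_run' or 'uniform'")
        if self.chain_rate_factor < 1:
            raise ValueError("chain_rate_factor must be >= 1")


@dataclass
class _Cell:
    chain: int
    birth_time: float
    next_division: float
    site: tuple[int, int]


@dataclass
class LatticeColony:
    """Occupancy grid plus per-cell chain labels and division timestamps.

    Sites are absolute integer (i, j) coordinates; the backing array grows as
    shove runs reach its border, so there is no hard wall.
    """

    model: DivisionTimeModel
    variant: SimVariant
    rng: np.random.Generator
    cells: dict[int, _Cell] = field(default_factory=dict)
    grid: dict[tuple[int, int], int] = field(default_factory=dict)
    time: float = 0.0
    _heap: list = field(default_factory=list)
    _next_id: int = 1

    # -- construction -----------------------------------------------------
    @classmethod
    def from_sites(cls, sites, chains, model=None, variant=None, seed=0):
        """Build a colony from explicit sites/chain labels (for analysis and
        tests; division clocks are freshly sampled)."""
        colony = cls(model or DivisionTimeModel(), variant or SimVariant(),
                     np.random.default_rng(seed))
        for site, chain in zip(sites, chains):
            colony._add_cell(int(chain), tuple(site), birth_time=0.0)
        return colony

    # -- bookkeeping ------------------------------------------------------
    def _chain_model(self, chain: int) -> DivisionTimeModel:
        f = self.variant.chain_rate_factor
        if chain == 2 and f != 1.0:
            return replace(self.model, mean=self.model.mean * f, sd=self.model.sd * f)
        return self.model

    def _add_cell(self, chain: int, site: tuple[int, int], birth_time: float) -> int:
        if site in self.grid:
            raise ValueError(f"site {site} already occupied")
        cid = self._next_id
        self._next_id += 1
        nd = birth_time + sample_division_time(self._chain_model(chain), self.rng)
        self.cells[cid] = _Cell(chain, birth_time, nd, site)
        self.grid[site] = cid
        heapq.heappush(self._heap, (nd, cid))
        return cid

    def _reschedule(self, cid: int, birth_time: float):
        cell = self.cells[cid]
        cell.birth_time = birth_time
        cell.next_division = birth_time + sample_division_time(
            self._chain_model(cell.chain), self.rng)
        heapq.heappush(self._heap, (cell.next_division, cid))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def chain_counts(self) -> dict[int, int]:
        counts = {1: 0, 2: 0}
        for c in self.cells.values():
            counts[c.chain] = counts.get(c.chain, 0) + 1
        return counts

    def occupancy(self) -> np.ndarray:
        """(n, 3) array of i, j, chain."""
        return np.array([[c.site[0], c.site[1], c.chain] for c in self.cells.values()],
                        dtype=int)

    def snapshot(self):
        """Lightweight copy for trajectories: (time, occupancy array)."""
        return self.time, self.occupancy()


def init_colony(model: DivisionTimeModel, variant: SimVariant | None = None,
                seed: int = 0) -> LatticeColony:
    """Two sister cells: chain 1 at the grid center, chain 2 on a uniformly
    random Moore-neighborhood site (Chebyshev distance 1)."""
    variant = variant or SimVariant()
    rng = np.random.default_rng(seed)
    colony = LatticeColony(model, variant, rng)
    center = (12, 12)  # center of the nominal 25x25 starting grid
    colony._add_cell(1, center, birth_time=0.0)
    di, dj = _DIRECTIONS[rng.integers(len(_DIRECTIONS))]
    colony._add_cell(2, (center[0] + di, center[1] + dj), birth_time=0.0)
    return colony


def next_divider(colony: LatticeColony) -> int:
    """Id of the cell with the earliest division timestamp (ties -> lowest
    id, matching heap ordering on (time, id))."""
    if not colony.cells:
        raise ValueError("empty colony")
    while colony._heap:
        nd, cid = colony._heap[0]
        cell = colony.cells.get(cid)
        if cell is not None and cell.next_division == nd:
            return cid
        heapq.heappop(colony._heap)  # stale entry
    raise RuntimeError("scheduler heap exhausted")


def _run_length(colony: LatticeColony, site, direction) -> int:
    """Contiguous occupied sites from ``site`` outward along ``direction``
    until the first empty site (Chebyshev steps for diagonals)."""
    di, dj = direction
    i, j = site
    r = 0
    while True:
        i, j = i + di, j + dj
        if (i, j) not in colony.grid:
            return r
        r += 1


def shove(colony: LatticeColony, mother_site, variant: SimVariant | None = None,
          rng: np.random.Generator | None = None) -> tuple[int, int]:
    """Free the site adjacent to ``mother_site`` by translating a contiguous
    run of cells one site outward.

    Direction weights are proportional to 1/run-length ("inverse_run") or
    equal ("uniform").  Cell count and chain labels are conserved; the freed
    adjacent site is returned.
    """
    variant = variant or colony.variant
    rng = rng or colony.rng
    runs = np.array([_run_length(colony, mother_site, d) for d in _DIRECTIONS],
                    dtype=float)
    if np.any(runs == 0):
        raise ValueError("Moore neighborhood is not fully occupied; no shove needed")
    if variant.shove_weighting == "uniform":
        weights = np.ones_like(runs)
    else:
        weights = 1.0 / runs
    k = rng.choice(len(_DIRECTIONS), p=weights / weights.sum())
    di, dj = _DIRECTIONS[k]
    r = int(runs[k])
    i0, j0 = mother_site
    # translate the run outward, farthest cell first
    for step in range(r, 0, -1):
        src = (i0 + step * di, j0 + step * dj)
        dst = (i0 + (step + 1) * di, j0 + (step + 1) * dj)
        cid = colony.grid.pop(src)
        colony.grid[dst] = cid
        colony.cells[cid].site = dst
    return (i0 + di, j0 + dj)


def place_daughter(colony: LatticeColony, mother_site,
                   variant: SimVariant | None = None,
                   rng: np.random.Generator | None = None) -> tuple[int, int]:
    """Choose the new daughter's site: uniform over unoccupied sites within
    Chebyshev distance <= placement_range, shoving first if none is free."""
    variant = variant or colony.variant
    rng = rng or colony.rng
    i0, j0 = mother_site
    R = variant.placement_range
    free = [(i0 + di, j0 + dj)
            for di in range(-R, R + 1) for dj in range(-R, R + 1)
            if (di, dj) != (0, 0) and (i0 + di, j0 + dj) not in colony.grid]
    if free:
        return free[rng.integers(len(free))]
    return shove(colony, mother_site, variant, rng)


def step(colony: LatticeColony) -> int:
    """One division event: returns the new cell's id."""
    cid = next_divider(colony)
    mother = colony.cells[cid]
    colony.time = mother.next_division
    site = place_daughter(colony, mother.site)
    # one daughter keeps the mother's site (and id); both get fresh clocks
    colony._reschedule(cid, colony.time)
    return colony._add_cell(mother.chain, site, birth_time=colony.time)


def run(colony: LatticeColony, n_target: int, record: bool = True):
    """Grow by repeated division events until ``n_target`` cells; returns the
    list of (time, occupancy) snapshots (one per division; empty if
    ``record`` is False)."""
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    trajectory = [colony.snapshot()] if record else []
    while colony.n_cells < n_target:
        step(colony)
        if record:
            trajectory.append(colony.snapshot())
    return trajectory


# -- on-lattice demixing metrics ------------------------------------------

def lattice_interenclave_contacts(colony: LatticeColony) -> float:
    """Mean over cells of (opposite-chain Moore neighbors) / (occupied Moore
    neighbors); cells with no occupied neighbor are excluded."""
    if colony.n_cells < 2:
        raise ValueError("need at least 2 cells")
    fractions = []
    for cell in colony.cells.values():
        i, j = cell.site
        occ = opp = 0
        for di, dj in _DIRECTIONS:
            nid = colony.grid.get((i + di, j + dj))
            if nid is not None:
                occ += 1
                if colony.cells[nid].chain != cell.chain:
                    opp += 1
        if occ:
            fractions.append(opp / occ)
    return float(np.mean(fractions))


def lattice_entropy(colony: LatticeColony, box_cells: int = 4) -> float:
    """Moving-box Shannon entropy of the two chain labels over lattice sites.

    Boxes of ``box_cells`` x ``box_cells`` sites tile the occupied bounding
    box at half-box stride; occupied boxes contribute
    SE = -p1 ln p1 - p2 ln p2 and the colony value is their mean.
    """
    if colony.n_cells < 2:
        raise ValueError("need at least 2 cells")
    occ = colony.occupancy()
    from .geometry import moving_box_entropy  # shared SE kernel

    return moving_box_entropy(occ[:, :2].astype(float), occ[:, 2],
                              box=float(box_cells)).mean_se
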