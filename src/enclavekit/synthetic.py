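"""Ground-truthed synthetic inputs for the tracking and analysis pipeline.

Three generators:

* :func:`grow_rod_colony` -- an off-lattice colony of rod-shaped
  (spherocylindrical) cells that elongate exponentially, divide with
  log-normal division durations, stay in contact with their sisters, and
  relax pairwise overlaps by soft repulsion.  Frames are recorded at a fixed
  interval (3 min by default, mimicking time-lapse imaging of monolayer
  colonies) and can be rendered to 16-bit labeled masks; the full lineage
  (track ids, parents, progeny-chain labels rooted at the two founder
  daughters) is returned as ground truth.

* :func:`make_defect_field` -- analytic nematic director fields with a
  planted half-integer topological defect, for exercising winding-number
  charge detection.

* :func:`make_two_color_pattern` -- two-chain point patterns (demixed /
  random / striped) for Shannon-entropy comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from ._utils import lognormal_params, unit, wrap_nematic


@dataclass
class RodCell:
    """One rod cell at one instant (positions um, times min, angles rad)."""

    id: int
    parent: int | None
    chain: int
    center: np.ndarray          # (2,)
    axis_angle: float           # (-pi/2, pi/2]
    length: float               # pole-to-pole
    width: float
    birth_time: float
    division_time: float        # absolute
    growth_rate: float = 0.0    # per-cell exponential elongation rate (1/min)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if not self.length >= self.width > 0:
            raise ValueError("require length >= width > 0")
        if not self.division_time > self.birth_time:
            raise ValueError("division_time must exceed birth_time")

    def copy(self) -> "RodCell":
        return replace(self, center=self.center.copy())


@dataclass(frozen=True)
class GeneratorConfig:
    """Colony generator parameters.

    Division durations are log-normal with arithmetic ``mean_division`` /
    ``sd_division`` minutes (defaults: the 25 C statistics 48 +- 13; use
    21 +- 6 for 37 C).  ``elongation`` is the single-cell exponential length
    growth rate (1/min); by default (None) each cell gets the homeostatic
    rate ln 2 / its own division duration, so it exactly doubles its birth
    length before dividing (sizer-like size homeostasis — lengths stay in a
    realistic band instead of drifting with the division-clock noise).
    Frames are recorded every ``frame_interval`` minutes.  ``n_seeds = 2``
    starts two separate founder cells whose colonies merge (chains = the
    founder colonies).
    """

    mean_division: float = 48.0
    sd_division: float = 13.0
    elongation: float | None = None
    frame_interval: float = 3.0
    pixel_size: float = 0.1
    relaxation_iters: int = 60
    overlap_tolerance: float = 0.1
    n_target: int = 64
    seed: int = 0
    n_seeds: int = 1
    width: float = 1.0
    birth_length: float = 2.5
    division_angle_noise: float = 0.05

    def __post_init__(self):
        for name in ("mean_division", "frame_interval", "pixel_size",
                     "overlap_tolerance", "width", "birth_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sd_division < 0 or self.relaxation_iters < 1 or self.n_target < 2:
            raise ValueError("invalid config")
        if self.n_seeds not in (1, 2):
            raise ValueError("n_seeds must be 1 or 2")

    def cell_growth_rate(self, duration: float) -> float:
        """Elongation rate for a cell with the given division duration."""
        return (np.log(2) / duration
                if self.elongation is None else self.elongation)

    def sample_division(self, rng: np.random.Generator) -> float:
        if self.sd_division == 0:
            return self.mean_division
        mu, sigma = lognormal_params(self.mean_division, self.sd_division)
        return float(rng.lognormal(mu, sigma))


@dataclass
class ColonyFrame:
    """One recorded time point: cell states, and optionally a rendered mask.

    ``mask`` labels are 1-based indices into ``cells`` (label = index + 1);
    physical coordinates follow x = column * pixel_size, y = row * pixel_size
    relative to ``origin``.
    """

    index: int
    time: float
    cells: list[RodCell]
    mask: np.ndarray | None = None
    pixel_size: float | None = None
    origin: np.ndarray | None = None
    relaxed: bool = True

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.center for c in self.cells])

    @property
    def chains(self) -> np.ndarray:
        return np.array([c.chain for c in self.cells])


@dataclass
class GroundTruth:
    """Per-frame mask-label -> lineage mapping plus division events."""

    # per frame: list over labels (label-1 ordering) of (track, parent, chain)
    per_frame: list[list[tuple[int, int | None, int]]] = field(default_factory=list)
    # (frame index of first frame at/after the event, mother, (d1, d2), time)
    divisions: list[tuple[int, int, tuple[int, int], float]] = field(default_factory=list)

    def frame_table(self, frame: int):
        return {label + 1: rec for label, rec in enumerate(self.per_frame[frame])}

    def chain_of_track(self) -> dict[int, int]:
        out = {}
        for recs in self.per_frame:
            for track, _, chain in recs:
                out[track] = chain
        return out


# ---------------------------------------------------------------------------
# rod mechanics
# ---------------------------------------------------------------------------

def _segment_endpoints(centers, angles, lengths, widths):
    """Spine segments of spherocylinders: pole-to-pole length L means a
    spine of length L - w capped by radius w/2."""
    u = unit(angles)
    half = np.maximum(lengths - widths, 1e-9)[:, None] / 2.0
    return centers - half * u, centers + half * u


def _closest_points(p1, q1, p2, q2):
    """Vectorized closest points between segment pairs (Ericson)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, np.clip((b * f - c * e) /
                                        np.where(denom > 1e-12, denom, 1.0),
                                        0.0, 1.0), 0.0)
    t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    recompute = t != t_cl
    s = np.where(recompute & (a > 1e-12),
                 np.clip((b * t_cl - c) / np.where(a > 1e-12, a, 1.0), 0.0, 1.0),
                 s)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t_cl[:, None] * d2
    return c1, c2


def _relax(centers, angles, lengths, widths, tol, max_iters,
           k_push=0.6, k_rot=0.8):
    """Iteratively reduce pairwise rod overlaps below ``tol``.

    Synchronous updates: each overlapping pair pushes both cells apart along
    the line of minimum separation and applies a small torque from the
    contact lever arm.  Returns (centers, angles, converged).
    """
    n = len(centers)
    if n < 2:
        return centers, angles, True
    for _ in range(max_iters):
        p1s, q1s = _segment_endpoints(centers, angles, lengths, widths)
        tree = cKDTree(centers)
        pairs = tree.query_pairs(float(lengths.max() + widths.max()),
                                 output_type="ndarray")
        if len(pairs) == 0:
            return centers, angles, True
        i, j = pairs[:, 0], pairs[:, 1]
        c1, c2 = _closest_points(p1s[i], q1s[i], p1s[j], q1s[j])
        delta = c1 - c2
        dist = np.linalg.norm(delta, axis=1)
        overlap = (widths[i] + widths[j]) / 2.0 - dist
        active = overlap > tol
        if not active.any():
            return centers, angles, True
        i, j = i[active], j[active]
        delta, dist = delta[active], dist[active]
        overlap = overlap[active]
        c1, c2 = c1[active], c2[active]
        # direction of push; degenerate (coincident) contacts get a random-ish
        # perpendicular from the first cell's axis
        good = dist > 1e-9
        nvec = np.where(good[:, None], delta / np.where(good, dist, 1.0)[:, None],
                        np.column_stack([-np.sin(angles[i]), np.cos(angles[i])]))
        push = 0.5 * k_push * overlap[:, None] * nvec
        dc = np.zeros_like(centers)
        np.add.at(dc, i, push)
        np.add.at(dc, j, -push)
        # torque: contact lever arm crossed with the push force
        mid = 0.5 * (c1 + c2)
        r_i = mid - centers[i]
        r_j = mid - centers[j]
        fi = overlap * k_rot
        inertia_i = lengths[i] ** 2 / 12.0 + 1e-6
        inertia_j = lengths[j] ** 2 / 12.0 + 1e-6
        tq_i = (r_i[:, 0] * nvec[:, 1] - r_i[:, 1] * nvec[:, 0]) * fi / inertia_i
        tq_j = (r_j[:, 0] * -nvec[:, 1] - r_j[:, 1] * -nvec[:, 0]) * fi / inertia_j
        da = np.zeros_like(angles)
        np.add.at(da, i, tq_i)
        np.add.at(da, j, tq_j)
        max_step = 0.25 * widths.min()
        dc = np.clip(dc, -max_step, max_step)
        da = np.clip(da, -0.08, 0.08)
        centers = centers + dc
        angles = wrap_nematic(angles + da)
    return centers, angles, False


# ---------------------------------------------------------------------------
# colony growth
# ---------------------------------------------------------------------------

def grow_rod_colony(config: GeneratorConfig,
                    render: bool = True) -> tuple[list[ColonyFrame], GroundTruth]:
    """Grow a rod colony from the founder's two daughters to ``n_target``
    cells, recording one frame per ``frame_interval`` minutes.

    Returns the frame list (masks rendered on a shared origin when
    ``render``) and the complete ground-truth lineage.  Frames whose overlap
    relaxation did not converge within ``relaxation_iters`` are flagged
    (``ColonyFrame.relaxed = False``) with a warning, never silently.
    """
    rng = np.random.default_rng(config.seed)
    cells: list[RodCell] = []
    next_id = 1

    def new_cell(parent, chain, center, angle, length, t):
        nonlocal next_id
        duration = config.sample_division(rng)
        cell = RodCell(next_id, parent, chain, np.asarray(center, float),
                       float(wrap_nematic(angle)), length, config.width,
                       t, t + duration,
                       growth_rate=config.cell_growth_rate(duration))
        next_id += 1
        cells.append(cell)
        return cell

    if config.n_seeds == 1:
        # t = 0 is the birth of the founder's two daughters, end to end
        l0 = config.birth_length
        a0 = rng.uniform(-np.pi / 2, np.pi / 2)
        u0 = unit(a0)
        for chain, sgn in ((1, -1.0), (2, 1.0)):
            new_cell(None, chain, sgn * (l0 / 2) * u0, a0 +
                     rng.normal(0, config.division_angle_noise), l0, 0.0)
    else:
        # two separate founder cells whose colonies grow and merge
        gap = 6.0 * config.birth_length
        for chain, sgn in ((1, -1.0), (2, 1.0)):
            a = rng.uniform(-np.pi / 2, np.pi / 2)
            new_cell(None, chain, (sgn * gap / 2, 0.0), a,
                     config.birth_length, 0.0)

    truth = GroundTruth()
    frames: list[ColonyFrame] = []
    t = 0.0
    frame_idx = 0
    dt = min(1.0, config.frame_interval / 3.0)
    reached = len(cells) >= config.n_target
    pending_divisions: list[tuple[int, tuple[int, int], float]] = []

    def record_frame(relaxed):
        nonlocal frame_idx
        frame = ColonyFrame(frame_idx, t, [c.copy() for c in cells],
                            relaxed=relaxed)
        frames.append(frame)
        truth.per_frame.append([(c.id, c.parent, c.chain) for c in cells])
        for mother, daughters, tdiv in pending_divisions:
            truth.divisions.append((frame_idx, mother, daughters, tdiv))
        pending_divisions.clear()
        frame_idx += 1

    def relax_now():
        nonlocal cells
        centers = np.array([c.center for c in cells])
        angles = np.array([c.axis_angle for c in cells])
        lengths = np.array([c.length for c in cells])
        widths = np.array([c.width for c in cells])
        centers, angles, ok = _relax(centers, angles, lengths, widths,
                                     config.overlap_tolerance,
                                     config.relaxation_iters)
        for c, ce, an in zip(cells, centers, angles):
            c.center = ce
            c.axis_angle = float(an)
        return ok

    ok = relax_now()
    record_frame(ok)

    while not reached:
        # advance one frame interval in small substeps
        t_frame_end = frames[-1].time + config.frame_interval
        ok = True
        while t < t_frame_end - 1e-9:
            h = min(dt, t_frame_end - t)
            t += h
            for c in cells:
                c.length *= np.exp(c.growth_rate * h)
            if not reached:
                # process division events due by now, earliest first
                while True:
                    due = [c for c in cells if c.division_time <= t]
                    if not due or reached:
                        break
                    mother = min(due, key=lambda c: (c.division_time, c.id))
                    cells.remove(mother)
                    u = unit(mother.axis_angle)
                    l_half = mother.length / 2.0
                    d_ids = []
                    for sgn in (-1.0, 1.0):
                        d = new_cell(mother.id, mother.chain,
                                     mother.center + sgn * (mother.length / 4) * u,
                                     mother.axis_angle +
                                     rng.normal(0, config.division_angle_noise),
                                     max(l_half, config.width + 1e-6),
                                     mother.division_time)
                        d_ids.append(d.id)
                    pending_divisions.append((mother.id, tuple(d_ids),
                                              mother.division_time))
                    if len(cells) >= config.n_target:
                        reached = True
            ok = relax_now() and ok
        record_frame(ok)
        if not ok:
            warnings.warn(f"relaxation did not converge at frame {frame_idx - 1}")
        if reached:
            break

    if render:
        render_frames(frames, config.pixel_size)
    return frames, truth


def render_frames(frames: list[ColonyFrame], pixel_size: float,
                  margin: float = 2.0) -> None:
    """Rasterize all frames as 16-bit labeled masks on a shared origin.

    Cells are drawn as spherocylinders (pixels within width/2 of the spine
    segment); contested pixels go to the cell whose surface is nearest.
    Label = cell index in ``frame.cells`` + 1; background 0.
    """
    all_pts = np.vstack([f.centroids for f in frames])
    max_half = max(c.length for f in frames for c in f.cells) / 2.0 + margin
    lo = all_pts.min(axis=0) - max_half
    hi = all_pts.max(axis=0) + max_half
    origin = lo
    w = int(np.ceil((hi[0] - lo[0]) / pixel_size)) + 1
    h = int(np.ceil((hi[1] - lo[1]) / pixel_size)) + 1
    for frame in frames:
        mask = np.zeros((h, w), dtype=np.uint16)
        best = np.full((h, w), np.inf, dtype=float)
        for k, cell in enumerate(frame.cells):
            u = unit(cell.axis_angle)
            half = max(cell.length - cell.width, 1e-9) / 2.0
            p = cell.center - half * u
            q = cell.center + half * u
            r = cell.width / 2.0
            cmin = np.minimum(p, q) - r - pixel_size
            cmax = np.maximum(p, q) + r + pixel_size
            c0 = max(0, int((cmin[0] - origin[0]) / pixel_size))
            c1 = min(w - 1, int(np.ceil((cmax[0] - origin[0]) / pixel_size)))
            r0 = max(0, int((cmin[1] - origin[1]) / pixel_size))
            r1 = min(h - 1, int(np.ceil((cmax[1] - origin[1]) / pixel_size)))
            if c1 < c0 or r1 < r0:
                continue
            cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
            x = cols * pixel_size + origin[0]
            y = rows * pixel_size + origin[1]
            # distance from pixel centers to the spine segment
            d = q - p
            len2 = d @ d
            tpar = ((x - p[0]) * d[0] + (y - p[1]) * d[1]) / max(len2, 1e-12)
            tpar = np.clip(tpar, 0.0, 1.0)
            dx = x - (p[0] + tpar * d[0])
            dy = y - (p[1] + tpar * d[1])
            surf = np.hypot(dx, dy) - r
            inside = surf < 0
            sub_best = best[r0:r1 + 1, c0:c1 + 1]
            take = inside & (surf < sub_best)
            sub_best[take] = surf[take]
            mask[r0:r1 + 1, c0:c1 + 1][take] = k + 1
        frame.mask = mask
        frame.pixel_size = pixel_size
        frame.origin = origin.copy()


# ---------------------------------------------------------------------------
# planted defect fields
# ---------------------------------------------------------------------------

def make_defect_field(charge: float, core, phase: float = 0.0,
                      shape=(128, 128)):
    """Analytic nematic director field with one planted defect.

    Phi(x, y) = charge * atan2(y - y0, x - x0) + phase, wrapped to
    (-pi/2, pi/2]; the core pixel is masked invalid.  ``charge`` must be a
    half-integer multiple (including 0); ``core`` = (x, y) in pixels.
    """
    from .nematics import OrientationField

    if abs(charge * 2 - round(charge * 2)) > 1e-9:
        raise ValueError("charge must be a half-integer")
    h, w = shape
    x0, y0 = core
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError("core must lie inside the field")
    yy, xx = np.mgrid[0:h, 0:w]
    phi = wrap_nematic(charge * np.arctan2(yy - y0, xx - x0) + phase)
    valid = np.ones(shape, dtype=bool)
    valid[int(round(y0)), int(round(x0))] = False
    return OrientationField(phi, valid, pixel_size=1.0)


# ---------------------------------------------------------------------------
# two-color point patterns
# ---------------------------------------------------------------------------

def make_two_color_pattern(n: int, layout: str = "demixed",
                           seed: int = 0, cell_area: float = 3.0) -> ColonyFrame:
    """Two-chain centroid pattern in a disc for entropy comparisons.

    layouts: ``demixed`` (half-plane split), ``random`` (balanced labels
    permuted over the same positions), ``striped`` (alternating bands of
    ~2 cell widths).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if layout not in ("demixed", "random", "striped"):
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    radius = np.sqrt(n * cell_area / np.pi)
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=(2 * n, 2))
        cand = cand[np.hypot(cand[:, 0], cand[:, 1]) < radius]
        pts.extend(cand.tolist())
    pts = np.array(pts[:n])
    order = np.argsort(pts[:, 0])
    chains = np.empty(n, dtype=int)
    if layout == "demixed":
        chains[order[: n // 2]] = 1
        chains[order[n // 2:]] = 2
    elif layout == "random":
        chains[: n // 2] = 1
        chains[n // 2:] = 2
        rng.shuffle(chains)
    else:
        band = 2.0 * np.sqrt(cell_area)
        chains = (np.floor(pts[:, 0] / band).astype(int) % 2) + 1
    cells = []
    for k, (p, ch) in enumerate(zip(pts, chains)):
        cells.append(RodCell(k + 1, None, int(ch), p,
                             0.0, 1.0, 1.0, 0.0, 1.0))
    return ColonyFrame(0, 0.0, cells)
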