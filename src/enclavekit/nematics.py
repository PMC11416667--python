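"""Orientation-field analysis and topological defect detection.

A dense colony of rods behaves as an active nematic: per-pixel orientation
Phi in (-pi/2, pi/2] comes from the structure tensor (Gaussian window about
one quarter of a cell), local alignment is summarized by the scalar order
parameter

    S_R = sqrt(<cos 2 Phi>_R^2 + <sin 2 Phi>_R^2),   0 <= S_R <= 1,

on a moving grid of windows holding ~3-4 cells, and defect cores are mined
from local minima of S_R below 0.3 and confirmed by the winding number
(topological charge) q of the director around a loop; only q = +-1/2 occurs
in these colonies.  Defects are grouped by location (interface CI, colony
boundary CO, bulk CB) and linked frame to frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from shapely.geometry import LineString, Point
from skimage.feature import structure_tensor

from ._utils import wrap_nematic


@dataclass
class OrientationField:
    """Per-pixel nematic angle (defined modulo pi) plus validity mask."""

    phi: np.ndarray
    valid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        if self.phi.shape != self.valid.shape:
            raise ValueError("phi and valid must share a shape")


@dataclass
class OrderGrid:
    """Gridded scalar order parameter S_R (NaN where a window was skipped)."""

    s: np.ndarray             # (ny, nx)
    centers_x: np.ndarray     # (nx,) um
    centers_y: np.ndarray     # (ny,) um
    window: float             # um
    stride: float             # um


@dataclass
class Defect:
    x: float                  # um
    y: float
    q: float                  # +-1/2
    frame: int = 0
    s_core: float = float("nan")
    residual: float = 0.0     # raw winding minus the quantized charge
    cls: str | None = None    # CI / CO / CB
    track: int | None = None


# ---------------------------------------------------------------------------

def mask_to_intensity(mask: np.ndarray) -> np.ndarray:
    """Pseudo phase-contrast intensity from a labeled mask: per-cell distance
    transform (bright ridges along cell axes), with boundaries between
    touching cells kept dark."""
    fg = mask > 0
    # zero out pixels whose 4-neighborhood contains a different nonzero label
    boundary = np.zeros_like(fg)
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rolled = np.roll(mask, shift, axis=ax)
        boundary |= fg & (rolled != mask) & (rolled > 0)
    interior = fg & ~boundary
    return ndi.distance_transform_edt(interior).astype(float)


def structure_tensor_orientation(image: np.ndarray, cell_size: float,
                                 pixel_size: float = 1.0,
                                 mask: np.ndarray | None = None,
                                 energy_rtol: float = 1e-6) -> OrientationField:
    """Per-pixel orientation from the Gaussian-averaged structure tensor.

    sigma = cell_size / 4 (in um, converted to pixels).  The orientation is
    the eigenvector of the *smaller* eigenvalue (along elongated
    structures), wrapped to (-pi/2, pi/2].  Pixels outside ``mask`` or with
    vanishing gradient energy are invalid.
    """
    sigma = max(cell_size / 4.0 / pixel_size, 0.5)
    arr = np.asarray(image, dtype=float)
    arr_rr, arr_rc, arr_cc = structure_tensor(arr, sigma=sigma, order="rc")
    jxx, jxy, jyy = arr_cc, arr_rc, arr_rr        # (x, y) = (col, row)
    # dominant-gradient direction, then rotate 90 deg to follow structures
    theta_grad = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
    phi = wrap_nematic(theta_grad + np.pi / 2.0)
    energy = jxx + jyy
    scale = float(np.ptp(arr))
    floor = max(energy_rtol * energy.max(), (1e-6 * scale) ** 2, 1e-300)
    valid = energy > floor if scale > 0 else np.zeros_like(energy, dtype=bool)
    if mask is not None:
        valid &= mask > 0
    return OrientationField(phi, valid, pixel_size)


def order_grid(field: OrientationField, window: float,
               stride: float | None = None, min_valid: int = 10) -> OrderGrid:
    """Moving-grid nematic order parameter.

    ``window`` (um) should hold roughly 3-4 cells; ``stride`` defaults to
    window/3 (never larger, per the moving-grid rule).  Windows with fewer
    than ``min_valid`` valid pixels are skipped (NaN).
    """
    px = field.pixel_size
    wpx = max(2, int(round(window / px)))
    # steps no coarser than a third of the window
    spx = max(1, int(np.floor((window / 3.0 if stride is None else stride) / px)))
    h, w = field.phi.shape
    c2 = np.where(field.valid, np.cos(2 * field.phi), 0.0)
    s2 = np.where(field.valid, np.sin(2 * field.phi), 0.0)
    ii = np.zeros((h + 1, w + 1, 3))
    for k, plane in enumerate((c2, s2, field.valid.astype(float))):
        ii[1:, 1:, k] = plane.cumsum(0).cumsum(1)
    ys = np.arange(0, max(h - wpx, 0) + 1, spx)
    xs = np.arange(0, max(w - wpx, 0) + 1, spx)
    s = np.full((len(ys), len(xs)), np.nan)
    for a, y0 in enumerate(ys):
        y1 = y0 + wpx
        for b, x0 in enumerate(xs):
            x1 = x0 + wpx
            box = ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]
            n = box[2]
            if n >= min_valid:
                s[a, b] = np.hypot(box[0] / n, box[1] / n)
    centers_x = (xs + wpx / 2.0) * px
    centers_y = (ys + wpx / 2.0) * px
    return OrderGrid(s, centers_x, centers_y, wpx * px, spx * px)


def defect_candidates(grid: OrderGrid, threshold: float = 0.3) -> list[tuple[float, float, float]]:
    """Candidate defect cores: local minima of S_R among sub-threshold
    windows, with non-maximum suppression within one window size.

    Returns (x um, y um, S) tuples.
    """
    s = grid.s
    low = s <= threshold
    sf = np.where(np.isnan(s), np.inf, s)
    mins = np.ones_like(low)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            shifted = np.full_like(sf, np.inf)
            ys = slice(max(dy, 0), sf.shape[0] + min(dy, 0))
            yd = slice(max(-dy, 0), sf.shape[0] + min(-dy, 0))
            xs = slice(max(dx, 0), sf.shape[1] + min(dx, 0))
            xd = slice(max(-dx, 0), sf.shape[1] + min(-dx, 0))
            shifted[yd, xd] = sf[ys, xs]
            mins &= sf <= shifted
    cand = np.argwhere(low & mins & np.isfinite(sf))
    points = [(grid.centers_x[x], grid.centers_y[y], sf[y, x]) for y, x in cand]
    points.sort(key=lambda p: p[2])
    kept = []
    min_sep = grid.window
    for x, y, v in points:
        if all(np.hypot(x - kx, y - ky) >= min_sep for kx, ky, _ in kept):
            kept.append((float(x), float(y), float(v)))
    return kept


def _square_loop(cy: int, cx: int, r: int):
    """Pixels of a square ring of radius r around (cy, cx), ordered by
    increasing atan2(y - cy, x - cx) — i.e. counterclockwise in the same
    (x, y) convention used for the orientation angles."""
    ring = []
    for x in range(cx - r, cx + r + 1):
        ring.append((cy - r, x))
        ring.append((cy + r, x))
    for y in range(cy - r + 1, cy + r):
        ring.append((y, cx - r))
        ring.append((y, cx + r))
    ring.sort(key=lambda p: np.arctan2(p[0] - cy, p[1] - cx))
    return ring


def topological_charge(field: OrientationField, point,
                       loop_radius: int = 3, max_escalation: int = 3):
    """Winding-number charge of the director around ``point`` (x, y in um).

    Sums nematically wrapped angle increments delta Phi in (-pi/2, pi/2]
    around a counterclockwise square loop; q = total / (2 pi), rounded to
    the nearest half-integer with the raw residual reported.  Loops crossing
    invalid pixels escalate the radius up to ``max_escalation`` times before
    failing (returns None).
    """
    px = field.pixel_size
    cx = int(round(point[0] / px))
    cy = int(round(point[1] / px))
    h, w = field.phi.shape
    for mult in range(1, max_escalation + 1):
        r = loop_radius * mult
        if cy - r < 0 or cx - r < 0 or cy + r >= h or cx + r >= w:
            continue
        ring = _square_loop(cy, cx, r)
        ys = np.array([p[0] for p in ring])
        xs = np.array([p[1] for p in ring])
        if not field.valid[ys, xs].all():
            continue
        phi = field.phi[ys, xs]
        dphi = wrap_nematic(np.diff(np.r_[phi, phi[0]]))
        raw = float(dphi.sum() / (2 * np.pi))
        q = round(raw * 2) / 2.0
        return q, raw - q
    warnings.warn(f"no valid winding loop around {point}")
    return None


def detect_defects(field: OrientationField, grid: OrderGrid,
                   threshold: float = 0.3, loop_radius: int = 3,
                   frame: int = 0) -> list[Defect]:
    """Candidate mining + charge confirmation; keeps |q| = 1/2 cores."""
    defects = []
    for x, y, s_core in defect_candidates(grid, threshold):
        res = topological_charge(field, (x, y), loop_radius)
        if res is None:
            continue
        q, residual = res
        if abs(q) == 0.5:
            defects.append(Defect(x, y, q, frame, s_core, residual))
    return defects


def classify_and_group(defects: list[Defect], interface,
                       boundary, d_i: float = 1.5,
                       boundary_margin: float | None = None) -> list[Defect]:
    """Assign each defect a location class: CI when within ``d_i`` um of the
    enclave interface, else CO when within the boundary margin (default
    d_i) of the colony outline, else CB (bulk)."""
    margin = d_i if boundary_margin is None else boundary_margin
    iface = (interface if isinstance(interface, LineString)
             else LineString(np.asarray(interface)))
    bnd = boundary.exterior if hasattr(boundary, "exterior") else (
        boundary if isinstance(boundary, LineString)
        else LineString(np.asarray(boundary)))
    for d in defects:
        p = Point(d.x, d.y)
        if iface.distance(p) <= d_i:
            d.cls = "CI"
        elif bnd.distance(p) <= margin:
            d.cls = "CO"
        else:
            d.cls = "CB"
    return defects


@dataclass
class DefectTrack:
    id: int
    q: float
    points: list = field(default_factory=list)   # (frame, x, y)

    @property
    def displacements(self) -> np.ndarray:
        pts = np.array([[x, y] for _, x, y in self.points])
        if len(pts) < 2:
            return np.zeros(0)
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    @property
    def total_displacement(self) -> float:
        return float(self.displacements.sum())


def track_defects(per_frame: list[list[Defect]],
                  max_step: float = 3.0) -> list[DefectTrack]:
    """Greedy nearest-neighbor linking of same-charge defects across
    consecutive frames; links farther than ``max_step`` um are refused."""
    tracks: list[DefectTrack] = []
    active: dict[int, DefectTrack] = {}
    next_id = 1
    prev_defects: list[Defect] = []
    for f, defects in enumerate(per_frame):
        new_active: dict[int, DefectTrack] = {}
        cand = []
        for di, d in enumerate(defects):
            for pi, p in enumerate(prev_defects):
                if p.q != d.q or p.track is None:
                    continue
                dist = np.hypot(d.x - p.x, d.y - p.y)
                if dist <= max_step:
                    cand.append((dist, pi, di))
        cand.sort()
        taken_p, taken_d = set(), set()
        for dist, pi, di in cand:
            if pi in taken_p or di in taken_d:
                continue
            taken_p.add(pi)
            taken_d.add(di)
            tr = active[prev_defects[pi].track]
            d = defects[di]
            d.track = tr.id
            tr.points.append((f, d.x, d.y))
            new_active[tr.id] = tr
        for di, d in enumerate(defects):
            if di in taken_d:
                continue
            tr = DefectTrack(next_id, d.q, [(f, d.x, d.y)])
            next_id += 1
            d.track = tr.id
            tracks.append(tr)
            new_active[tr.id] = tr
        active = new_active
        prev_defects = defects
    return tracks
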