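"""Label-free lineage tracking from integer-labeled segmentation masks.

The tracker links cells across consecutive frames in three stages:

1. centroid matching -- a pair is linked when each is the *only* cell of the
   other frame within the centroid cutoff d_c (mutual uniqueness; default
   0.75 um, of the order of a cell width);
2. division detection -- an unmatched cell's two "dummy centroids" (the
   predicted daughter centroids at +-l_c/4 along its axis) are matched to
   two distinct unassigned next-frame centroids within d_c;
3. pole rescue -- remaining cells (typically boundary cells with room to
   slide) are linked when centroid and both pole displacements stay within
   the pole cutoff.

Cells that survive all three stages unlinked are reported as unresolved,
never silently dropped.  Progeny chains 1 and 2 are rooted at the two cells
of frame 0 (the founder's daughters) and inherited at every division.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage import measure, morphology

from ._utils import unit, wrap_nematic


@dataclass
class CellRecord:
    """Per-cell features extracted from one labeled frame (um units)."""

    frame: int
    label: int
    centroid: np.ndarray        # (2,) x, y
    area: float                 # um^2
    length: float               # pole-to-pole l_c
    width: float                # 4 a_c / (pi l_c)
    orientation: float          # (-pi/2, pi/2]
    poles: np.ndarray           # (2, 2)
    contour: np.ndarray         # (n, 2) closed polygon
    length_ellipse: float = 0.0  # fitted-ellipse major axis (cross-check)
    width_ellipse: float = 0.0   # fitted-ellipse minor axis (cross-check)
    on_border: bool = False


@dataclass(frozen=True)
class TrackingConfig:
    centroid_cutoff: float = 0.75       # d_c, um
    pole_cutoff: float = 1.5            # um (2 x d_c)
    dummy_offset_fraction: float = 0.25  # of l_c

    def __post_init__(self):
        if min(self.centroid_cutoff, self.pole_cutoff,
               self.dummy_offset_fraction) <= 0:
            raise ValueError("all tracking cutoffs must be positive")


@dataclass
class _Track:
    id: int
    chain: int | None
    parent: int | None
    members: list = field(default_factory=list)   # (frame, label)


@dataclass
class LineageForest:
    """Tracks, parent links and chain labels over all frames."""

    assignments: dict = field(default_factory=dict)   # (frame, label) -> track
    tracks: dict = field(default_factory=dict)        # track id -> _Track
    divisions: list = field(default_factory=list)     # (frame, mother, (d1, d2))
    unresolved: list = field(default_factory=list)    # (frame, label, reason)

    def chain_of(self, frame: int, label: int):
        tid = self.assignments.get((frame, label))
        return None if tid is None else self.tracks[tid].chain

    def frame_chains(self, frame: int) -> dict[int, int]:
        """Mapping label -> chain for one frame (resolved cells only)."""
        return {label: self.tracks[tid].chain
                for (f, label), tid in self.assignments.items()
                if f == frame and self.tracks[tid].chain is not None}


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_features(mask: np.ndarray, pixel_size: float,
                     frame: int = 0) -> list[CellRecord]:
    """One :class:`CellRecord` per mask label.

    Length is the pole-to-pole distance (poles = contour points with extreme
    projection on the major axis); width follows w_c = 4 a_c / (pi l_c) and
    is cross-checked against the fitted-ellipse minor axis.  Border-touching
    labels are flagged; single-pixel labels are rejected with a warning.
    """
    px = float(pixel_size)
    records = []
    h, w = mask.shape
    for region in measure.regionprops(mask):
        if region.area < 2:
            warnings.warn(f"label {region.label}: single-pixel region rejected")
            continue
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        on_border = bool(rows.min() == 0 or cols.min() == 0 or
                         rows.max() == h - 1 or cols.max() == w - 1)
        centroid = np.array([cols.mean(), rows.mean()]) * px
        area = region.area * px * px
        # orientation from xy central moments
        xc, yc = cols.mean(), rows.mean()
        mu20 = np.mean((cols - xc) ** 2)
        mu02 = np.mean((rows - yc) ** 2)
        mu11 = np.mean((cols - xc) * (rows - yc))
        theta = float(wrap_nematic(0.5 * np.arctan2(2 * mu11, mu20 - mu02)))
        # contour in global um coordinates
        r0, c0, _, _ = region.bbox
        sub = np.pad(region.image, 1)
        contours = measure.find_contours(sub.astype(float), 0.5)
        contour_px = max(contours, key=len) + np.array([r0 - 1, c0 - 1])
        contour = np.column_stack([contour_px[:, 1], contour_px[:, 0]]) * px
        # poles: extreme projections of the contour on the major axis
        u = unit(theta)
        proj = (contour - centroid) @ u
        pole1 = contour[int(np.argmax(proj))]
        pole2 = contour[int(np.argmin(proj))]
        poles = np.array([pole1, pole2])
        length = float(np.linalg.norm(pole1 - pole2))
        width = float(4.0 * area / (np.pi * length)) if length > 0 else 0.0
        records.append(CellRecord(
            frame, int(region.label), centroid, float(area), length, width,
            theta, poles, contour,
            length_ellipse=float(region.axis_major_length * px),
            width_ellipse=float(region.axis_minor_length * px),
            on_border=on_border))
    return records


# ---------------------------------------------------------------------------
# matching stages
# ---------------------------------------------------------------------------

def match_frames(prev: list[CellRecord], next_: list[CellRecord],
                 cfg: TrackingConfig | None = None):
    """Mutual-uniqueness centroid matching.

    Returns (assignment {prev index -> next index}, unmatched prev indices,
    unassigned next indices).  A pair is accepted only when each cell is the
    single cell of the other frame within the cutoff — the strict reading of
    looking for the "only" candidate, which prevents chain swaps when two
    cells straddle one.
    """
    cfg = cfg or TrackingConfig()
    if not prev or not next_:
        return {}, list(range(len(prev))), list(range(len(next_)))
    pc = np.array([r.centroid for r in prev])
    nc = np.array([r.centroid for r in next_])
    tree_n = cKDTree(nc)
    neigh_p = tree_n.query_ball_point(pc, cfg.centroid_cutoff)
    tree_p = cKDTree(pc)
    neigh_n = tree_p.query_ball_point(nc, cfg.centroid_cutoff)
    assignment = {}
    for i, cand in enumerate(neigh_p):
        if len(cand) == 1 and len(neigh_n[cand[0]]) == 1 and neigh_n[cand[0]][0] == i:
            assignment[i] = cand[0]
    unmatched = [i for i in range(len(prev)) if i not in assignment]
    assigned = set(assignment.values())
    unassigned = [j for j in range(len(next_)) if j not in assigned]
    return assignment, unmatched, unassigned


def dummy_centroids(cell: CellRecord, cfg: TrackingConfig | None = None) -> np.ndarray:
    """Predicted daughter centroids at +-(offset fraction * l_c) along the
    major axis (the exact positions for a symmetric end-to-end split)."""
    cfg = cfg or TrackingConfig()
    u = unit(cell.orientation)
    off = cfg.dummy_offset_fraction * cell.length
    return np.array([cell.centroid + off * u, cell.centroid - off * u])


def detect_divisions(prev: list[CellRecord], next_: list[CellRecord],
                     unmatched: list[int], unassigned: list[int],
                     cfg: TrackingConfig | None = None):
    """Match unmatched mothers to daughter pairs through dummy centroids.

    Dummy-to-centroid candidate pairs within d_c are assigned greedily by
    distance (globally, so adjacent simultaneous divisions cannot steal each
    other's daughters).  A mother is resolved only when both dummies claim
    distinct daughters; single-dummy matches are released and deferred to
    pole rescue.

    Returns (events [(mother idx, (d1 idx, d2 idx))], remaining unmatched,
    remaining unassigned).
    """
    cfg = cfg or TrackingConfig()
    if not unmatched or len(unassigned) < 2:
        return [], list(unmatched), list(unassigned)
    cand = []
    for i in unmatched:
        for k, dummy in enumerate(dummy_centroids(prev[i], cfg)):
            for j in unassigned:
                d = np.linalg.norm(next_[j].centroid - dummy)
                if d < cfg.centroid_cutoff:
                    cand.append((d, i, k, j))
    cand.sort()
    dummy_taken, cell_taken = set(), set()
    claims: dict[int, dict[int, int]] = {}
    for d, i, k, j in cand:
        if (i, k) in dummy_taken or j in cell_taken:
            continue
        dummy_taken.add((i, k))
        cell_taken.add(j)
        claims.setdefault(i, {})[k] = j
    events = []
    for i, got in claims.items():
        if len(got) == 2:
            events.append((i, (got[0], got[1])))
    used_next = {j for _, pair in events for j in pair}
    mothers = {i for i, _ in events}
    rem_unmatched = [i for i in unmatched if i not in mothers]
    rem_unassigned = [j for j in unassigned if j not in used_next]
    return events, rem_unmatched, rem_unassigned


def match_by_poles(prev: list[CellRecord], next_: list[CellRecord],
                   unmatched: list[int], unassigned: list[int],
                   cfg: TrackingConfig | None = None):
    """Rescue fast movers: a pair is accepted when the centroid displacement
    and both pole displacements (best pole pairing) are below the pole
    cutoff; candidates are taken greedily by total displacement."""
    cfg = cfg or TrackingConfig()
    cand = []
    for i in unmatched:
        for j in unassigned:
            dc = np.linalg.norm(next_[j].centroid - prev[i].centroid)
            if dc >= cfg.pole_cutoff:
                continue
            pp, pn = prev[i].poles, next_[j].poles
            direct = [np.linalg.norm(pn[0] - pp[0]), np.linalg.norm(pn[1] - pp[1])]
            crossed = [np.linalg.norm(pn[1] - pp[0]), np.linalg.norm(pn[0] - pp[1])]
            d1, d2 = min(direct, crossed, key=lambda p: p[0] + p[1])
            if d1 < cfg.pole_cutoff and d2 < cfg.pole_cutoff:
                cand.append((dc + d1 + d2, i, j))
    cand.sort()
    assignment = {}
    taken_i, taken_j = set(), set()
    for _, i, j in cand:
        if i in taken_i or j in taken_j:
            continue
        assignment[i] = j
        taken_i.add(i)
        taken_j.add(j)
    rem_unmatched = [i for i in unmatched if i not in taken_i]
    rem_unassigned = [j for j in unassigned if j not in taken_j]
    return assignment, rem_unmatched, rem_unassigned


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def build_progeny_chains(frames: list[list[CellRecord]],
                         cfg: TrackingConfig | None = None) -> LineageForest:
    """Run the three matching stages over all frame pairs and emit the
    lineage forest with chains 1 and 2 rooted at the two frame-0 cells.

    Frame 0 must contain exactly two cells (t = 0 is the birth of the
    founder's two daughters, or the two founders in a merging-colonies
    scenario); anything else raises.
    """
    cfg = cfg or TrackingConfig()
    if len(frames[0]) != 2:
        raise ValueError(
            "frame 0 must contain exactly 2 cells (tracking starts when the "
            f"founder's two daughters are born); got {len(frames[0])}")
    forest = LineageForest()
    next_tid = 1

    def new_track(chain, parent, frame, label):
        nonlocal next_tid
        tr = _Track(next_tid, chain, parent, [(frame, label)])
        forest.tracks[next_tid] = tr
        forest.assignments[(frame, label)] = next_tid
        next_tid += 1
        return tr.id

    roots = sorted(frames[0], key=lambda r: r.label)
    for chain, rec in enumerate(roots, start=1):
        new_track(chain, None, 0, rec.label)

    for f in range(len(frames) - 1):
        prev, nxt = frames[f], frames[f + 1]
        assignment, unmatched, unassigned = match_frames(prev, nxt, cfg)
        events, unmatched, unassigned = detect_divisions(
            prev, nxt, unmatched, unassigned, cfg)
        rescued, unmatched, unassigned = match_by_poles(
            prev, nxt, unmatched, unassigned, cfg)
        assignment.update(rescued)

        for i, j in assignment.items():
            tid = forest.assignments.get((f, prev[i].label))
            if tid is None:
                continue
            forest.tracks[tid].members.append((f + 1, nxt[j].label))
            forest.assignments[(f + 1, nxt[j].label)] = tid
        for i, (j1, j2) in events:
            mother = forest.assignments.get((f, prev[i].label))
            chain = forest.tracks[mother].chain if mother else None
            d1 = new_track(chain, mother, f + 1, nxt[j1].label)
            d2 = new_track(chain, mother, f + 1, nxt[j2].label)
            forest.divisions.append((f + 1, mother, (d1, d2)))
        for i in unmatched:
            forest.unresolved.append((f, prev[i].label, "track lost"))
        for j in unassigned:
            # start an anonymous, chainless track so the cell keeps an identity
            new_track(None, None, f + 1, nxt[j].label)
            forest.unresolved.append((f + 1, nxt[j].label, "unresolved origin"))
    return forest


def track_masks(masks, pixel_size: float,
                cfg: TrackingConfig | None = None):
    """Convenience wrapper: feature extraction + chain building from a
    sequence of labeled masks.  Returns (forest, per-frame records)."""
    frames = [extract_features(m, pixel_size, frame=i)
              for i, m in enumerate(masks)]
    return build_progeny_chains(frames, cfg), frames


# ---------------------------------------------------------------------------
# colony boundary
# ---------------------------------------------------------------------------

def colony_boundary(mask: np.ndarray, pixel_size: float,
                    closing_radius_px: int = 3):
    """Outer colony boundary by dilation + hole filling + erosion.

    Returns a list of (polygon, perimeter um, area um^2) per connected
    colony, largest first; multiple disjoint colonies are flagged with a
    warning.
    """
    from .geometry import _largest_contour

    binary = mask > 0
    selem = morphology.disk(closing_radius_px)
    closed = ndi.binary_erosion(
        ndi.binary_fill_holes(ndi.binary_dilation(binary, selem)), selem)
    labeled, n = ndi.label(closed)
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        warnings.warn(f"{n} disjoint colonies found")
    out = []
    for k in range(1, n + 1):
        contour = _largest_contour(labeled == k)
        xy = np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size
        poly = Polygon(xy).buffer(0)
        out.append((poly, float(poly.exterior.length), float(poly.area)))
    out.sort(key=lambda t: -t[2])
    return out
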