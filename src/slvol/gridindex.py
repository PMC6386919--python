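"""Integer grid indexing of detected laser dots and missing-dot imputation.

Each detected dot receives integer lattice coordinates (i, j) relative to
the brighter centre dot at (0, 0).  The four nearest neighbours of the
centre define the two grid axes.  Assignment then grows breadth-first
from the centre: each assigned dot predicts its four lattice neighbours
using locally re-estimated axis vectors (the step actually observed one
cell earlier), and the nearest unassigned dot within an acceptance
radius of 0.45 x pitch claims the index.  Local prediction keeps the
assignment correct under the smooth pixel shifts that surface depth
imposes along the camera-projector baseline, where a single global
affine lattice would mis-assign the baseline-axis index; on planar
scenes the two coincide.  Dots the growth cannot reach (e.g. across a
sharp depth discontinuity) are dropped with a warning rather than
mis-indexed.

Missing interior indices are imputed from the pixel positions of the
nearest available dots along both grid axes; a grid less than half
occupied raises a rescan-recommended flag.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .detect import LaserDot
from .geometry import SlvolError

__all__ = [
    "NoCenterError",
    "DegenerateGridError",
    "GridConfig",
    "DotGrid",
    "index_dots",
    "impute_missing",
]


class NoCenterError(SlvolError):
    pass


class DegenerateGridError(SlvolError):
    pass


@dataclass
class GridConfig:
    rows: int = 11
    cols: int = 11
    accept_frac: float = 0.45       # acceptance radius as a pitch fraction
    accept_frac_u: float = 0.6      # looser bound along the baseline axis
    accept_frac_v: float = 0.35     # strict bound across rows (no disparity)
    occupancy_rescan: float = 0.5   # below this occupancy, recommend rescan

    @property
    def half_i(self) -> int:
        return (self.cols - 1) // 2

    @property
    def half_j(self) -> int:
        return (self.rows - 1) // 2


@dataclass
class DotGrid:
    """Indexed dots: map (i, j) -> LaserDot, centre at (0, 0)."""

    dots: dict
    imputed: set = field(default_factory=set)
    axes: tuple | None = None        # (u, v) pixel-space axis vectors
    dropped: int = 0
    rescan_recommended: bool = False
    warnings: list = field(default_factory=list)

    def positions(self) -> np.ndarray:
        return np.array([[d.x_px, d.y_px] for d in self.dots.values()])

    def occupancy(self, cfg: GridConfig) -> float:
        return len(self.dots) / float(cfg.rows * cfg.cols)


def _pick_axes(center_xy, neighbour_xy):
    """Two grid axis vectors from the four nearest centre neighbours.

    Canonical orientation: u is the more horizontal axis with positive x,
    v the other with positive y (pixel y grows downward), so calibration
    and scan frames agree on the index convention.
    """
    vecs = neighbour_xy - center_xy
    # primary axis: the nearest neighbour
    order = np.argsort(np.linalg.norm(vecs, axis=1))
    u = vecs[order[0]]
    nu = np.linalg.norm(u)
    best, best_sin = None, 0.0
    for k in order[1:]:
        w = vecs[k]
        s = abs(u[0] * w[1] - u[1] * w[0]) / (nu * np.linalg.norm(w))
        if s > best_sin:
            best_sin, best = s, w
    if best is None or best_sin < 0.17:  # under ~10 degrees: collinear
        raise DegenerateGridError("centre neighbours are collinear")
    v = best
    if abs(u[0]) < abs(v[0]):
        u, v = v, u
    if u[0] < 0:
        u = -u
    if v[1] < 0:
        v = -v
    return np.asarray(u, float), np.asarray(v, float)


def _degraded_single_axis(dots, center, cfg):
    """Fewer than five dots: index along the single dominant direction."""
    grid = {(0, 0): center}
    others = [d for d in dots if d is not center]
    if not others:
        return DotGrid(dots=grid, axes=None)
    c = np.array([center.x_px, center.y_px])
    vecs = np.array([[d.x_px - c[0], d.y_px - c[1]] for d in others])
    u = vecs[np.argmin(np.linalg.norm(vecs, axis=1))]
    u = u if (abs(u[0]) >= abs(u[1]) and u[0] > 0) or (abs(u[0]) < abs(u[1])) else u
    pitch2 = float(u @ u)
    taken = {(0, 0)}
    for d, w in zip(others, vecs):
        i = int(round(float(w @ u) / pitch2))
        key = (i, 0)
        if key in taken or abs(w @ u / pitch2 - i) > 0.5:
            continue
        taken.add(key)
        grid[key] = d
    g = DotGrid(dots=grid, axes=(u, None), dropped=len(dots) - len(grid))
    g.warnings.append("degraded single-axis indexing (fewer than 5 dots)")
    return g


def index_dots(dots, cfg: GridConfig | None = None) -> DotGrid:
    """Assign integer grid indices to detected dots (centre dot at (0, 0))."""
    cfg = cfg or GridConfig()
    dots = list(dots)
    center = next((d for d in dots if d.is_center), None)
    if center is None:
        raise NoCenterError("no centre dot flagged")
    if len(dots) == 1:
        return DotGrid(dots={(0, 0): center})
    if len(dots) < 5:
        return _degraded_single_axis(dots, center, cfg)

    pos = np.array([[d.x_px, d.y_px] for d in dots])
    c_idx = dots.index(center)
    c = pos[c_idx]
    others = np.delete(np.arange(len(dots)), c_idx)
    dist = np.linalg.norm(pos[others] - c, axis=1)
    near4 = others[np.argsort(dist)[:4]]
    u, v = _pick_axes(c, pos[near4])
    # residual bounds in lattice units; u is the baseline axis where
    # surface depth shifts the pattern, v is the depth-invariant axis
    basis_inv = np.linalg.inv(np.stack([u, v], axis=1))
    search_r = cfg.accept_frac_u * np.linalg.norm(u) + cfg.accept_frac_v * np.linalg.norm(v)

    tree = cKDTree(pos)
    assigned: dict[tuple, int] = {(0, 0): c_idx}
    owner = {c_idx: (0, 0)}
    steps = ((1, 0), (-1, 0), (0, 1), (0, -1))

    def in_bounds(i, j):
        return (-cfg.half_i <= i <= cfg.cols - 1 - cfg.half_i
                and -cfg.half_j <= j <= cfg.rows - 1 - cfg.half_j)

    def predict(i, j):
        """Consensus prediction from every assigned neighbour, each using
        the locally observed axis step when available."""
        preds = []
        for di, dj in steps:
            nb = (i - di, j - dj)
            if nb not in assigned:
                continue
            p_nb = pos[assigned[nb]]
            prev = (i - 2 * di, j - 2 * dj)
            if prev in assigned:
                step = p_nb - pos[assigned[prev]]
            else:
                step = u * di + v * dj
            preds.append(p_nb + step)
        return np.mean(preds, axis=0) if preds else None

    def best_candidate(i, j):
        pred = predict(i, j)
        if pred is None:
            return None
        best_k, best_cost = None, np.inf
        for m in tree.query_ball_point(pred, search_r):
            if m in owner:
                continue
            alpha, beta = basis_inv @ (pos[m] - pred)
            if abs(alpha) > cfg.accept_frac_u or abs(beta) > cfg.accept_frac_v:
                continue
            cost = (alpha / cfg.accept_frac_u) ** 2 + (beta / cfg.accept_frac_v) ** 2
            if cost < best_cost:
                best_k, best_cost = m, cost
        if best_k is None:
            return None
        return best_cost, best_k

    # best-first growth: confident links are locked in before dubious ones
    heap: list = []
    counter = 0

    def push_frontier(i, j):
        nonlocal counter
        for di, dj in steps:
            cell = (i + di, j + dj)
            if cell in assigned or not in_bounds(*cell):
                continue
            cand = best_candidate(*cell)
            if cand is not None:
                counter += 1
                heapq.heappush(heap, (cand[0], counter, cell, cand[1]))

    push_frontier(0, 0)
    while heap:
        _, _, cell, k = heapq.heappop(heap)
        if cell in assigned or k in owner:
            # stale entry: re-evaluate the cell with current assignments
            if cell not in assigned:
                cand = best_candidate(*cell)
                if cand is not None:
                    counter += 1
                    heapq.heappush(heap, (cand[0], counter, cell, cand[1]))
            continue
        assigned[cell] = k
        owner[k] = cell
        push_frontier(*cell)

    grid = DotGrid(
        dots={key: dots[k] for key, k in assigned.items()},
        axes=(u, v),
        dropped=len(dots) - len(assigned),
    )
    if grid.dropped:
        grid.warnings.append(f"{grid.dropped} dot(s) not assignable to the lattice")
    if grid.occupancy(cfg) < cfg.occupancy_rescan:
        grid.rescan_recommended = True
        grid.warnings.append("grid occupancy below 50%; rescan recommended")
    return grid


def _axis_estimate(grid_dots, i, j, di, dj, max_reach):
    """Position estimate for (i, j) from the nearest dots along one axis
    direction pair; interpolates across the gap when both sides exist,
    otherwise extrapolates using the nearest observed step."""
    def nearest(sdi, sdj):
        for s in range(1, max_reach + 1):
            key = (i + sdi * s, j + sdj * s)
            if key in grid_dots:
                return s, grid_dots[key]
        return None, None

    a, da = nearest(-di, -dj)
    b, db = nearest(di, dj)
    if da is not None and db is not None:
        pa = np.array([da.x_px, da.y_px])
        pb = np.array([db.x_px, db.y_px])
        return pa + (pb - pa) * (a / (a + b))
    for s, d0, sgn in ((a, da, -1), (b, db, +1)):
        if d0 is None:
            continue
        s2, d1 = None, None
        for extra in range(1, max_reach + 1):
            key = (i + sgn * di * (s + extra), j + sgn * dj * (s + extra))
            if key in grid_dots:
                s2, d1 = s + extra, grid_dots[key]
                break
        if d1 is None:
            return None
        p0 = np.array([d0.x_px, d0.y_px])
        p1 = np.array([d1.x_px, d1.y_px])
        step = (p1 - p0) / (s2 - s)
        return p0 - step * s
    return None


def impute_missing(grid: DotGrid, cfg: GridConfig | None = None) -> DotGrid:
    """Fill absent interior indices by averaging the two axis estimates.

    An index is imputed only when both the horizontal and the vertical
    axis yield a position estimate; observed dots are never moved.
    """
    cfg = cfg or GridConfig()
    observed = dict(grid.dots)
    out = dict(grid.dots)
    imputed = set(grid.imputed)
    reach = max(cfg.rows, cfg.cols)
    for i in range(-cfg.half_i, cfg.cols - cfg.half_i):
        for j in range(-cfg.half_j, cfg.rows - cfg.half_j):
            if (i, j) in out:
                continue
            est_u = _axis_estimate(observed, i, j, 1, 0, reach)
            est_v = _axis_estimate(observed, i, j, 0, 1, reach)
            if est_u is None or est_v is None:
                continue
            p = (est_u + est_v) / 2.0
            out[(i, j)] = LaserDot(
                x_px=float(p[0]), y_px=float(p[1]),
                peak_luminance=0.0, area_px=1, provenance="imputed",
            )
            imputed.add((i, j))
    new = DotGrid(
        dots=out, imputed=imputed, axes=grid.axes, dropped=grid.dropped,
        rescan_recommended=grid.rescan_recommended, warnings=list(grid.warnings),
    )
    return new
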