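"""Stretching open active contour (SOAC) evolution.

Each snake is an open polyline r(s) evolving under

* internal forces: first-order (elasticity) and second-order (rigidity)
  stiffness, discretized as a pentadiagonal operator with free ends;
* an image force at every point, the gradient of the (rescaled, optionally
  presmoothed) intensity, which attracts the curve to ridge centerlines;
* a stretching force at the two tips, directed along the outward tangent
  with magnitude k_str * (1 - I_b / I_f), where I_f is the tip intensity
  and I_b the local background sampled on an annulus perpendicular to the
  tip tangent.  A tip whose local contrast vanishes (I_f <= I_b) stops
  stretching: that is how a snake detects a filament end.

Time stepping is semi-implicit (implicit internal forces, explicit
external forces), the standard unconditionally stable snake scheme.  After
each step the snake is resampled to uniform arc-length spacing.  A free
tip that comes within ``collide_dist`` of another snake's body freezes and
records a T-junction; junction positions are later clustered and the
network reconfigured by the topology module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.linalg import solveh_banded
from scipy.spatial import cKDTree

from filanet.imgio import Volume
from filanet.initseeds import detect_ridges, link_seeds

logger = logging.getLogger(__name__)

FREE = "free"
FROZEN = "frozen"  # tip ended in a T-junction
STOPPED = "stopped"  # tip left the allowed intensity range


@dataclass
class Snake:
    """An open polyline in voxel coordinates; the discrete SOAC."""

    points: np.ndarray  # (n, 3)
    spacing: float = 1.0
    head_state: str = FREE
    tail_state: str = FREE
    id: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("snake points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a snake needs at least 2 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def copy(self) -> "Snake":
        return Snake(
            self.points.copy(), self.spacing, self.head_state, self.tail_state, self.id
        )


@dataclass
class ExtractionParams:
    """All tunable parameters of the extraction pipeline.

    Distances are in isotropic voxels, intensities in rescaled [0, 1]
    units.  The image-force weight k_img is fixed at 1; only the stretch
    factor k_str and the ridge threshold tau are meant to be scanned.
    """

    tau: float = 0.02
    k_str: float = 0.5
    k_img: float = 1.0
    elasticity: float = 0.05
    rigidity: float = 0.1
    step: float = 0.5
    spacing: float = 1.0
    conv_tol: float = 0.05
    conv_window: int = 10
    max_iter: int = 10000
    bg_radii: tuple[float, float] = (3.0, 6.0)
    collide_dist: float = 1.5
    overlap_dist: float = 1.0
    junction_cluster_dist: float = 3.0
    intensity_range: tuple[float, float] = (0.0, 1.0)
    damp_z: bool = False
    init_axes: frozenset[str] | None = None
    min_snake_length: int = 5
    sigma_smooth: float = 0.0

    def __post_init__(self) -> None:
        if self.k_img != 1.0:
            raise ValueError("k_img is fixed at 1 (unit convention)")
        for name in ("step", "spacing", "conv_tol", "collide_dist", "overlap_dist",
                     "junction_cluster_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.intensity_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("intensity_range must satisfy 0 <= lo < hi <= 1")
        if self.init_axes is not None:
            self.init_axes = frozenset(self.init_axes)


@dataclass
class TJunction:
    """Collision of a snake tip with the body of another snake."""

    position: np.ndarray  # (3,)
    tip_snake: tuple[int, str]  # (snake id, "head" | "tail")
    body_snake: tuple[int, int]  # (snake id, nearest point index)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)


def _perp_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / np.linalg.norm(tangent)
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    w = np.cross(t, u)
    return u, w


def local_background(
    v: Volume,
    tip: np.ndarray,
    tangent: np.ndarray,
    bg_radii: tuple[float, float] = (3.0, 6.0),
) -> tuple[float, float, float]:
    """Foreground and local-background intensity statistics at a tip.

    I_f is the interpolated intensity at the tip (0 outside the volume).
    I_b and sigma_b are the mean and standard deviation of intensities
    sampled uniformly on concentric circles of radius r_near..r_far in the
    plane through the tip perpendicular to the tangent.  For single-slice
    (2D) volumes the annulus degenerates to a pair of in-plane line
    segments flanking the tip.
    """
    tip = np.asarray(tip, dtype=np.float64)
    tangent = np.asarray(tangent, dtype=np.float64)
    if np.linalg.norm(tangent) == 0:
        raise ValueError("tangent must be nonzero")
    i_f = float(v.interp(tip[None, :])[0])
    r_near, r_far = bg_radii
    radii = np.arange(r_near, r_far + 1e-9, 1.0)
    if v.is_2d:
        t2 = tangent[:2]
        n2 = np.array([-t2[1], t2[0], 0.0])
        nrm = np.linalg.norm(n2)
        if nrm == 0:  # tangent along z in a 2D image: any in-plane normal
            n2 = np.array([1.0, 0.0, 0.0])
        else:
            n2 /= nrm
        offsets = np.concatenate([radii, -radii])
        samples = tip[None, :] + offsets[:, None] * n2[None, :]
    else:
        u, w = _perp_basis(tangent)
        pts = []
        for r in radii:
            m = max(8, int(np.ceil(2 * np.pi * r)))
            ang = 2 * np.pi * np.arange(m) / m
            pts.append(tip[None, :] + r * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w)))
        samples = np.vstack(pts)
    vals = v.sample_nearest(samples)
    return i_f, float(vals.mean()), float(vals.std())


def stretch_magnitude(i_f: float, i_b: float, k_str: float) -> float:
    """Tip stretching force magnitude k_str * (1 - I_b / I_f).

    Zero unless I_f > I_b > 0: a tip in a zero- or negative-contrast
    region stops stretching (filament end reached).
    """
    if i_f > i_b > 0:
        return k_str * (1.0 - i_b / i_f)
    return 0.0


class _ImageForces:
    """Precomputed gradient field of a (optionally presmoothed) volume."""

    def __init__(self, v: Volume, sigma_smooth: float = 0.0):
        data = v.data
        if sigma_smooth > 0:
            sig = (sigma_smooth, sigma_smooth, 0 if data.shape[2] == 1 else sigma_smooth)
            data = ndimage.gaussian_filter(data, sig)
        if data.shape[2] > 1:
            self.grad = list(np.gradient(data))
        else:  # single-slice volume: in-plane gradient only
            gx, gy = np.gradient(data[:, :, 0])
            self.grad = [gx[:, :, None], gy[:, :, None], np.zeros_like(data)]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        coords = points.T
        out = np.empty_like(points)
        for k in range(3):
            out[:, k] = ndimage.map_coordinates(
                self.grad[k], coords, order=1, mode="constant", cval=0.0
            )
        return out


_BANDED_CACHE: dict = {}


def _internal_banded(n: int, elasticity: float, rigidity: float, step: float):
    """Upper banded form of (I + step * K) with K = a D'D + b M'M (free ends)."""
    key = (n, elasticity, rigidity, step)
    ab = _BANDED_CACHE.get(key)
    if ab is not None:
        return ab
    K = np.zeros((n, n))
    if n >= 2:
        D = np.zeros((n - 1, n))
        idx = np.arange(n - 1)
        D[idx, idx] = -1.0
        D[idx, idx + 1] = 1.0
        K += elasticity * D.T @ D
    if n >= 3:
        M = np.zeros((n - 2, n))
        idx = np.arange(n - 2)
        M[idx, idx] = 1.0
        M[idx, idx + 1] = -2.0
        M[idx, idx + 2] = 1.0
        K += rigidity * M.T @ M
    A = np.eye(n) + step * K
    ab = np.zeros((3, n))
    for d in range(3):
        ab[2 - d, d:] = np.diagonal(A, offset=d)
    if len(_BANDED_CACHE) > 512:
        _BANDED_CACHE.clear()
    _BANDED_CACHE[key] = ab
    return ab


def resample_snake(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing (endpoints kept)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return points[:1].repeat(2, axis=0)
    m = max(2, int(np.round(total / spacing)) + 1)
    snew = np.linspace(0.0, total, m)
    out = np.empty((m, 3))
    for k in range(3):
        out[:, k] = np.interp(snew, s, points[:, k])
    return out


class _NetworkIndex:
    """KD-tree over the points of already-converged snakes."""

    def __init__(self):
        self.snakes: list[Snake] = []
        self._pts: list[np.ndarray] = []
        self._ids: list[np.ndarray] = []
        self._idx: list[np.ndarray] = []
        self.tree: cKDTree | None = None

    def add(self, s: Snake) -> None:
        self.snakes.append(s)
        self._pts.append(s.points)
        self._ids.append(np.full(len(s.points), s.id))
        self._idx.append(np.arange(len(s.points)))
        pts = np.vstack(self._pts)
        self.tree = cKDTree(pts)
        self.ids = np.concatenate(self._ids)
        self.point_idx = np.concatenate(self._idx)

    @property
    def empty(self) -> bool:
        return self.tree is None

    def nearest(self, p: np.ndarray):
        d, i = self.tree.query(p)
        return float(d), int(self.ids[i]), int(self.point_idx[i])


def _tip_tangent(points: np.ndarray, end: str) -> np.ndarray:
    """Outward tangent at a tip, averaged over up to 3 edge vectors."""
    k = min(3, len(points) - 1)
    if end == "head":
        t = points[0] - points[k]
    else:
        t = points[-1] - points[-1 - k]
    nrm = np.linalg.norm(t)
    return t / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])


def evolve_snake(
    s: Snake,
    v: Volume,
    p: ExtractionParams,
    existing: _NetworkIndex | None = None,
    forces: _ImageForces | None = None,
) -> tuple[Snake | None, list[TJunction]]:
    """Evolve one snake to convergence against the growing network.

    Returns the converged snake (or None if it degenerated) and the
    T-junctions recorded when a tip froze on another snake's body.
    """
    if forces is None:
        forces = _ImageForces(v, p.sigma_smooth)
    pts = resample_snake(s.points, p.spacing)
    head_state, tail_state = s.head_state, s.tail_state
    tjs: list[TJunction] = []
    lo, hi = p.intensity_range
    quiet = 0
    is2d = v.is_2d
    len_hist = [float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())]
    for iteration in range(p.max_iter):
        n = len(pts)
        fext = p.k_img * forces(pts)
        # tip handling: stretch, gating, collision
        for end, state_name in (("head", head_state), ("tail", tail_state)):
            i_tip = 0 if end == "head" else n - 1
            tip = pts[i_tip]
            if state_name == FROZEN:
                continue
            tip_int = float(v.interp(tip[None, :])[0])
            if not (lo <= tip_int <= hi):
                # outside the allowed intensity range: no elongation here
                if end == "head":
                    head_state = STOPPED
                else:
                    tail_state = STOPPED
                continue
            if state_name == STOPPED:
                if end == "head":
                    head_state = FREE
                else:
                    tail_state = FREE
            tan = _tip_tangent(pts, end)
            # collision with an existing snake's body freezes the tip
            if existing is not None and not existing.empty:
                d, sid, pidx = existing.nearest(tip)
                if d <= p.collide_dist:
                    tjs.append(TJunction(tip.copy(), (s.id, end), (sid, pidx)))
                    if end == "head":
                        head_state = FROZEN
                    else:
                        tail_state = FROZEN
                    continue
            i_f, i_b, _ = local_background(v, tip, tan, p.bg_radii)
            mag = stretch_magnitude(i_f, i_b, p.k_str)
            if p.damp_z and not is2d:
                mag *= float(np.hypot(tan[0], tan[1]))
            fext[i_tip] += mag * tan
        ab = _internal_banded(n, p.elasticity, p.rigidity, p.step)
        rhs = pts + p.step * fext
        new = solveh_banded(ab, rhs, lower=False)
        if is2d:
            new[:, 2] = pts[:, 2]
        if head_state == FROZEN:
            new[0] = pts[0]
        if tail_state == FROZEN:
            new[-1] = pts[-1]
        disp = float(np.max(np.linalg.norm(new - pts, axis=1)))
        # resample every step: letting end gaps grow to the resample band
        # raises the elastic end force by up to 50% and can stall slow tips
        pts = resample_snake(new, p.spacing)
        if len(pts) < 2 or not np.isfinite(pts).all():
            logger.info("snake %d degenerated during evolution", s.id)
            return None, tjs
        # converged = points stationary AND length stable over the whole
        # window: a slowly elongating tip can keep both the per-iteration
        # displacement and the per-iteration length change below tolerance
        cur_len = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        len_hist.append(cur_len)
        if disp < p.conv_tol:
            quiet += 1
            if (
                quiet >= p.conv_window
                and abs(cur_len - len_hist[-1 - p.conv_window]) < p.conv_tol
            ):
                break
        else:
            quiet = 0
    # exit resample restores the uniform-spacing invariant
    out = Snake(resample_snake(pts, p.spacing), p.spacing, head_state, tail_state, s.id)
    return out, tjs


def remove_overlap(
    s: Snake,
    existing: _NetworkIndex,
    overlap_dist: float,
    min_snake_length: int,
) -> list[Snake]:
    """Delete runs of points of ``s`` lying within ``overlap_dist`` of the
    existing network; return the surviving fragments (each >= min length)."""
    if existing is None or existing.empty:
        return [s]
    d, _ = existing.tree.query(s.points)
    keep = d > overlap_dist
    frags: list[Snake] = []
    start = None
    n = len(keep)
    for i in range(n + 1):
        if i < n and keep[i]:
            if start is None:
                start = i
        else:
            if start is not None:
                if i - start >= min_snake_length:
                    frag = Snake(
                        s.points[start:i].copy(),
                        s.spacing,
                        s.head_state if start == 0 else FREE,
                        s.tail_state if i == n else FREE,
                        s.id,
                    )
                    frags.append(frag)
                start = None
    return frags


def extract_all(
    v: Volume, p: ExtractionParams
) -> tuple[list[Snake], list[TJunction]]:
    """Full sequential extraction: seed, evolve, de-overlap, collect junctions.

    Seeds are evolved one after another in decreasing order of mean seed
    intensity; each converged snake joins the network before the next seed
    evolves, and overlap removal is applied both before evolution (cheap
    pruning of redundant seeds) and after convergence.  Deterministic.
    """
    if not v.rescaled:
        raise ValueError("extract_all expects a rescaled volume")
    rm = detect_ridges(
        v,
        p.tau,
        axes=None,
        intensity_range=p.intensity_range if p.intensity_range != (0.0, 1.0) else None,
    )
    seeds = link_seeds(rm, v, p.min_snake_length, p.init_axes,
                       nms_radius=p.bg_radii[0])
    if not seeds:
        logger.warning("no seeds found (tau=%g); empty extraction", p.tau)
        return [], []
    # longest seeds first (ties: brightest first): long chains are the most
    # trustworthy filament evidence, and short transverse artifacts seeded on
    # bright crossings then fall to overlap pruning instead of entering first
    mean_int = np.asarray([float(v.interp(s.points).mean()) for s in seeds])
    npts = np.asarray([s.n_points for s in seeds])
    order = np.lexsort((-mean_int, -npts))
    forces = _ImageForces(v, p.sigma_smooth)
    net = _NetworkIndex()
    tjs_all: list[TJunction] = []
    next_id = max(s.id for s in seeds) + 1
    # (snake, generation): overlap fragments re-enter evolution a few times
    queue: list[tuple[Snake, int]] = [(seeds[i], 0) for i in order]
    max_generation = 3
    qi = 0
    while qi < len(queue):
        snake, gen = queue[qi]
        qi += 1
        for frag in remove_overlap(snake, net, p.overlap_dist, p.min_snake_length):
            if frag is not snake:
                frag.id = next_id
                next_id += 1
            evolved, tjs = evolve_snake(frag, v, p, net, forces)
            if evolved is None:
                continue
            frags = remove_overlap(evolved, net, p.overlap_dist, p.min_snake_length)
            if len(frags) == 1 and frags[0].n_points == evolved.n_points:
                net.add(evolved)
                tjs_all.extend(tjs)
            elif gen < max_generation:
                for f in frags:
                    f.id = next_id
                    next_id += 1
                    queue.append((f, gen + 1))
    return net.snakes, tjs_all
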