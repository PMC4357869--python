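"""SOAC initialization: ridge-point detection and seed linking.

A ridge point in axis k is a location where the intensity is a local
maximum along axis k, detected by a sign change of the k-th gradient
component whose magnitude exceeds the ridge threshold tau.  There is no
cap on the separation between the positive and the negative gradient
crossing, so filaments of any width are picked up; within a flat plateau
the midpoint of the maximal-intensity run is flagged.

Seeds along direction k are chains of voxels that are ridge points in both
transverse axes: a filament running along k presents a transverse intensity
maximum in each perpendicular scan direction.  Chains are grown voxel by
voxel with unit steps in k and at most one voxel of transverse drift
(26-connectivity), then emitted as short open polylines ("snakes") for the
evolution stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from filanet.imgio import Volume

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class RidgeMap:
    """Per-axis boolean grids of ridge points."""

    maps: dict[str, np.ndarray]
    axes_used: frozenset[str]
    tau: float

    def __getitem__(self, axis: str) -> np.ndarray:
        return self.maps[axis]

    def count(self) -> int:
        return int(sum(m.sum() for m in self.maps.values()))


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=True)
def _ridge_lines_kernel(intensity, g, tau, out):  # pragma: no cover - jitted
    nlines, n = intensity.shape
    for li in range(nlines):
        a = 0
        while a < n:
            # [a, b] is a run of equal intensity values
            b = a
            while b + 1 < n and intensity[li, b + 1] == intensity[li, a]:
                b += 1
            peak = intensity[li, a]
            is_max = (a == 0 or intensity[li, a - 1] < peak) and (
                b == n - 1 or intensity[li, b + 1] < peak
            )
            if is_max:
                # expand left while at or below the peak; max ascent gradient
                up = -np.inf
                i = a - 1
                while i >= 0 and intensity[li, i] <= peak:
                    if g[li, i] > up:
                        up = g[li, i]
                    i -= 1
                if a > 0 and g[li, a] > up:
                    up = g[li, a]
                # expand right; max descent-gradient magnitude
                down = -np.inf
                i = b + 1
                while i < n and intensity[li, i] <= peak:
                    if -g[li, i] > down:
                        down = -g[li, i]
                    i += 1
                if b < n - 1 and -g[li, b] > down:
                    down = -g[li, b]
                strength = up if up < down else down
                if strength >= tau:
                    out[li, (a + b) // 2] = True
            a = b + 1


def _ridge_1d_stack(intensity: np.ndarray, tau: float) -> np.ndarray:
    """Ridge detection along the last axis of a 2D stack of scan lines.

    Each plateau-run local maximum gets a tau-independent strength: over
    the widest window in which it remains the maximum, the smaller of the
    largest ascending gradient (left side) and the largest descending
    gradient magnitude (right side).  The peak is flagged at the plateau
    midpoint when its strength reaches tau.  Because strengths and
    positions do not depend on tau, raising tau only removes ridge points
    (monotonicity), and the two gradient extremes may lie arbitrarily far
    from the peak, so wide filaments are detected as well as narrow ones.
    Shoulders of higher peaks never out-rank the peak itself: their window
    ends where the profile rises above them.
    """
    nlines, n = intensity.shape
    out = np.zeros((nlines, n), dtype=np.bool_)
    if n < 3:
        return out
    g = np.gradient(intensity, axis=1)
    _ridge_lines_kernel(
        np.ascontiguousarray(intensity), np.ascontiguousarray(g), tau, out
    )
    return out


def detect_ridges(
    v: Volume,
    tau: float,
    axes: set[str] | frozenset[str] | None = None,
    intensity_range: tuple[float, float] | None = None,
) -> RidgeMap:
    """Detect ridge points of a rescaled volume along the requested axes.

    ``axes`` defaults to all axes with extent > 1.  When
    ``intensity_range = (lo, hi)`` is given, ridge points whose intensity
    falls outside the range are discarded (gating used e.g. to exclude
    bright non-filament structures).
    """
    if tau <= 0:
        raise ValueError("ridge threshold tau must be positive")
    if axes is None:
        axes = {a for a, k in AXIS_INDEX.items() if v.shape[k] > 1}
    axes = frozenset(axes)
    if not axes:
        raise ValueError("empty axes set")
    maps: dict[str, np.ndarray] = {}
    for axis in sorted(axes):
        k = AXIS_INDEX[axis]
        if v.shape[k] <= 1:
            maps[axis] = np.zeros(v.shape, dtype=bool)
            continue
        moved = np.moveaxis(v.data, k, -1)
        flat = moved.reshape(-1, v.shape[k])
        ridges = _ridge_1d_stack(flat, tau).reshape(moved.shape)
        maps[axis] = np.moveaxis(ridges, -1, k)
    if intensity_range is not None:
        lo, hi = intensity_range
        ok = (v.data >= lo) & (v.data <= hi)
        for axis in maps:
            maps[axis] &= ok
    return RidgeMap(maps, axes, tau)


def _chain_direction(
    cand: np.ndarray, intensity: np.ndarray, k: int, min_length: int
) -> list[np.ndarray]:
    """Chain candidate voxels into polylines running along axis k."""
    # work in a permuted frame where the chaining axis is axis 0
    perm = [k] + [a for a in range(3) if a != k]
    inv = np.argsort(perm)
    cand_p = np.transpose(cand, perm)
    inten_p = np.transpose(intensity, perm)
    visited = np.zeros_like(cand_p)
    chains: list[np.ndarray] = []
    # deterministic seed order: decreasing intensity among candidates
    idx = np.argwhere(cand_p)
    if len(idx) == 0:
        return chains
    order = np.argsort(-inten_p[idx[:, 0], idx[:, 1], idx[:, 2]], kind="stable")
    shape = cand_p.shape

    def step(pos, direction):
        # advance one level along the chain axis (transverse drift <= 1);
        # a single missing level may be bridged with drift <= 2, since
        # noise easily knocks one voxel out of the dual-ridge intersection
        for skip, reach in ((1, 1), (2, 2)):
            j = pos[0] + direction * skip
            if j < 0 or j >= shape[0]:
                return None
            best = None
            best_i = -np.inf
            for da in range(-reach, reach + 1):
                for db in range(-reach, reach + 1):
                    a, b = pos[1] + da, pos[2] + db
                    if 0 <= a < shape[1] and 0 <= b < shape[2]:
                        if cand_p[j, a, b] and not visited[j, a, b]:
                            if inten_p[j, a, b] > best_i:
                                best_i = inten_p[j, a, b]
                                best = (j, a, b)
            if best is not None:
                return best
        return None

    for i in order:
        start = tuple(idx[i])
        if visited[start]:
            continue
        visited[start] = True
        chain = [start]
        for direction in (+1, -1):
            pos = start
            while True:
                nxt = step(pos, direction)
                if nxt is None:
                    break
                visited[nxt] = True
                if direction > 0:
                    chain.append(nxt)
                else:
                    chain.insert(0, nxt)
                pos = nxt
        if len(chain) >= min_length:
            pts = np.asarray(chain, dtype=np.float64)[:, inv]
            chains.append(pts)
    return chains


def _axis_line_footprint(k: int, half_len: int) -> np.ndarray:
    """Boolean line footprint of 2*half_len+1 voxels along axis k."""
    shape = [1, 1, 1]
    shape[k] = 2 * half_len + 1
    return np.ones(shape, dtype=bool)


def link_seeds(
    rm: RidgeMap,
    v: Volume,
    min_length: int = 5,
    init_axes: set[str] | frozenset[str] | None = None,
    nms_radius: float = 4.0,
):
    """Link ridge points into initial snakes along the chosen directions.

    For direction k, candidate voxels are ridge points of *both* transverse
    axes (of the single in-plane transverse axis for 2D volumes) that are
    additionally locally flat along k itself (|d_k I| <= tau): a filament
    centerline is an intensity maximum transversally and close to constant
    longitudinally, whereas ghost columns sitting on the axial slope of an
    anisotropic PSF blur fail the flatness test.  Candidates must also be
    the brightest point of their transverse disc of radius ``nms_radius``
    (default: the inner stretch-annulus radius, i.e. where local background
    begins): dimmer parallel ridges inside that disc are PSF halo, not
    separate filaments.  Chains shorter than ``min_length`` points are
    discarded.  Returns a list of :class:`~filanet.dynamics.Snake`.
    """
    from filanet.dynamics import Snake

    if init_axes is None:
        init_axes = {a for a, k in AXIS_INDEX.items() if v.shape[k] > 1}
    # flatness is judged on a lightly smoothed volume: shot noise on bright
    # centerlines would otherwise fail the test, while the systematic axial
    # slope of a PSF tail (correlated over the PSF scale) survives smoothing
    from scipy import ndimage as _ndi

    smooth_sigma = [2.0 if v.shape[a] > 1 else 0.0 for a in range(3)]
    smoothed = _ndi.gaussian_filter(v.data, smooth_sigma)
    snakes = []
    sid = 0
    for axis in sorted(init_axes):
        k = AXIS_INDEX[axis]
        if v.shape[k] <= 1:
            continue
        transverse = [a for a in AXIS_INDEX if a != axis and v.shape[AXIS_INDEX[a]] > 1]
        if not transverse:
            continue
        cand = np.abs(np.gradient(smoothed, axis=k)) <= rm.tau
        if nms_radius > 0:
            # halo suppression: brightness along a true direction-k filament
            # is roughly uniform, so a candidate dimmer than half the
            # brightest point on its own axis-k line (background-subtracted)
            # is the axial PSF halo of that brighter structure, not a
            # separate filament.  Line half-length 2 * r_near covers the
            # halo extent (r_near is where local background begins).
            fp = _axis_line_footprint(k, int(np.ceil(2 * nms_radius)))
            local_max = _ndi.maximum_filter(smoothed, footprint=fp, mode="nearest")
            bg = float(np.median(smoothed))
            cand &= (smoothed - bg) >= 0.5 * (local_max - bg)
        for a in transverse:
            if a in rm.maps:
                cand &= rm.maps[a]
            else:
                cand[:] = False
        for pts in _chain_direction(cand, v.data, k, min_length):
            snakes.append(Snake(points=pts, id=sid))
            sid += 1
    return snakes
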