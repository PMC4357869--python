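"""Biological summary statistics computed from an extracted network.

Covers the analyses commonly applied to filament networks in confined
geometries: radial density/intensity profiles around a center (droplets),
segment orientation distributions in spherical coordinates, the radial
angle against an outward direction, curvature along snakes and the
worm-like-chain persistence length estimated from the curvature
distribution, and density maps in spherocylinder coordinates for
rod-shaped cells.

Orientation convention: each segment vector a = (x, y, z) between
consecutive snake points is polarity-free (a and -a are the same
filament direction), so phi in (-90, 90] degrees and theta in [0, 180)
degrees, both pi-periodic.  For x > 0, phi = atan(y/x) and
theta = acos(z/|a|); for x < 0 the vector is inverted first.  A segment
along the z-axis has phi = theta = 0 by convention, and a segment in the
y-z plane (x = 0, y != 0) is inverted when y < 0 and assigned phi = 90.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from filanet.imgio import Volume
from filanet.topology import Network

logger = logging.getLogger(__name__)


def segment_orientation(a: np.ndarray) -> tuple[float, float]:
    """Azimuthal and polar angle (phi, theta) of a segment vector, degrees."""
    a = np.asarray(a, dtype=np.float64)
    if np.linalg.norm(a) == 0:
        raise ValueError("zero segment vector")
    x, y, z = a
    if x == 0 and y == 0:
        return 0.0, 0.0
    if x == 0:
        if y < 0:
            a = -a
        phi = 90.0
        theta = float(np.degrees(np.arccos(a[2] / np.linalg.norm(a))))
    else:
        if x < 0:
            a = -a
        x, y, z = a
        phi = float(np.degrees(np.arctan(y / x)))
        theta = float(np.degrees(np.arccos(z / np.linalg.norm(a))))
    # pi-periodic boundary identifications keep the printed open ranges
    if phi == -90.0:
        phi = 90.0
    if theta >= 180.0:
        theta -= 180.0
    return phi, theta


def radial_angle(a: np.ndarray, midpoint: np.ndarray, center: np.ndarray) -> float:
    """Angle gamma in [0, 90] degrees between a segment and the outward
    radial direction from ``center`` (polarity-free fold)."""
    a = np.asarray(a, dtype=np.float64)
    r = np.asarray(midpoint, dtype=np.float64) - np.asarray(center, dtype=np.float64)
    na, nr = np.linalg.norm(a), np.linalg.norm(r)
    if na == 0:
        raise ValueError("zero segment vector")
    if nr == 0:
        raise ValueError("midpoint coincides with center")
    cosg = abs(float(np.dot(a, r) / (na * nr)))
    return float(np.degrees(np.arccos(np.clip(cosg, 0.0, 1.0))))


def segment_table(net: Network, v: Volume | None = None,
                  center: np.ndarray | None = None):
    """Per-segment records (midpoint, length, phi, theta, gamma, intensity)
    as a tidy DataFrame; one row per inter-point segment."""
    import pandas as pd

    rows = []
    for s in net.snakes:
        pts = s.points
        vecs = np.diff(pts, axis=0)
        mids = 0.5 * (pts[:-1] + pts[1:])
        if v is not None:
            inten = 0.5 * (v.interp(pts[:-1]) + v.interp(pts[1:]))
        else:
            inten = np.full(len(vecs), np.nan)
        for k, (a, m) in enumerate(zip(vecs, mids)):
            if np.linalg.norm(a) == 0:
                continue
            phi, theta = segment_orientation(a)
            gamma = (
                radial_angle(a, m, center)
                if center is not None and not np.allclose(m, center)
                else np.nan
            )
            rows.append(
                dict(snake_id=s.id, mx=m[0], my=m[1], mz=m[2],
                     length=float(np.linalg.norm(a)), phi=phi, theta=theta,
                     gamma=gamma, intensity=float(inten[k]))
            )
    return pd.DataFrame(rows)


@dataclass
class DensityProfile:
    """Radial shell profile around a center: counts are divided by the
    shell surface area 4 pi r^2 with r the shell's inner radius."""

    r: np.ndarray  # inner radii 0..R-1
    counts: np.ndarray
    rho: np.ndarray
    snake_intensity: np.ndarray
    voxel_intensity: np.ndarray


def radial_profiles(
    net: Network, v: Volume, center: np.ndarray, R: int
) -> DensityProfile:
    """Snake-point density and intensity vs distance from a center.

    For each unit-width shell r < d <= r + 1 (r = 0 .. R-1): the number of
    snake points in the shell divided by 4 pi r^2, the mean image
    intensity at those snake points, and the mean intensity over all
    voxels in the shell.  The r = 0 shell has zero nominal surface area;
    its density is reported as inf when occupied (0 when empty).
    """
    center = np.asarray(center, dtype=np.float64)
    if np.any(center < 0) or np.any(center > np.asarray(v.shape) - 1):
        logger.warning("center %s outside the volume", center)
    if R < 1:
        raise ValueError("R must be >= 1")
    pts = net.all_points()
    d = np.linalg.norm(pts - center, axis=1) if len(pts) else np.empty(0)
    inten = v.interp(pts) if len(pts) else np.empty(0)
    r_edges = np.arange(R + 1, dtype=np.float64)
    counts = np.zeros(R)
    snake_int = np.full(R, np.nan)
    for r in range(R):
        in_shell = (d > r_edges[r]) & (d <= r_edges[r + 1])
        counts[r] = in_shell.sum()
        if counts[r] > 0:
            snake_int[r] = float(inten[in_shell].mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = counts / (4 * np.pi * r_edges[:-1] ** 2)
    rho[0] = np.inf if counts[0] > 0 else 0.0
    # voxel-intensity profile over the same shells
    grids = np.meshgrid(*[np.arange(n) for n in v.shape], indexing="ij")
    dv = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    voxel_int = np.full(R, np.nan)
    for r in range(R):
        sel = (dv > r_edges[r]) & (dv <= r_edges[r + 1])
        if sel.any():
            voxel_int[r] = float(v.data[sel].mean())
    return DensityProfile(r_edges[:-1], counts, rho, snake_int, voxel_int)


def surface_fraction(net: Network, center: np.ndarray, R: float,
                     frac: float = 0.9) -> float:
    """Fraction of snake points at distance >= frac * R from the center."""
    pts = net.all_points()
    if len(pts) == 0:
        raise ValueError("empty network")
    d = np.linalg.norm(pts - np.asarray(center, dtype=np.float64), axis=1)
    return float(np.mean(d >= frac * R))


@dataclass
class CurvatureSample:
    s: float
    kappa: float


def curvature(points: np.ndarray, delta_c: float = 8.0,
              sample_step: float = 1.0) -> list[CurvatureSample]:
    """Curvature samples kappa(s) = |t(s + Dc/2) - t(s - Dc/2)| / Dc.

    Unit tangents t(s) are chords between positions Dc apart in arc
    length (linearly interpolated along the polyline), so the estimate is
    insensitive to the contour's intrinsic point spacing.  Samples exist
    only where both tangent chords fit inside the curve, i.e. for
    s in [Dc, L - Dc].  Snakes should be cut at junctions beforehand.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        return []
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]
    if L <= 2 * delta_c:
        return []

    def pos(sv: np.ndarray) -> np.ndarray:
        out = np.empty((len(sv), 3))
        for k in range(3):
            out[:, k] = np.interp(sv, s, pts[:, k])
        return out

    # samples are centered in the valid range so the set is invariant under
    # reversal of the polyline (s -> L - s)
    span = L - 2 * delta_c
    m = int(np.floor(span / sample_step + 1e-9)) + 1
    start = delta_c + 0.5 * (span - (m - 1) * sample_step)
    sv = start + sample_step * np.arange(m)

    def tangent(at: np.ndarray) -> np.ndarray:
        a = pos(at - delta_c / 2)
        b = pos(at + delta_c / 2)
        t = b - a
        return t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)

    t_plus = tangent(sv + delta_c / 2)
    t_minus = tangent(sv - delta_c / 2)
    kappa = np.linalg.norm(t_plus - t_minus, axis=1) / delta_c
    return [CurvatureSample(float(a), float(k)) for a, k in zip(sv, kappa)]


def network_curvatures(net: Network, delta_c: float = 8.0) -> np.ndarray:
    """Curvature samples over all snakes of a network (already junction-cut)."""
    out = []
    for s in net.snakes:
        out.extend(c.kappa for c in curvature(s.points, delta_c))
    return np.asarray(out)


def fit_persistence_length(
    kappas: np.ndarray,
    delta_c: float,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    chord_tangents: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Persistence length from the worm-like-chain curvature distribution.

    For a 3D worm-like chain sampled over arc length Dc with *point*
    tangents, the curvature density is Rayleigh,
    p(kappa) = lp Dc kappa exp(-lp Dc kappa^2 / 2), whose
    maximum-likelihood estimate is closed form: lp = 2 / (Dc mean(kappa^2)).

    The tangents produced by :func:`curvature` are secants over windows of
    length Dc.  Window averaging filters tangent diffusion: for an
    exponentially correlated WLC tangent the expected squared angle between
    adjacent window secants is 2/3 of the point-tangent value, so the raw
    estimate must be multiplied by 2/3.  ``chord_tangents=True`` (default)
    applies that correction; pass False when kappas are genuine
    point-tangent draws from the Rayleigh density.

    Returns (lp, (lo, hi)) with a bootstrap percentile 95% interval.
    """
    kappas = np.asarray(kappas, dtype=np.float64)
    if len(kappas) < 50:
        raise ValueError("need at least 50 curvature samples")
    factor = 2.0 / 3.0 if chord_tangents else 1.0

    def estimate(k):
        msq = float(np.mean(k**2))
        if msq == 0:
            raise ValueError(
                "all curvatures are zero; persistence length diverges"
            )
        return factor * 2.0 / (delta_c * msq)

    lp = estimate(kappas)
    if rng is None:
        rng = np.random.default_rng(0)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        sample = rng.choice(kappas, size=len(kappas), replace=True)
        boots[i] = estimate(sample)
    return lp, (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))


def sample_wlc_curvature(
    lp: float, delta_c: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw curvature magnitudes from the 3D WLC (Rayleigh) density."""
    sigma = 1.0 / np.sqrt(lp * delta_c)
    return rng.rayleigh(sigma, size=n)


@dataclass
class SpherocylinderProfile:
    """Density over (distance to closest cell tip) x (normalized radius)."""

    xt_edges: np.ndarray
    r_edges: np.ndarray  # in units of r / R_c
    counts: np.ndarray  # (n_xt, n_r)
    density: np.ndarray  # counts / bin volume


def spherocylinder_density(
    net: Network,
    tip1: np.ndarray,
    tip2: np.ndarray,
    R_c: float,
    n_xt: int = 10,
    n_r: int = 5,
    xt_max: float | None = None,
) -> SpherocylinderProfile:
    """Snake-point density in spherocylinder coordinates of a rod-shaped cell.

    For each point: x_t is the distance to the closest cell tip (axial
    distance to the near tip plane when inside the cylinder, Euclidean to
    the tip point beyond it) and r the perpendicular distance to the
    symmetry axis.  The 2D histogram over (x_t, r / R_c) is normalized by
    the cylindrical bin volume 2 pi r_mid dr dx_t.  Points with r > R_c
    fall into the outermost radial bin (with a warning).
    """
    tip1 = np.asarray(tip1, dtype=np.float64)
    tip2 = np.asarray(tip2, dtype=np.float64)
    axis = tip2 - tip1
    L = np.linalg.norm(axis)
    if L == 0:
        raise ValueError("cell tips must be distinct")
    if R_c <= 0:
        raise ValueError("R_c must be positive")
    u = axis / L
    pts = net.all_points()
    if len(pts) == 0:
        raise ValueError("empty network")
    rel = pts - tip1
    a = rel @ u  # axial coordinate in [0, L] inside the cylinder
    r = np.linalg.norm(rel - np.outer(a, u), axis=1)
    inside = (a >= 0) & (a <= L)
    xt = np.where(inside, np.minimum(a, L - a), 0.0)
    d1 = np.linalg.norm(pts - tip1, axis=1)
    d2 = np.linalg.norm(pts - tip2, axis=1)
    xt = np.where(inside, xt, np.minimum(d1, d2))
    if np.any(r > R_c):
        logger.warning("%d points beyond R_c counted in the outermost bin",
                       int(np.sum(r > R_c)))
    rnorm = np.clip(r / R_c, 0.0, 1.0 - 1e-12)
    if xt_max is None:
        xt_max = float(L / 2)
    xt_edges = np.linspace(0.0, xt_max, n_xt + 1)
    r_edges = np.linspace(0.0, 1.0, n_r + 1)
    counts, _, _ = np.histogram2d(
        np.clip(xt, 0, xt_max - 1e-12), rnorm, bins=[xt_edges, r_edges]
    )
    dxt = np.diff(xt_edges)
    r_mid = 0.5 * (r_edges[:-1] + r_edges[1:]) * R_c
    dr = np.diff(r_edges) * R_c
    vol = 2 * np.pi * np.outer(dxt, r_mid * dr)
    return SpherocylinderProfile(xt_edges, r_edges, counts, counts / vol)
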