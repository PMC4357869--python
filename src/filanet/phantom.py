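"""Synthetic filament phantoms: ground-truth networks rendered as noisy images.

The rendering recipe mimics confocal imaging of labelled filaments: assign a
background intensity (30) everywhere and a foreground intensity (90) to the
centerline voxels, convolve with an anisotropic Gaussian kernel
sigma = (1.73, 1.73, 5.0) voxels standing in for the point spread function,
scale the result by 0.4 and draw each voxel from a Poisson law with that
mean (shot noise).  A Gaussian-noise variant replaces the Poisson draw with
additive zero-mean noise.

Two normalization conventions for the PSF kernel are offered.  ``"sum"``
(unit integral) conserves total photon count; a 1-voxel-thick centerline is
then strongly diluted by the blur.  ``"peak"`` (unit maximum) keeps the
assigned foreground close to the post-blur ridge intensity.  Together with
the foreground ``thickness`` these are the calibration knobs used to match a
requested mean local SNR; see :func:`calibrate_thickness`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from filanet.imgio import Volume


@dataclass
class GroundTruth:
    """A set of ground-truth centerline polylines inside a voxel grid.

    polylines are (m, 3) float arrays of (x, y, z) voxel coordinates with
    consecutive points at most 1 voxel apart (after densification).
    """

    polylines: list[np.ndarray]
    box: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, dtype=np.float64) for p in self.polylines]
        box = np.asarray(self.box, dtype=np.float64)
        for p in self.polylines:
            if p.ndim != 2 or p.shape[1] != 3:
                raise ValueError("polylines must be (m, 3) arrays")
            if np.any(p < -0.5) or np.any(p > box - 0.5):
                raise ValueError("ground-truth point outside the box")

    def all_points(self) -> np.ndarray:
        if not self.polylines:
            return np.empty((0, 3))
        return np.vstack(self.polylines)


@dataclass
class PhantomSpec:
    """Imaging and noise parameters for rendering a GroundTruth.

    Intensities are raw (pre-rescaling) units.  ``thickness`` is the
    diameter in voxels of the rasterized foreground tube; ``kernel_norm``
    selects sum- or peak-normalization of the PSF kernel.
    """

    background: float = 30.0
    foreground: float = 90.0
    psf_sigma: tuple[float, float, float] = (1.73, 1.73, 5.0)
    intensity_scale: float = 0.4
    noise_model: str = "shot"  # "shot" | "gaussian" | "none"
    gaussian_sigma: float = 3.5
    seed: int = 0
    thickness: float = 1.0
    kernel_norm: str = "sum"  # "sum" | "peak"

    def __post_init__(self) -> None:
        if not (self.foreground > self.background > 0):
            raise ValueError("require foreground > background > 0")
        if any(s <= 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma components must be positive")
        if not (0 < self.intensity_scale <= 1):
            raise ValueError("intensity_scale must be in (0, 1]")
        if self.noise_model not in ("shot", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.kernel_norm not in ("sum", "peak"):
            raise ValueError(f"unknown kernel normalization {self.kernel_norm!r}")


def densify(points: np.ndarray, max_step: float = 1.0) -> np.ndarray:
    """Insert points along a polyline so consecutive gaps are <= max_step."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        return pts.copy()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    out = [pts[0]]
    for i, d in enumerate(seg):
        n = max(1, int(np.ceil(d / max_step - 1e-9)))
        for j in range(1, n + 1):
            out.append(pts[i] + (pts[i + 1] - pts[i]) * (j / n))
    return np.asarray(out)


def _clip_segment(p0, p1, lo, hi):
    """Clip segment p0-p1 to the axis-aligned box [lo, hi]; None if outside."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for k in range(3):
        if abs(d[k]) < 1e-12:
            if p0[k] < lo[k] or p0[k] > hi[k]:
                return None
            continue
        ta = (lo[k] - p0[k]) / d[k]
        tb = (hi[k] - p0[k]) / d[k]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
    if t0 >= t1:
        return None
    return p0 + t0 * d, p0 + t1 * d


def make_rod_mesh(
    box: tuple[int, int, int],
    n: int,
    length_range: tuple[float, float] = (40.0, 90.0),
    seed: int = 0,
    margin: float = 8.0,
) -> GroundTruth:
    """Random straight-rod meshwork: n rods of uniformly random position and
    orientation, clipped to the box inset by ``margin`` voxels (keeps the
    rendered signal clear of the grid border), densified to <= 1-voxel steps.
    """
    box = tuple(int(b) for b in box)
    lo = np.full(3, margin, dtype=np.float64)
    hi = np.asarray(box, dtype=np.float64) - 1 - margin
    if np.any(hi - lo < length_range[0] / 2):
        raise ValueError("box too small for the requested minimum rod length")
    rng = np.random.default_rng(seed)
    polylines = []
    while len(polylines) < n:
        center = lo + rng.random(3) * (hi - lo)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        length = rng.uniform(*length_range)
        clipped = _clip_segment(center - u * length / 2, center + u * length / 2, lo, hi)
        if clipped is None:
            continue
        p0, p1 = clipped
        if np.linalg.norm(p1 - p0) < length_range[0] / 2:
            continue  # too little survived clipping; redraw
        polylines.append(densify(np.array([p0, p1]), 1.0))
    return GroundTruth(polylines, box)


def make_crossing_rods(
    box: tuple[int, int, int] = (64, 64, 16), angle_deg: float = 90.0
) -> GroundTruth:
    """Two straight rods crossing at the box center in the mid-z plane.

    Deterministic; the canonical two-crossing-filaments example used to
    demonstrate T-junction formation and junction reconfiguration.
    """
    box = tuple(int(b) for b in box)
    c = (np.asarray(box, dtype=np.float64) - 1) / 2
    half = min(box[0], box[1]) / 2 - 9
    a = np.deg2rad(angle_deg / 2)
    d1 = np.array([np.cos(a), np.sin(a), 0.0])
    d2 = np.array([np.cos(a), -np.sin(a), 0.0])
    polys = [
        densify(np.array([c - half * d1, c + half * d1]), 1.0),
        densify(np.array([c - half * d2, c + half * d2]), 1.0),
    ]
    return GroundTruth(polys, box)


def _sample_bend_angle(rng: np.random.Generator, sigma: float) -> float:
    """Draw a 3D worm-like-chain polar bend angle.

    Target density on [0, pi] is proportional to
    exp(-theta^2 / (2 sigma^2)) * sin(theta) with sigma^2 = step / lp.
    Rejection sampling from the Rayleigh(sigma) proposal (density
    proportional to theta * exp(-theta^2 / 2 sigma^2)) with acceptance
    ratio sin(theta)/theta <= 1.
    """
    while True:
        theta = rng.rayleigh(sigma)
        if theta >= np.pi:
            continue
        if theta == 0.0 or rng.random() <= np.sin(theta) / theta:
            return theta


def _rotate_tangent(t: np.ndarray, theta: float, phi: float) -> np.ndarray:
    # orthonormal frame around t
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    new = (
        np.cos(theta) * t
        + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    )
    return new / np.linalg.norm(new)


def make_wlc_chains(
    box: tuple[int, int, int],
    n: int,
    contour_length: float,
    lp: float,
    dim: int = 3,
    seed: int = 0,
    step: float = 1.0,
    margin: float = 4.0,
    max_retries: int = 200,
) -> GroundTruth:
    """Discrete worm-like chains with persistence length ``lp`` (voxels).

    In 3D the tangent is rotated at each arc-length step by a polar angle
    drawn from p(theta) ~ exp(-lp theta^2 / (2 step)) sin(theta) with uniform
    azimuth, giving the tangent autocorrelation <t(s) . t(s+D)> = exp(-D/lp).
    In 2D the in-plane turn angle is Gaussian with variance step/lp.  Chains
    escaping the box are redrawn up to ``max_retries`` times.
    """
    if lp <= 0:
        raise ValueError("persistence length must be positive")
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    box = tuple(int(b) for b in box)
    rng = np.random.default_rng(seed)
    lo = np.full(3, margin)
    hi = np.asarray(box, dtype=np.float64) - 1 - margin
    if dim == 2:
        lo[2] = hi[2] = (box[2] - 1) / 2
    sigma = np.sqrt(step / lp)
    nsteps = int(np.round(contour_length / step))
    polylines = []
    for _ in range(n):
        for attempt in range(max_retries + 1):
            p = lo + rng.random(3) * np.maximum(hi - lo, 0)
            if dim == 3:
                t = rng.normal(size=3)
            else:
                t = np.array([*rng.normal(size=2), 0.0])
            t /= np.linalg.norm(t)
            pts = [p.copy()]
            ok = True
            for _ in range(nsteps):
                if dim == 3:
                    theta = _sample_bend_angle(rng, sigma)
                    phi = rng.uniform(0, 2 * np.pi)
                    t = _rotate_tangent(t, theta, phi)
                else:
                    ang = np.arctan2(t[1], t[0]) + rng.normal(0, sigma)
                    t = np.array([np.cos(ang), np.sin(ang), 0.0])
                p = p + step * t
                if np.any(p < lo - 1e-9) or np.any(p > hi + 1e-9):
                    ok = False
                    break
                pts.append(p.copy())
            if ok:
                polylines.append(densify(np.asarray(pts), 1.0))
                break
        else:
            raise RuntimeError(
                f"worm-like chain escaped the box {max_retries} times; "
                "use a larger box or shorter contour length"
            )
    return GroundTruth(polylines, box)


def rasterize(gt: GroundTruth, thickness: float = 1.0) -> np.ndarray:
    """Boolean foreground mask: voxels within thickness/2 of a centerline voxel."""
    mask = np.zeros(gt.box, dtype=bool)
    for poly in gt.polylines:
        pts = densify(poly, 0.5)
        idx = np.round(pts).astype(int)
        idx = np.clip(idx, 0, np.asarray(gt.box) - 1)
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if thickness > 1.0:
        dist = ndimage.distance_transform_edt(~mask)
        mask = dist <= thickness / 2
    return mask


def render(
    gt: GroundTruth, spec: PhantomSpec, rng: np.random.Generator | None = None
) -> Volume:
    """Render a GroundTruth into a raw-intensity noisy Volume.

    Foreground tube voxels get ``spec.foreground`` on a ``spec.background``
    field; the foreground excess is blurred by the anisotropic Gaussian PSF
    (truncated at 4 sigma), the image is scaled by ``intensity_scale`` and
    per-voxel noise is applied (Poisson for "shot", additive for
    "gaussian", none for "none").  The caller rescales to [0, 1].
    """
    if not gt.polylines:
        raise ValueError("cannot render an empty GroundTruth")
    mask = rasterize(gt, spec.thickness)
    excess = (spec.foreground - spec.background) * mask.astype(np.float64)
    blurred = ndimage.gaussian_filter(excess, sigma=spec.psf_sigma, truncate=4.0)
    if spec.kernel_norm == "peak":
        blurred *= float(np.prod(spec.psf_sigma)) * (2 * np.pi) ** 1.5
    ip = spec.intensity_scale * (spec.background + blurred)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "shot":
        data = rng.poisson(np.clip(ip, 0, None)).astype(np.float64)
    elif spec.noise_model == "gaussian":
        data = ip + rng.normal(0.0, spec.gaussian_sigma, size=ip.shape)
    else:
        data = ip
    return Volume(np.clip(data, 0.0, None))


def _gt_tangents(poly: np.ndarray) -> np.ndarray:
    tan = np.gradient(poly, axis=0)
    norm = np.linalg.norm(tan, axis=1, keepdims=True)
    return tan / np.maximum(norm, 1e-12)


def mean_local_snr(
    v: Volume, gt: GroundTruth, bg_radii: tuple[float, float] = (3.0, 6.0)
) -> float:
    """Mean local SNR over ground-truth centerline points.

    Uses the same annulus estimator as the F-function: for each centerline
    point, (I_f - I_b) / sigma_b with I_b, sigma_b sampled on circles of
    radius in ``bg_radii`` perpendicular to the local tangent.
    """
    from filanet.optimize import local_snr

    vals = []
    for poly in gt.polylines:
        tans = _gt_tangents(poly)
        for p, t in zip(poly, tans):
            vals.append(local_snr(v, p, t, bg_radii))
    return float(np.mean(vals))


def calibrate_thickness(
    target_snr: float,
    spec: PhantomSpec,
    box: tuple[int, int, int] = (64, 64, 64),
    n_rods: int = 4,
    seed: int = 0,
    tol: float = 0.1,
    bounds: tuple[float, float] = (1.0, 8.0),
) -> float:
    """Find the foreground thickness whose rendered mean local SNR matches
    ``target_snr``, by bisection on a small rod phantom.

    Mean local SNR increases with thickness (more signal mass survives the
    PSF blur), so bisection is well-posed.  Returns the calibrated
    thickness; other spec fields are taken from ``spec`` unchanged.
    """
    from dataclasses import replace

    gt = make_rod_mesh(box, n_rods, (25.0, 40.0), seed=seed)

    def measure(th: float) -> float:
        s = replace(spec, thickness=th)
        v = render(gt, s, rng=np.random.default_rng(seed + 1))
        return mean_local_snr(v, gt)

    lo, hi = bounds
    f_lo, f_hi = measure(lo), measure(hi)
    if target_snr <= f_lo:
        return lo
    if target_snr >= f_hi:
        return hi
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        f_mid = measure(mid)
        if abs(f_mid - target_snr) < tol:
            return mid
        if f_mid < target_snr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def write_polylines(gt: GroundTruth, path) -> None:
    """Write ground truth as plain text: ``id x y z`` per point, blank line
    between polylines, ``#box nx ny nz`` header."""
    with open(path, "w") as fh:
        fh.write(f"#box {gt.box[0]} {gt.box[1]} {gt.box[2]}\n")
        for i, poly in enumerate(gt.polylines):
            for p in poly:
                fh.write(f"{i} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")


def read_polylines(path) -> GroundTruth:
    """Inverse of :func:`write_polylines`."""
    box = None
    polylines: list[list[list[float]]] = []
    current: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                if current:
                    polylines.append(current)
                    current = []
                continue
            if line.startswith("#box"):
                box = tuple(int(x) for x in line.split()[1:4])
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'id x y z'")
            current.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if current:
        polylines.append(current)
    if box is None:
        pts = np.vstack([np.asarray(p) for p in polylines])
        box = tuple(int(np.ceil(pts[:, k].max())) + 1 for k in range(3))
    return GroundTruth([np.asarray(p) for p in polylines], box)
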