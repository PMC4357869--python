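"""Extraction scoring and ground-truth-free parameter optimization.

With ground truth available, an extraction is scored by the symmetric
Hausdorff distance (worst-case nearest-neighbor distance, both directions)
and the vertex error (mean nearest-neighbor distance, averaged over both
directions), computed on networks densified to 0.5-voxel point spacing.

Without ground truth, the F-function

    F = -L_total + c * L_<t

scores a result from the image alone: L_total is the total snake length,
L_<t the length of snake segments lying in regions whose local SNR
(I_f - I_b) / sigma_b falls below a threshold t, and c > 1 sets how
heavily uncertain length is penalized.  Minimizing F over a (tau, k_str)
scan favors complete extractions while rejecting snakes tracing noise.
Varying (t, c) over the empirically valid triangle
{1 < t < 5, 1 < c < 5, 3 < t + c < 6} yields a small set of candidate
optimal parameter cells for the user to choose from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from filanet.dynamics import ExtractionParams, extract_all
from filanet.imgio import Volume
from filanet.phantom import densify
from filanet.topology import Network, cluster_junctions, reconfigure

logger = logging.getLogger(__name__)

SNR_SIGMA_FLOOR = 1e-6


@dataclass
class EvalScores:
    hausdorff: float
    vertex_error: float


@dataclass
class FScore:
    """F = -L_total + c * L_<t, with the lengths that produced it."""

    l_total: float
    l_low: float
    t: float
    c: float

    @property
    def f(self) -> float:
        return -self.l_total + self.c * self.l_low


def densify_points(polylines, max_step: float = 0.5) -> np.ndarray:
    """Stack densified polylines into one (n, 3) point set."""
    pts = [densify(np.asarray(p), max_step) for p in polylines if len(p) >= 1]
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def _directed_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(b).query(a)
    return d


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (voxels)."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("hausdorff requires nonempty point sets")
    return float(max(_directed_dists(a, b).max(), _directed_dists(b, a).max()))


def vertex_error(a: np.ndarray, b: np.ndarray) -> float:
    """Mean nearest-neighbor distance, averaged over both directions."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("vertex_error requires nonempty point sets")
    return float(0.5 * (_directed_dists(a, b).mean() + _directed_dists(b, a).mean()))


def local_snr(
    v: Volume,
    point: np.ndarray,
    tangent: np.ndarray,
    bg_radii: tuple[float, float] = (3.0, 6.0),
) -> float:
    """Local signal-to-noise ratio (I_f - I_b) / sigma_b at a curve point.

    Background statistics come from the annulus perpendicular to the local
    tangent (see :func:`filanet.dynamics.local_background`); sigma_b is
    floored at a small epsilon and the result clamped at 0.
    """
    from filanet.dynamics import local_background

    i_f, i_b, sig = local_background(v, point, tangent, bg_radii)
    return max(0.0, (i_f - i_b) / max(sig, SNR_SIGMA_FLOOR))


def _snake_point_snrs(
    v: Volume, points: np.ndarray, bg_radii: tuple[float, float]
) -> np.ndarray:
    tans = np.gradient(points, axis=0)
    nrm = np.linalg.norm(tans, axis=1, keepdims=True)
    tans = tans / np.maximum(nrm, 1e-12)
    return np.array([local_snr(v, p, t, bg_radii) for p, t in zip(points, tans)])


def network_edge_snr(
    net: Network, v: Volume, bg_radii: tuple[float, float] = (3.0, 6.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge (length, mean endpoint SNR) over all snakes of a network.

    The reusable core of the F-function: F at any (t, c) is a cheap
    reduction over these arrays.
    """
    lengths, snrs = [], []
    for s in net.snakes:
        if s.n_points < 2:
            continue
        psnr = _snake_point_snrs(v, s.points, bg_radii)
        seg = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        lengths.append(seg)
        snrs.append(0.5 * (psnr[:-1] + psnr[1:]))
    if not lengths:
        return np.empty(0), np.empty(0)
    return np.concatenate(lengths), np.concatenate(snrs)


def f_from_edges(
    lengths: np.ndarray, edge_snr: np.ndarray, t: float, c: float
) -> FScore:
    l_total = float(lengths.sum())
    l_low = float(lengths[edge_snr < t].sum())
    return FScore(l_total, l_low, t, c)


def f_function(
    net: Network,
    v: Volume,
    t: float,
    c: float,
    bg_radii: tuple[float, float] = (3.0, 6.0),
) -> FScore:
    """Evaluate F = -L_total + c * L_<t for one extraction result.

    An edge contributes to L_<t when the mean of its endpoint SNRs is
    strictly below t.  Empty networks score F = 0 by convention.
    """
    if c <= 1:
        raise ValueError("penalty factor c must be larger than unity")
    lengths, snrs = network_edge_snr(net, v, bg_radii)
    return f_from_edges(lengths, snrs, t, c)


@dataclass
class ScanCell:
    tau: float
    k_str: float
    network: Network | None
    edge_lengths: np.ndarray | None
    edge_snr: np.ndarray | None
    scores: EvalScores | None = None
    error: str | None = None


@dataclass
class ScanResult:
    """Grid of extraction results over (tau, k_str)."""

    cells: list[ScanCell]
    tau_values: np.ndarray
    kstr_values: np.ndarray

    def to_frame(self, t: float = 3.0, c: float = 2.0):
        """Tidy per-cell summary (tau, k_str, F, L_total, scores) DataFrame."""
        import pandas as pd

        rows = []
        for cell in self.cells:
            row = {"tau": cell.tau, "k_str": cell.k_str, "error": cell.error}
            if cell.edge_lengths is not None:
                fs = f_from_edges(cell.edge_lengths, cell.edge_snr, t, c)
                row.update(F=fs.f, L_total=fs.l_total, L_low=fs.l_low)
            if cell.scores is not None:
                row.update(
                    hausdorff=cell.scores.hausdorff,
                    vertex_error=cell.scores.vertex_error,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_against_gt(net: Network, gt_polylines) -> EvalScores:
    """Hausdorff + vertex error of a network against ground-truth polylines,
    both densified to 0.5-voxel spacing."""
    a = densify_points([s.points for s in net.snakes], 0.5)
    b = densify_points(gt_polylines, 0.5)
    return EvalScores(hausdorff(a, b), vertex_error(a, b))


def extract_network(v: Volume, p: ExtractionParams) -> Network:
    """Convenience: full pipeline snakes -> junction nodes -> reconfigured net."""
    snakes, tjs = extract_all(v, p)
    nodes = cluster_junctions(tjs, p.junction_cluster_dist)
    return reconfigure(snakes, nodes, junction_cluster_dist=p.junction_cluster_dist)


def scan(
    v: Volume,
    tau_values,
    kstr_values,
    base: ExtractionParams | None = None,
    gt_polylines=None,
    bg_radii: tuple[float, float] | None = None,
) -> ScanResult:
    """Run the full extraction over a (tau, k_str) grid.

    Per-cell failures are recorded on the cell, never abort the scan.
    When ground-truth polylines are supplied, Hausdorff and vertex-error
    scores are attached to each cell.
    """
    if base is None:
        base = ExtractionParams()
    if bg_radii is None:
        bg_radii = base.bg_radii
    cells = []
    for tau in tau_values:
        for k_str in kstr_values:
            p = replace(base, tau=float(tau), k_str=float(k_str))
            try:
                net = extract_network(v, p)
                lengths, snrs = network_edge_snr(net, v, bg_radii)
                scores = None
                if gt_polylines is not None and len(net.snakes) > 0:
                    scores = evaluate_against_gt(net, gt_polylines)
                cells.append(ScanCell(p.tau, p.k_str, net, lengths, snrs, scores))
            except Exception as exc:
                logger.warning("scan cell tau=%g k_str=%g failed: %s", tau, k_str, exc)
                cells.append(ScanCell(float(tau), float(k_str), None, None, None,
                                      error=str(exc)))
    return ScanResult(cells, np.asarray(tau_values, float), np.asarray(kstr_values, float))


def valid_tc_grid(step: float = 0.2) -> list[tuple[float, float]]:
    """(t, c) grid inside the valid triangle 1<t<5, 1<c<5, 3<t+c<6."""
    vals = np.arange(1.0 + step, 5.0, step)
    return [
        (round(float(t), 10), round(float(c), 10))
        for t in vals
        for c in vals
        if 3.0 < t + c < 6.0
    ]


def candidates(
    sr: ScanResult, tc_step: float = 0.2
) -> list[tuple[float, float, ScanCell]]:
    """Candidate optimal cells: for each (t, c) in the valid triangle, the
    (tau, k_str) cell minimizing F; de-duplicated.

    Ties across cells break toward smaller k_str, then smaller tau (the
    most conservative extraction among equals).
    """
    ok = [c for c in sr.cells if c.edge_lengths is not None]
    if not ok:
        return []
    picked: dict[tuple[float, float], tuple[float, float]] = {}
    out = []
    for t, c in valid_tc_grid(tc_step):
        best = min(
            ok,
            key=lambda cell: (
                f_from_edges(cell.edge_lengths, cell.edge_snr, t, c).f,
                cell.k_str,
                cell.tau,
            ),
        )
        key = (best.tau, best.k_str)
        if key not in picked:
            picked[key] = (t, c)
            out.append((t, c, best))
    return out
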