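"""Junction clustering and network topology reconfiguration.

T-junctions recorded during evolution are clustered (single linkage) into
junction nodes.  Every snake passing near a node is cut there, and the
incident segment ends are greedily re-paired by continuation angle: two
segments whose outgoing tangents are closest to antiparallel (angle near
180 degrees) are spliced into one snake running smoothly through the
junction.  Segments without a smooth continuation terminate at the node.
The result is a network whose snakes follow physical filaments across
junctions instead of stopping or kinking there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from filanet.dynamics import FREE, Snake, TJunction


@dataclass
class Network:
    """Converged snakes, junction nodes and their incidence."""

    snakes: list[Snake]
    junctions: list[np.ndarray] = field(default_factory=list)
    incidence: list[list[tuple[int, str]]] = field(default_factory=list)
    # incidence[j]: list of (snake id, "head"|"tail"|"through") at node j

    def snake_by_id(self, sid: int) -> Snake:
        for s in self.snakes:
            if s.id == sid:
                return s
        raise KeyError(f"no snake with id {sid}")

    def total_length(self) -> float:
        return float(sum(s.length() for s in self.snakes))

    def all_points(self) -> np.ndarray:
        if not self.snakes:
            return np.empty((0, 3))
        return np.vstack([s.points for s in self.snakes])


def cluster_junctions(
    tjs: list[TJunction], junction_cluster_dist: float
) -> list[np.ndarray]:
    """Single-linkage clustering of T-junction positions; nodes at centroids."""
    if not tjs:
        return []
    pos = np.array([t.position for t in tjs])
    if len(pos) == 1:
        return [pos[0]]
    labels = fcluster(
        linkage(pdist(pos), method="single"),
        t=junction_cluster_dist,
        criterion="distance",
    )
    return [pos[labels == lbl].mean(axis=0) for lbl in np.unique(labels)]


def _segment_tangent_at(seg: np.ndarray, at_head: bool, k: int = 3) -> np.ndarray:
    """Outgoing tangent (pointing away from the node end) over ~k edges."""
    k = min(k, len(seg) - 1)
    t = (seg[k] - seg[0]) if at_head else (seg[-1 - k] - seg[-1])
    nrm = np.linalg.norm(t)
    return t / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])


def _cut_snake(points: np.ndarray, cut_idx: list[int], min_pts: int = 2):
    """Split a polyline at the given interior indices (shared cut points)."""
    cuts = sorted(set(cut_idx))
    bounds = [0] + cuts + [len(points) - 1]
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a + 1 >= min_pts:
            segs.append(points[a : b + 1].copy())
    return segs


def reconfigure(
    snakes: list[Snake],
    nodes: list[np.ndarray],
    angle_threshold: float = 120.0,
    junction_cluster_dist: float = 3.0,
) -> Network:
    """Cut snakes at junction nodes and splice smooth continuations.

    At each node, incident segment ends are paired greedily in decreasing
    order of continuation angle (the angle between the two outgoing
    tangents; 180 degrees = perfectly straight through).  Only pairs with
    continuation angle >= ``angle_threshold`` are spliced.  Nodes with
    fewer than 3 incident segment ends are not genuine junctions and are
    dropped (their cuts are re-spliced).
    """
    if not nodes:
        return Network([s.copy() for s in snakes], [], [])
    node_arr = np.array([np.asarray(n, dtype=np.float64) for n in nodes])

    # --- cut every snake at the point nearest each node it passes ---------
    segments: list[np.ndarray] = []  # polyline pieces
    seg_end_node: list[dict] = []  # per segment: {"head": node_idx|None, ...}
    for s in snakes:
        d = np.linalg.norm(s.points[:, None, :] - node_arr[None, :, :], axis=2)
        cut_idx: list[int] = []
        end_node: dict[int, int] = {}  # point index -> node
        for j in range(len(node_arr)):
            dm = d[:, j]
            i = int(np.argmin(dm))
            if dm[i] > junction_cluster_dist:
                continue
            if 0 < i < len(s.points) - 1:
                cut_idx.append(i)
            end_node[i] = j
        segs = _cut_snake(s.points, cut_idx)
        for seg in segs:
            ends = {"head": None, "tail": None}
            for i, j in end_node.items():
                target = s.points[i]
                if np.allclose(seg[0], target):
                    ends["head"] = j
                if np.allclose(seg[-1], target):
                    ends["tail"] = j
            segments.append(seg)
            seg_end_node.append(ends)

    # --- greedy pairing of incident ends at each node ---------------------
    # an "end" is (segment index, "head"|"tail")
    node_ends: list[list[tuple[int, str]]] = [[] for _ in node_arr]
    for si, ends in enumerate(seg_end_node):
        for which in ("head", "tail"):
            j = ends[which]
            if j is not None:
                node_ends[j].append((si, which))

    seg_len = [float(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum())
               for seg in segments]
    pairings: dict[tuple[int, str], tuple[int, str]] = {}
    real_nodes: list[int] = []
    for j, ends in enumerate(node_ends):
        if len(ends) >= 3:
            real_nodes.append(j)
        cand = []
        for a in range(len(ends)):
            for b in range(a + 1, len(ends)):
                (sa, wa), (sb, wb) = ends[a], ends[b]
                if sa == sb:
                    continue  # a segment cannot splice to itself at a node
                ta = _segment_tangent_at(segments[sa], wa == "head")
                tb = _segment_tangent_at(segments[sb], wb == "head")
                ang = np.degrees(np.arccos(np.clip(np.dot(ta, tb), -1.0, 1.0)))
                cand.append((ang, seg_len[sa] + seg_len[sb], ends[a], ends[b]))
        cand.sort(key=lambda c: (-c[0], -c[1]))
        used = set()
        for ang, _, ea, eb in cand:
            if ang < angle_threshold:
                break
            if ea in used or eb in used or ea in pairings or eb in pairings:
                continue
            pairings[ea] = eb
            pairings[eb] = ea
            used.add(ea)
            used.add(eb)

    # --- stitch paired segments into final snakes -------------------------
    visited = [False] * len(segments)
    out_snakes: list[Snake] = []
    sid = 0

    def oriented(si: int, start_from: str) -> np.ndarray:
        return segments[si] if start_from == "head" else segments[si][::-1]

    for si in range(len(segments)):
        if visited[si]:
            continue
        # find a free end to start from (head preferred); cycles start anywhere
        start = None
        for which in ("head", "tail"):
            if (si, which) not in pairings:
                start = which
                break
        if start is None:
            start = "head"  # closed loop through junctions; break it here
        chain_pts = [oriented(si, start)]
        visited[si] = True
        cur = (si, "tail" if start == "head" else "head")
        while cur in pairings:
            nxt_si, nxt_which = pairings[cur]
            if visited[nxt_si]:
                break
            chain_pts.append(oriented(nxt_si, nxt_which))
            visited[nxt_si] = True
            cur = (nxt_si, "tail" if nxt_which == "head" else "head")
        pts = np.vstack(chain_pts)
        # drop exact duplicates at splice points
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
        pts = pts[keep]
        if len(pts) >= 2:
            out_snakes.append(Snake(pts, id=sid))
            sid += 1

    # --- incidence of final snakes at surviving nodes ---------------------
    junctions = [node_arr[j] for j in real_nodes]
    incidence: list[list[tuple[int, str]]] = []
    for j in real_nodes:
        inc: list[tuple[int, str]] = []
        node = node_arr[j]
        for s in out_snakes:
            d = np.linalg.norm(s.points - node, axis=1)
            if d.min() > junction_cluster_dist:
                continue
            i = int(np.argmin(d))
            if i == 0:
                inc.append((s.id, "head"))
            elif i == len(s.points) - 1:
                inc.append((s.id, "tail"))
            else:
                inc.append((s.id, "through"))
        incidence.append(inc)
    return Network(out_snakes, junctions, incidence)


def node_degree(net: Network, j: int) -> int:
    """Number of incident segment ends at node j (a through-snake counts 2)."""
    return sum(2 if which == "through" else 1 for _, which in net.incidence[j])


def edit_network(net: Network, op: str, **args) -> Network:
    """Programmatic network edits: the scripted stand-ins for manual curation.

    op = "delete_snake" (snake_id), "trim" (snake_id, start, stop),
    "delete_junction" (junction_index).
    """
    snakes = [s.copy() for s in net.snakes]
    junctions = [j.copy() for j in net.junctions]
    incidence = [list(i) for i in net.incidence]
    if op == "delete_snake":
        sid = args["snake_id"]
        if all(s.id != sid for s in snakes):
            raise KeyError(f"no snake with id {sid}")
        snakes = [s for s in snakes if s.id != sid]
        incidence = [[e for e in inc if e[0] != sid] for inc in incidence]
    elif op == "trim":
        sid, start, stop = args["snake_id"], args["start"], args["stop"]
        for k, s in enumerate(snakes):
            if s.id == sid:
                pts = s.points[start:stop]
                if len(pts) < 2:
                    raise ValueError("trim would leave fewer than 2 points")
                snakes[k] = Snake(pts.copy(), s.spacing, FREE, FREE, s.id)
                break
        else:
            raise KeyError(f"no snake with id {sid}")
    elif op == "delete_junction":
        j = args["junction_index"]
        if not (0 <= j < len(junctions)):
            raise KeyError(f"no junction with index {j}")
        del junctions[j]
        del incidence[j]
    else:
        raise ValueError(f"unknown edit operation {op!r}")
    return Network(snakes, junctions, incidence)
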