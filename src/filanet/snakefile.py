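"""Plain-text snake file format.

Header lines ``#param key value`` echo the run configuration, body lines
``s <snake_id> <point_idx> <x> <y> <z> <intensity>`` carry snake points,
and ``#junction <x> <y> <z> [id:end ...]`` lines the junction nodes with
their incidence.  Round-trips losslessly to 6 decimals.
"""

from __future__ import annotations

import numpy as np

from filanet.dynamics import Snake
from filanet.imgio import Volume
from filanet.topology import Network


def write_snakes(net: Network, path, params: dict | None = None,
                 v: Volume | None = None) -> None:
    with open(path, "w") as fh:
        for key in sorted(params or {}):
            fh.write(f"#param {key} {params[key]}\n")
        for s in net.snakes:
            inten = v.interp(s.points) if v is not None else np.zeros(s.n_points)
            for i, (p, it) in enumerate(zip(s.points, inten)):
                fh.write(
                    f"s {s.id} {i} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {it:.6f}\n"
                )
        for node, inc in zip(net.junctions, net.incidence):
            tags = " ".join(f"{sid}:{which}" for sid, which in inc)
            fh.write(
                f"#junction {node[0]:.6f} {node[1]:.6f} {node[2]:.6f} {tags}\n".rstrip()
                + "\n"
            )


def read_snakes(path) -> tuple[Network, dict]:
    params: dict[str, str] = {}
    snake_pts: dict[int, list] = {}
    junctions: list[np.ndarray] = []
    incidence: list[list[tuple[int, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                if line.startswith("#param "):
                    _, key, value = line.split(maxsplit=2)
                    params[key] = value
                elif line.startswith("#junction "):
                    parts = line.split()
                    junctions.append(np.array([float(x) for x in parts[1:4]]))
                    inc = []
                    for tag in parts[4:]:
                        sid, which = tag.split(":")
                        inc.append((int(sid), which))
                    incidence.append(inc)
                elif line.startswith("s "):
                    _, sid, idx, x, y, z, it = line.split()
                    snake_pts.setdefault(int(sid), []).append(
                        (int(idx), float(x), float(y), float(z))
                    )
                elif line.startswith("#"):
                    continue
                else:
                    raise ValueError("unrecognized record")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
    snakes = []
    for sid in sorted(snake_pts):
        rows = sorted(snake_pts[sid])
        pts = np.array([[x, y, z] for _, x, y, z in rows])
        snakes.append(Snake(pts, id=sid))
    return Network(snakes, junctions, incidence), params
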