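"""Readers and writers for the external formats the framework touches.

Structures travel as STL (2D polylines become degenerate 3D "ribbons" of zero
depth) and CSV point tables; motion keyframes, metric series and transform
logs as CSV with unit-bearing headers; field snapshots as legacy-ASCII VTK
structured-points files readable by standard VTK tooling; run configuration
as TOML; and each batch writes a plain-text manifest recording the case id,
configuration snapshot, software version and timestamps.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .grid import FlowState
from .motion import MotionKeyframes, RigidTransform
from .structure import LagrangianStructure, polyline

RIBBON_DEPTH = 1e-4  # m; z-extent of the STL ribbon for 2D polylines


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------
def write_structure_stl(structure: LagrangianStructure, path) -> None:
    """Write each polyline segment as a thin triangulated ribbon at z=0.

    ASCII STL with full double precision (binary STL stores float32, which
    cannot round-trip coordinates to the 1e-9 m dedup tolerance).
    """
    tris = []
    for seg in structure.segments:
        pts = structure.X[seg]
        for a, b in zip(pts[:-1], pts[1:]):
            p0 = (a[0], a[1], 0.0)
            p1 = (b[0], b[1], 0.0)
            p2 = (a[0], a[1], RIBBON_DEPTH)
            p3 = (b[0], b[1], RIBBON_DEPTH)
            tris.append((p0, p1, p2))
            tris.append((p1, p3, p2))
    with open(path, "w") as fh:
        fh.write("solid ibvalve\n")
        for tri in tris:
            fh.write("  facet normal 0 0 0\n    outer loop\n")
            for v in tri:
                fh.write(f"      vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid ibvalve\n")


def read_structure_stl(path, role: str = "wall") -> LagrangianStructure:
    """Read an STL ribbon back as a 2D polyline structure.

    Vertices are de-duplicated within 1e-9 m, the z=0 section is extracted,
    and point ordering is deterministic: a chain is traced through the edge
    graph starting from the lexicographically smallest vertex.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl")
    except Exception as exc:  # corrupt / truncated input
        size = path.stat().st_size
        raise ValueError(
            f"cannot parse STL {path} (file size {size} bytes): {exc}"
        ) from exc
    if mesh.is_empty or len(mesh.vertices) == 0:
        raise ValueError(f"empty STL {path} (no facets, size {path.stat().st_size} bytes)")
    v = np.asarray(mesh.vertices)
    sect = v[np.abs(v[:, 2]) < 1e-9][:, :2]
    # deduplicate within 1e-9
    key = np.round(sect / 1e-9).astype(np.int64)
    _, order = np.unique(key, axis=0, return_index=True)
    pts2 = sect[np.sort(order)]
    # trace a chain through z=0 edges of the mesh
    edges = set()
    vkey = {tuple(k): i for i, k in enumerate(np.round(pts2 / 1e-9).astype(np.int64))}

    def node(p):
        return vkey.get(tuple(np.round(p[:2] / 1e-9).astype(np.int64)))

    for f in mesh.faces:
        tri = v[f]
        at0 = np.abs(tri[:, 2]) < 1e-9
        if at0.sum() == 2:
            a, b = (node(p) for p in tri[at0])
            if a is not None and b is not None and a != b:
                edges.add((min(a, b), max(a, b)))
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    # start at lexicographically smallest endpoint (degree 1) or vertex
    ends = [i for i, nb in adj.items() if len(nb) == 1]
    pool = ends if ends else list(adj)
    start = min(pool, key=lambda i: (pts2[i, 0], pts2[i, 1]))
    chain = [start]
    prev = None
    cur = start
    while True:
        nxt = [n for n in adj.get(cur, []) if n != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        chain.append(cur)
    closed = cur == start and len(chain) > 2
    return polyline(pts2[chain], closed=closed, role=role)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------
def write_keyframes_csv(kf: MotionKeyframes, path) -> None:
    n, nph, _ = kf.displacements.shape
    pid = np.repeat(np.arange(n), nph)
    ph = np.tile(np.arange(nph), n)
    df = pd.DataFrame(
        {
            "point_id": pid,
            "phase_index": ph,
            "dx_m": kf.displacements[:, :, 0].ravel(),
            "dy_m": kf.displacements[:, :, 1].ravel(),
        }
    )
    df.attrs["period_s"] = kf.period
    with open(path, "w") as fh:
        fh.write(f"# period_s={kf.period}\n# phase_times_s={','.join(map(str, kf.phase_times))}\n")
        df.to_csv(fh, index=False)


def read_keyframes_csv(path) -> MotionKeyframes:
    with open(path) as fh:
        period = float(fh.readline().split("=")[1])
        times = np.array([float(x) for x in fh.readline().split("=")[1].split(",")])
        df = pd.read_csv(fh)
    n = df["point_id"].nunique()
    nph = df["phase_index"].nunique()
    D = np.empty((n, nph, 2))
    D[df["point_id"], df["phase_index"], 0] = df["dx_m"]
    D[df["point_id"], df["phase_index"], 1] = df["dy_m"]
    return MotionKeyframes(times, D, period)


def write_transform_log_csv(entries, path) -> None:
    """entries: iterable of (t, RigidTransform)."""
    rows = [
        {"t_s": t, "angle_rad": tr.angle, "tx_m": tr.translation[0], "ty_m": tr.translation[1]}
        for t, tr in entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_points_csv(structure: LagrangianStructure, path) -> None:
    pd.DataFrame(
        {"point_id": np.arange(structure.n_points), "x_m": structure.X[:, 0], "y_m": structure.X[:, 1]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VTK snapshots (legacy ASCII structured points)
# ---------------------------------------------------------------------------
def write_structures_vtk(structures: list, path) -> None:
    """Structure polylines as a legacy-ASCII VTK POLYDATA file."""
    pts = []
    lines = []
    off = 0
    for s in structures:
        for seg in s.segments:
            lines.append(np.arange(off, off + len(seg)))
            pts.append(s.chi[seg])
            off += len(seg)
    pts = np.vstack(pts)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nibvalve structures\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        np.savetxt(fh, np.column_stack([pts, np.zeros(len(pts))]), fmt="%.9g")
        total = sum(len(ln) + 1 for ln in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for ln in lines:
            fh.write(" ".join([str(len(ln))] + [str(i) for i in ln]) + "\n")


def write_snapshot_vtk(
    state: FlowState, path, mask: np.ndarray | None = None, structures: list | None = None
) -> None:
    """Cell-centered velocity (face-averaged), pressure and optional fluid
    mask on a legacy-ASCII VTK STRUCTURED_POINTS grid; structure polylines
    go to a polydata side file (<path stem>_structures.vtk)."""
    state.check_finite()
    if structures:
        side = Path(path).with_name(Path(path).stem + "_structures.vtk")
        write_structures_vtk(structures, side)
    g = state.grid
    uc = 0.5 * (state.u[1:, :] + state.u[:-1, :])
    vc = 0.5 * (state.v[:, 1:] + state.v[:, :-1])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"ibvalve snapshot t={state.t:.9g} s\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {g.nx} {g.ny} 1\n")
        fh.write(f"ORIGIN {g.x0 + g.h / 2} {g.y0 + g.h / 2} 0\n")
        fh.write(f"SPACING {g.h} {g.h} {g.h}\n")
        fh.write(f"POINT_DATA {g.nx * g.ny}\n")
        fh.write("VECTORS velocity_m_s float\n")
        out = np.zeros((g.nx * g.ny, 3))
        out[:, 0] = uc.T.ravel()  # VTK is x-fastest
        out[:, 1] = vc.T.ravel()
        np.savetxt(fh, out, fmt="%.7g")
        fh.write("SCALARS pressure_pa float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, state.p.T.ravel()[:, None], fmt="%.7g")
        if mask is not None:
            fh.write("SCALARS fluid_mask int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, mask.T.ravel().astype(int)[:, None], fmt="%d")


def read_snapshot_vtk(path):
    """Read back a snapshot written by write_snapshot_vtk.

    Returns (velocity (nx, ny, 2), pressure (nx, ny), mask or None).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    dims = next(ln for ln in lines if ln.startswith("DIMENSIONS")).split()
    nx, ny = int(dims[1]), int(dims[2])
    iv = lines.index(next(ln for ln in lines if ln.startswith("VECTORS")))
    vel = np.loadtxt(lines[iv + 1 : iv + 1 + nx * ny])
    ip = next(i for i, ln in enumerate(lines) if ln.startswith("SCALARS pressure"))
    p = np.loadtxt(lines[ip + 2 : ip + 2 + nx * ny])
    mask = None
    for i, ln in enumerate(lines):
        if ln.startswith("SCALARS fluid_mask"):
            mask = np.loadtxt(lines[i + 2 : i + 2 + nx * ny]).astype(bool)
            mask = mask.reshape(ny, nx).T
    uv = np.stack([vel[:, 0].reshape(ny, nx).T, vel[:, 1].reshape(ny, nx).T], axis=-1)
    return uv, p.reshape(ny, nx).T, mask


# ---------------------------------------------------------------------------
# config + manifest
# ---------------------------------------------------------------------------
def read_config_toml(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


class RunManifest:
    """Plain-text run log: case id, config snapshot, software version,
    execution timestamps and per-scenario output paths."""

    def __init__(self, case_id: str, config_snapshot: str = ""):
        self.case_id = case_id
        self.config_snapshot = config_snapshot
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.entries = []

    def add(self, label: str, outputs: list, status: str = "ok", note: str = "") -> None:
        self.entries.append(
            {"label": label, "outputs": [str(o) for o in outputs], "status": status, "note": note}
        )

    def write(self, path) -> None:
        for e in self.entries:
            for o in e["outputs"]:
                if not Path(o).exists():
                    raise FileNotFoundError(f"manifest lists missing output {o}")
        doc = {
            "case_id": self.case_id,
            "software_version": __version__,
            "started": self.started,
            "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "scenarios": self.entries,
        }
        with open(path, "w") as fh:
            fh.write("# ibvalve run manifest\n")
            json.dump(doc, fh, indent=2)
            fh.write("\n")
            if self.config_snapshot:
                fh.write("# --- configuration snapshot (verbatim) ---\n")
                fh.write(self.config_snapshot)
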