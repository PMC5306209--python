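"""Readers and writers for clouds, Hermite meshes and pipeline artifacts.

Clouds: whitespace xyz/txt, PLY (via trimesh), and legacy ASCII VTK
polydata.  Hermite meshes: legacy ASCII VTK polydata carrying the node
positions as POINTS, quad connectivity as POLYGONS, the derivative DOFs
as POINT_DATA field arrays and the per-corner derivative maps as
CELL_DATA field arrays -- a plain-text container that round-trips the
full 12-DOF representation losslessly while remaining loadable (points
and polygons) by standard VTK viewers.  Triangulated PLY/STL export is
available for visualisation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fitting import SegmentationCloud
from .hermite import HermiteMesh, MeshTopology

__all__ = [
    "read_cloud",
    "write_cloud",
    "read_mesh",
    "write_mesh",
    "export_triangulated",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Clouds


def read_cloud(path) -> SegmentationCloud:
    """Load a segmentation cloud (.xyz/.txt, .ply, or legacy .vtk)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".xyz", ".txt", ".csv"):
        pts = np.loadtxt(path, delimiter="," if suffix == ".csv" else None)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise FormatError(f"{path}: expected 3 columns of coordinates")
    elif suffix == ".ply":
        import trimesh

        obj = trimesh.load(path, process=False)
        pts = np.asarray(obj.vertices, dtype=float)
    elif suffix == ".vtk":
        pts = _read_vtk_points(path)
    else:
        raise FormatError(f"unsupported cloud format: {suffix!r}")
    if not np.all(np.isfinite(pts)):
        raise FormatError(f"{path}: non-finite coordinates")
    return SegmentationCloud(pts, label=path.stem)


def write_cloud(cloud: SegmentationCloud, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".xyz", ".txt"):
        np.savetxt(path, cloud.points, fmt="%.6f")
    elif suffix == ".vtk":
        with open(path, "w") as fh:
            _write_vtk_header(fh, "atriashape segmentation cloud")
            _write_vtk_points(fh, cloud.points)
            n = len(cloud.points)
            fh.write(f"VERTICES {n} {2 * n}\n")
            for i in range(n):
                fh.write(f"1 {i}\n")
    else:
        raise FormatError(f"unsupported cloud format: {suffix!r}")


# ---------------------------------------------------------------------------
# Legacy VTK plumbing


def _write_vtk_header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(title + "\n")
    fh.write("ASCII\nDATASET POLYDATA\n")


def _write_vtk_points(fh, pts: np.ndarray) -> None:
    fh.write(f"POINTS {len(pts)} double\n")
    np.savetxt(fh, pts, fmt="%.10g")


def _tokens(path):
    with open(path) as fh:
        for line in fh:
            yield from line.split()


def _read_vtk_points(path) -> np.ndarray:
    toks = _tokens(path)
    for t in toks:
        if t.upper() == "POINTS":
            n = int(next(toks))
            next(toks)  # dtype
            flat = [float(next(toks)) for _ in range(3 * n)]
            return np.array(flat).reshape(n, 3)
    raise FormatError(f"{path}: no POINTS section found")


# ---------------------------------------------------------------------------
# Hermite meshes


def write_mesh(mesh: HermiteMesh, path) -> None:
    """Write a Hermite mesh as legacy ASCII VTK polydata (lossless)."""
    path = Path(path)
    if path.suffix.lower() != ".vtk":
        raise FormatError("Hermite meshes are written as legacy .vtk")
    topo = mesh.topology
    F = topo.n_faces
    with open(path, "w") as fh:
        _write_vtk_header(fh, "atriashape Hermite mesh " + json.dumps(
            {k: v for k, v in topo.meta.items() if isinstance(v, (int, float, str))}
        ))
        _write_vtk_points(fh, mesh.positions)
        # VTK polygon winding: boundary cycle of the (u,v) corner square
        cyc = topo.faces[:, [0, 1, 3, 2]]
        fh.write(f"POLYGONS {F} {5 * F}\n")
        for row in cyc:
            fh.write("4 " + " ".join(str(i) for i in row) + "\n")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("FIELD hermite_dofs 3\n")
        for name, arr in (
            ("deriv_u", mesh.deriv_u),
            ("deriv_v", mesh.deriv_v),
            ("deriv_uv", mesh.deriv_uv),
        ):
            fh.write(f"{name} 3 {mesh.n_nodes} double\n")
            np.savetxt(fh, arr, fmt="%.10g")
        fh.write(f"CELL_DATA {F}\n")
        fh.write("FIELD hermite_corner_maps 1\n")
        fh.write(f"corner_maps 36 {F} double\n")
        np.savetxt(fh, topo.corner_maps.reshape(F, 36), fmt="%.10g")


def read_mesh(path) -> HermiteMesh:
    """Read a Hermite mesh written by :func:`write_mesh`."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().split("\n")
    if len(lines) < 2 or not lines[0].startswith("# vtk"):
        raise FormatError(f"{path}: not a legacy VTK file")
    meta = {}
    if lines[1].startswith("atriashape Hermite mesh "):
        try:
            meta = json.loads(lines[1][len("atriashape Hermite mesh "):])
        except json.JSONDecodeError:
            meta = {}

    toks = iter(" ".join(lines[2:]).split())
    positions = faces = None
    arrays: dict[str, np.ndarray] = {}
    corner_maps = None
    try:
        while True:
            t = next(toks, None)
            if t is None:
                break
            key = t.upper()
            if key == "POINTS":
                n = int(next(toks)); next(toks)
                positions = np.array(
                    [float(next(toks)) for _ in range(3 * n)]
                ).reshape(n, 3)
            elif key == "POLYGONS":
                nf = int(next(toks)); next(toks)
                rows = []
                for _ in range(nf):
                    c = int(next(toks))
                    if c != 4:
                        raise FormatError("Hermite mesh polygons must be quads")
                    rows.append([int(next(toks)) for _ in range(4)])
                cyc = np.array(rows, dtype=int)
                faces = cyc[:, [0, 1, 3, 2]]  # undo boundary-cycle winding
            elif t in ("deriv_u", "deriv_v", "deriv_uv"):
                next(toks)
                cnt = int(next(toks)); next(toks)
                arrays[t] = np.array(
                    [float(next(toks)) for _ in range(3 * cnt)]
                ).reshape(cnt, 3)
            elif t == "corner_maps":
                next(toks)
                cnt = int(next(toks)); next(toks)
                corner_maps = np.array(
                    [float(next(toks)) for _ in range(36 * cnt)]
                ).reshape(cnt, 4, 3, 3)
    except StopIteration as exc:  # pragma: no cover - malformed file
        raise FormatError(f"{path}: truncated VTK file") from exc

    if positions is None or faces is None:
        raise FormatError(f"{path}: missing POINTS or POLYGONS")
    missing = {"deriv_u", "deriv_v", "deriv_uv"} - set(arrays)
    if missing or corner_maps is None:
        raise FormatError(
            f"{path}: not a Hermite mesh (missing {sorted(missing) or 'corner_maps'})"
        )
    topo = MeshTopology(faces=faces, corner_maps=corner_maps, meta=meta)
    return HermiteMesh(
        positions, arrays["deriv_u"], arrays["deriv_v"], arrays["deriv_uv"], topo
    )


def export_triangulated(mesh: HermiteMesh, path, n_per_edge: int = 10) -> None:
    """Positions-only triangulated export (.ply or .stl) for visualisation."""
    from .markers import triangulate

    path = Path(path)
    tm = triangulate(mesh, n_per_edge)
    if path.suffix.lower() not in (".ply", ".stl"):
        raise FormatError("triangulated export supports .ply and .stl")
    tm.export(path)
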