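"""Scalar left-atrial shape markers.

Implements the marker panel used for recurrence prediction: enclosed
volume and surface area, anterior-posterior (AP) radius in three flavours
(smooth mesh, raw segmentation slab, imported echo value), left-right and
foot-head radii with their ratios, sphericity (percent agreement with the
best-fit sphere), and vertical asymmetry -- a signed mm-sum over mirrored
slice pairs of the AP-extent difference between the superior and inferior
hemispheres.  Positive vertical asymmetry means the superior hemisphere
is AP-larger.

Axis convention throughout: +x left (LR), +y anterior (AP), +z head (FH).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import trimesh
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull

from .fitting import SegmentationCloud
from .hermite import HermiteMesh, sample_surface, surface_integrals

__all__ = [
    "triangulate",
    "fit_sphere",
    "sphericity",
    "ap_radius_mesh",
    "ap_radius_segmentation",
    "axis_radii",
    "vertical_asymmetry",
    "compute_marker_table",
    "MARKER_COLUMNS",
]

MARKER_COLUMNS = [
    "volume_mm3",
    "surface_area_mm2",
    "ap_radius_mesh_mm",
    "ap_radius_seg_mm",
    "ap_radius_echo_mm",
    "lr_radius_mm",
    "fh_radius_mm",
    "ratio_ap_lr",
    "ratio_lr_fh",
    "sphericity_pct",
    "vertical_asymmetry_mm",
]


def triangulate(mesh: HermiteMesh, n_per_edge: int = 10) -> trimesh.Trimesh:
    """Dense triangulation of the Hermite surface (for sections/export).

    Each patch is sampled on an (n+1)x(n+1) boundary-inclusive grid and
    split into triangles; duplicate vertices along shared patch edges are
    merged and degenerate pole triangles dropped.
    """
    n = int(n_per_edge)
    g = np.linspace(0.0, 1.0, n + 1)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    F = mesh.n_faces
    from .hermite import _eval_many

    fidx = np.repeat(np.arange(F), (n + 1) ** 2)
    u = np.tile(uu.ravel(), F)
    v = np.tile(vv.ravel(), F)
    pts = _eval_many(mesh, fidx, u, v)

    tris = []
    per = (n + 1) ** 2
    idx = np.arange(per).reshape(n + 1, n + 1)
    for f in range(F):
        base = f * per
        a = base + idx[:-1, :-1].ravel()
        b = base + idx[1:, :-1].ravel()
        c = base + idx[1:, 1:].ravel()
        d = base + idx[:-1, 1:].ravel()
        tris.append(np.column_stack([a, b, c]))
        tris.append(np.column_stack([a, c, d]))
    tm = trimesh.Trimesh(vertices=pts, faces=np.vstack(tris), process=True)
    tm.update_faces(tm.nondegenerate_faces())
    return tm


# ---------------------------------------------------------------------------
# Sphericity


def fit_sphere(points: np.ndarray):
    """Least-squares sphere fit minimising sum (|p - c| - R)^2.

    Algebraic (Coope) initialisation followed by geometric refinement.
    Returns (center, radius).
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or len(P) < 4:
        raise ValueError("need >= 4 points in 3D")
    if np.linalg.matrix_rank(P - P.mean(axis=0)) < 3:
        raise ValueError("degenerate (coplanar) point set")
    A = np.column_stack([2 * P, np.ones(len(P))])
    b = np.einsum("ij,ij->i", P, P)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(sol[3] + c0 @ c0))

    def resid(x):
        return np.linalg.norm(P - x[:3], axis=1) - x[3]

    out = least_squares(resid, np.r_[c0, r0], method="lm", max_nfev=200)
    c, r = out.x[:3], float(out.x[3])
    return c, abs(r)


def sphericity(surface_samples: np.ndarray) -> float:
    """Sphericity in percent: 100 for a perfect sphere.

    Defined as ``(1 - mean |r_i - R| / R) * 100`` where r_i are distances
    of the surface samples to the best-fit sphere centre and R its
    radius (normalised mean absolute residual of the sphere fit).
    """
    P = np.asarray(surface_samples, dtype=float)
    c, R = fit_sphere(P)
    resid = np.abs(np.linalg.norm(P - c, axis=1) - R)
    return float((1.0 - resid.mean() / R) * 100.0)


# ---------------------------------------------------------------------------
# Radii


def _min_caliper_halfwidth(xy: np.ndarray) -> float:
    """Half of the minimal caliper width of a planar point set."""
    pts = np.asarray(xy, dtype=float)
    if len(pts) < 3:
        raise ValueError("degenerate cross-section")
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    lens = np.linalg.norm(edges, axis=1)
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lens[:, None]
    # width along each edge normal = spread of hull points on that normal
    proj = hp @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min() / 2.0)


def _cross_section(tm: trimesh.Trimesh, z: float) -> np.ndarray | None:
    sec = tm.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if sec is None or len(sec.vertices) == 0:
        return None
    return np.asarray(sec.vertices)


def ap_radius_mesh(mesh: HermiteMesh, n_per_edge: int = 10) -> float:
    """Shortest equatorial radius of the smooth mesh, mm.

    The surface is cut by the horizontal plane through its centroid; the
    result is half the minimal caliper width of the equatorial contour
    (the smallest in-plane diameter over all directions), which for an
    axis-aligned ellipsoid equals the shortest equatorial semi-axis.
    """
    tm = triangulate(mesh, n_per_edge)
    return _ap_radius_from_triangulation(tm)


def _ap_radius_from_triangulation(tm: trimesh.Trimesh) -> float:
    sec = _cross_section(tm, tm.center_mass[2])
    if sec is None:
        raise ValueError("empty equatorial cross-section")
    return _min_caliper_halfwidth(sec[:, :2])


def ap_radius_segmentation(cloud: SegmentationCloud, slab_halfwidth: float = 2.0) -> float:
    """AP radius straight from the segmentation cloud, mm.

    Half the anterior-posterior (y) extent of the points lying within a
    slab of half-width ``slab_halfwidth`` around the cloud centre of
    mass's z level -- the raw-image counterpart of :func:`ap_radius_mesh`.
    """
    pts = cloud.points
    z_com = pts[:, 2].mean()
    slab = pts[np.abs(pts[:, 2] - z_com) <= slab_halfwidth]
    if len(slab) == 0:
        raise ValueError("no points in the equatorial slab")
    return float((slab[:, 1].max() - slab[:, 1].min()) / 2.0)


def axis_radii(mesh: HermiteMesh, n_per_edge: int = 8) -> dict:
    """Half-extents of the surface along the anatomical axes and ratios."""
    pts, *_ = sample_surface(mesh, n_per_edge)
    ext = (pts.max(axis=0) - pts.min(axis=0)) / 2.0
    lr, ap, fh = float(ext[0]), float(ext[1]), float(ext[2])
    return {
        "lr": lr,
        "ap": ap,
        "fh": fh,
        "ratio_ap_lr": ap / lr,
        "ratio_lr_fh": lr / fh,
    }


# ---------------------------------------------------------------------------
# Vertical asymmetry


def _slice_ap_extents(tm: trimesh.Trimesh, levels: np.ndarray) -> np.ndarray:
    """AP (y) extent of the surface cross-section at each z level.

    Vectorised edge-plane crossing: for every unique triangle edge that
    straddles a level, the y coordinate of the crossing point is
    interpolated; the extent is max - min of those crossings (NaN where
    the plane misses the surface).  Equivalent to sectioning the
    triangulated surface and measuring the contour's y span.
    """
    edges = tm.edges_unique
    P = tm.vertices
    z1, z2 = P[edges[:, 0], 2], P[edges[:, 1], 2]
    y1, y2 = P[edges[:, 0], 1], P[edges[:, 1], 1]
    zlo = np.minimum(z1, z2)
    zhi = np.maximum(z1, z2)
    dz = z2 - z1
    out = np.full(len(levels), np.nan)
    for i, z in enumerate(levels):
        m = (zlo <= z) & (zhi >= z) & (dz != 0)
        if not m.any():
            continue
        t = (z - z1[m]) / dz[m]
        y = y1[m] + t * (y2[m] - y1[m])
        out[i] = y.max() - y.min()
    return out


def vertical_asymmetry(
    mesh: HermiteMesh, n_slice_pairs: int = 50, n_per_edge: int = 10
) -> float:
    """Signed superior-inferior imbalance of AP size, mm.

    With z0 the centroid height and H the smaller of the two pole
    distances, slices are taken at mirrored heights z0 +/- (j - 1/2) H/n
    for j = 1..n.  Each slice contributes the difference of AP extents
    (max y - min y of the cross-section contour), superior minus
    inferior; the marker is the sum over slice pairs.  Positive values
    mean the superior hemisphere is larger anterior-posteriorly.
    """
    tm = triangulate(mesh, n_per_edge)
    return _va_from_triangulation(tm, n_slice_pairs)


def _va_from_triangulation(tm: trimesh.Trimesh, n_slice_pairs: int) -> float:
    z0 = tm.center_mass[2]  # volume centroid; robust to winding orientation
    zmax = tm.vertices[:, 2].max()
    zmin = tm.vertices[:, 2].min()
    H = min(zmax - z0, z0 - zmin)
    if H <= 0:
        raise ValueError("surface has no vertical extent about its centroid")
    h = (np.arange(1, n_slice_pairs + 1) - 0.5) * H / n_slice_pairs
    ext = _slice_ap_extents(tm, np.r_[z0 - h, z0 + h])
    lower, upper = ext[:n_slice_pairs], ext[n_slice_pairs:]
    pair_ok = np.isfinite(lower) & np.isfinite(upper)
    if not pair_ok.all():
        warnings.warn(
            f"{int((~pair_ok).sum())} slice pair(s) had an empty cross-section, skipped"
        )
    if not pair_ok.any():
        raise ValueError("all slice pairs were empty")
    return float(np.sum(upper[pair_ok] - lower[pair_ok]))


# ---------------------------------------------------------------------------
# Marker table


def compute_marker_table(
    meshes,
    clouds=None,
    clinical: pd.DataFrame | None = None,
    subject_ids=None,
    n_slice_pairs: int = 50,
    slab_halfwidth: float = 2.0,
) -> pd.DataFrame:
    """Per-subject marker table, optionally merged with clinical data.

    Mesh-derived markers (volume, area, radii, vertical asymmetry) come
    from each subject's Hermite mesh; sphericity and the segmentation AP
    radius use the subject's raw cloud when provided, falling back to
    dense mesh samples for sphericity otherwise (the segmentation AP
    radius is left missing in that case, not imputed).  ``clinical`` is
    merged on ``subject_id`` and may supply ``ap_radius_echo_mm`` and the
    recurrence/censoring columns; missing entries stay missing.
    """
    meshes = list(meshes)
    n = len(meshes)
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(n)]
    subject_ids = list(subject_ids)
    if len(set(subject_ids)) != n:
        raise ValueError("duplicate subject ids")
    if clouds is not None and len(clouds) != n:
        raise ValueError("clouds must match meshes one-to-one")

    rows = []
    for i, mesh in enumerate(meshes):
        ints = surface_integrals(mesh)
        rad = axis_radii(mesh)
        if clouds is not None:
            pts = clouds[i].points
            sph = sphericity(pts)
            ap_seg = ap_radius_segmentation(clouds[i], slab_halfwidth)
        else:
            pts, *_ = sample_surface(mesh, 8)
            sph = sphericity(pts)
            ap_seg = np.nan
        tm = triangulate(mesh)  # shared by the section-based markers
        rows.append({
            "subject_id": subject_ids[i],
            "volume_mm3": ints["volume"],
            "surface_area_mm2": ints["area"],
            "ap_radius_mesh_mm": _ap_radius_from_triangulation(tm),
            "ap_radius_seg_mm": ap_seg,
            "ap_radius_echo_mm": np.nan,
            "lr_radius_mm": rad["lr"],
            "fh_radius_mm": rad["fh"],
            "ratio_ap_lr": rad["ratio_ap_lr"],
            "ratio_lr_fh": rad["ratio_lr_fh"],
            "sphericity_pct": sph,
            "vertical_asymmetry_mm": _va_from_triangulation(tm, n_slice_pairs),
        })
    table = pd.DataFrame(rows)

    if clinical is not None:
        if "subject_id" not in clinical.columns:
            raise ValueError("clinical table needs a subject_id column")
        clin = clinical.copy()
        if "ap_radius_echo_mm" in clin.columns:
            table = table.drop(columns=["ap_radius_echo_mm"])
        table = table.merge(clin, on="subject_id", how="left", validate="1:1")
    for col in ("recurrence_12m", "recurrence_24m"):
        if col not in table.columns:
            table[col] = np.nan
    return table
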