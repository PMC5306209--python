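"""Bicubic Hermite closed-surface meshes.

The left-atrial body is represented as a closed C1 surface built from
bicubic Hermite patches.  Each node carries 12 degrees of freedom: its
position (x, y, z) and nine derivative components (two first parametric
derivatives and the mixed partial, each a 3-vector).  Faces are quads in a
local (u, v) in [0, 1]^2 chart; the two pole caps of the sphere-derived
template are triangles stored as quads with a collapsed edge so that a
single patch code path serves every face.

Coordinate convention (anatomical): +x = right->left (LR), +y =
posterior->anterior (AP), +z = foot->head (FH).

Stored node derivatives are expressed per unit of the template's global
(theta, phi) parametrisation.  Each face corner carries a fixed 3x3 map
taking the stored (deriv_u, deriv_v, deriv_uv) stack to the patch-local
(d/du, d/dv, d2/dudv) tuple; for regular corners this is the diagonal
arc-span scaling (dtheta, dphi, dtheta*dphi), while pole corners blend the
pole node's two stored tangent carriers by the corner's longitude.  The
maps are fixed at template construction, so C1 continuity across patch
edges is preserved under any deformation of the node DOFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HermiteNode",
    "MeshTopology",
    "HermiteMesh",
    "make_sphere_template",
    "evaluate_patch",
    "surface_integrals",
    "mesh_to_vector",
    "vector_to_mesh",
    "sample_surface",
    "euler_characteristic",
    "check_closed",
]

DOF_PER_NODE = 12


class TopologyError(ValueError):
    """Mesh is not a closed, consistently oriented 2-manifold."""


@dataclass(frozen=True)
class HermiteNode:
    """One mesh node: position plus parametric derivative carriers (mm)."""

    position: np.ndarray
    deriv_u: np.ndarray
    deriv_v: np.ndarray
    deriv_uv: np.ndarray

    def as_dof(self) -> np.ndarray:
        """The node's 12 scalar degrees of freedom, position first."""
        out = np.concatenate(
            [self.position, self.deriv_u, self.deriv_v, self.deriv_uv]
        )
        if out.shape != (DOF_PER_NODE,) or not np.all(np.isfinite(out)):
            raise ValueError("node DOF must be 12 finite scalars")
        return out


@dataclass(frozen=True)
class MeshTopology:
    """Face connectivity and the per-corner derivative maps.

    ``faces`` holds 4 node indices per face in corner order
    ``(u,v) = (0,0), (1,0), (0,1), (1,1)``.  Collapsed quads (two equal
    indices along one edge) represent pole triangles.  ``corner_maps`` is a
    ``(F, 4, 3, 3)`` array; row ``corner_maps[f, k]`` maps the stacked
    stored derivatives ``[deriv_u; deriv_v; deriv_uv]`` (a 3x3 matrix of
    row vectors) to the patch-corner ``[dS/du; dS/dv; d2S/dudv]``.
    """

    faces: np.ndarray
    corner_maps: np.ndarray
    axes_convention: str = "x=LR,y=AP,z=FH"
    meta: dict = field(default_factory=dict)

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.faces.max()) + 1


@dataclass
class HermiteMesh:
    """Closed bicubic Hermite surface: per-node DOF arrays plus topology.

    Attributes
    ----------
    positions, deriv_u, deriv_v, deriv_uv : (V, 3) float arrays, mm
    topology : MeshTopology shared across subjects of one template family
    """

    positions: np.ndarray
    deriv_u: np.ndarray
    deriv_v: np.ndarray
    deriv_uv: np.ndarray
    topology: MeshTopology

    def __post_init__(self) -> None:
        V = self.positions.shape[0]
        for name in ("positions", "deriv_u", "deriv_v", "deriv_uv"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (V, 3):
                raise ValueError(f"{name} must have shape (V, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if self.topology.n_nodes > V:
            raise ValueError("topology references nodes beyond the node table")

    @property
    def n_nodes(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_faces(self) -> int:
        return self.topology.n_faces

    def node(self, i: int) -> HermiteNode:
        return HermiteNode(
            self.positions[i].copy(),
            self.deriv_u[i].copy(),
            self.deriv_v[i].copy(),
            self.deriv_uv[i].copy(),
        )

    def dof_matrix(self) -> np.ndarray:
        """(V, 12) matrix of node DOFs, node-major / component-minor."""
        return np.hstack(
            [self.positions, self.deriv_u, self.deriv_v, self.deriv_uv]
        )

    def copy(self) -> "HermiteMesh":
        return HermiteMesh(
            self.positions.copy(),
            self.deriv_u.copy(),
            self.deriv_v.copy(),
            self.deriv_uv.copy(),
            self.topology,
        )

    def transformed(self, scale: float = 1.0, translation=(0.0, 0.0, 0.0)) -> "HermiteMesh":
        """Similarity-transformed copy (derivatives scale with `scale`)."""
        t = np.asarray(translation, dtype=float)
        return HermiteMesh(
            self.positions * scale + t,
            self.deriv_u * scale,
            self.deriv_v * scale,
            self.deriv_uv * scale,
            self.topology,
        )


# ---------------------------------------------------------------------------
# Hermite basis


def _h(t: np.ndarray):
    """Cubic Hermite basis values: (h00, h10, h01, h11)."""
    t = np.asarray(t, dtype=float)
    t2 = t * t
    t3 = t2 * t
    return (
        2 * t3 - 3 * t2 + 1,
        t3 - 2 * t2 + t,
        -2 * t3 + 3 * t2,
        t3 - t2,
    )


def _dh(t: np.ndarray):
    """First derivatives of the cubic Hermite basis."""
    t = np.asarray(t, dtype=float)
    t2 = t * t
    return (
        6 * t2 - 6 * t,
        3 * t2 - 4 * t + 1,
        -6 * t2 + 6 * t,
        3 * t2 - 2 * t,
    )


def _corner_data(mesh: HermiteMesh, face_idx: np.ndarray):
    """Patch-corner values for faces: positions and mapped derivatives.

    Returns (P, A, B, M), each of shape (n, 4, 3): corner position,
    dS/du, dS/dv, d2S/dudv at the 4 corners of each requested face.
    """
    topo = mesh.topology
    fidx = np.atleast_1d(np.asarray(face_idx, dtype=int))
    nodes = topo.faces[fidx]  # (n, 4)
    P = mesh.positions[nodes]  # (n, 4, 3)
    stored = np.stack(
        [mesh.deriv_u[nodes], mesh.deriv_v[nodes], mesh.deriv_uv[nodes]],
        axis=2,
    )  # (n, 4, 3rows, 3)
    mapped = topo.corner_maps[fidx] @ stored  # (n, 4, 3, 3)
    return P, mapped[:, :, 0, :], mapped[:, :, 1, :], mapped[:, :, 2, :]


def _eval_many(mesh: HermiteMesh, face_idx, u, v, want_derivs: bool = False):
    """Evaluate S(u, v) (and optionally dS/du, dS/dv) on many patches at once."""
    fidx = np.atleast_1d(np.asarray(face_idx, dtype=int))
    u = np.broadcast_to(np.asarray(u, dtype=float), fidx.shape)
    v = np.broadcast_to(np.asarray(v, dtype=float), fidx.shape)
    P, A, B, M = _corner_data(mesh, fidx)

    hu = _h(u)
    hv = _h(v)
    # corner order in storage: (0,0), (1,0), (0,1), (1,1)
    # value-basis along u for corners: (h00, h01, h00, h01); tangent: (h10, h11, ...)
    cu = (0, 1, 0, 1)  # u-coordinate of corner k
    cv = (0, 0, 1, 1)

    def blend(hu_, hv_):
        out = np.zeros(fidx.shape + (3,))
        for k in range(4):
            pu, du_ = hu_[cu[k]], hu_[2 + cu[k]]
            pv, dv_ = hv_[cv[k]], hv_[2 + cv[k]]
            out += (
                (pu * pv)[..., None] * P[:, k]
                + (du_ * pv)[..., None] * A[:, k]
                + (pu * dv_)[..., None] * B[:, k]
                + (du_ * dv_)[..., None] * M[:, k]
            )
        return out

    def basis_tuple(h_):
        # (value at corner0, value at corner1, tangent at corner0, tangent at corner1)
        return (h_[0], h_[2], h_[1], h_[3])

    S = blend(basis_tuple(hu), basis_tuple(hv))
    if not want_derivs:
        return S
    dhu = basis_tuple(_dh(u))
    dhv = basis_tuple(_dh(v))
    Su = blend(dhu, basis_tuple(hv))
    Sv = blend(basis_tuple(hu), dhv)
    return S, Su, Sv


def evaluate_patch(mesh: HermiteMesh, face: int, u, v) -> np.ndarray:
    """Evaluate one bicubic Hermite patch at parameter(s) (u, v).

    At each corner the patch reproduces the corner node's position exactly
    and its stored derivatives up to the patch's fixed parametric scaling.

    Parameters
    ----------
    face : valid face index
    u, v : scalars or equal-shape arrays in [0, 1]

    Returns
    -------
    (..., 3) array of surface points, mm.
    """
    if not (0 <= face < mesh.n_faces):
        raise IndexError(f"face index {face} out of range [0, {mesh.n_faces})")
    u_arr = np.asarray(u, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    if np.any((u_arr < -1e-12) | (u_arr > 1 + 1e-12)) or np.any(
        (v_arr < -1e-12) | (v_arr > 1 + 1e-12)
    ):
        raise ValueError("(u, v) must lie in the unit square")
    shape = np.broadcast_shapes(u_arr.shape, v_arr.shape)
    fidx = np.full(shape if shape else (1,), face, dtype=int)
    S = _eval_many(mesh, fidx.ravel(),
                   np.broadcast_to(u_arr, shape).ravel() if shape else u_arr,
                   np.broadcast_to(v_arr, shape).ravel() if shape else v_arr)
    return S.reshape(shape + (3,)) if shape else S[0]


def sample_surface(mesh: HermiteMesh, n_per_edge: int = 8, interior: bool = True):
    """Sample every patch on an ``n x n`` parameter grid.

    With ``interior=True`` the grid uses cell midpoints (no duplicated
    shared-edge points); otherwise it includes the patch boundary.

    Returns
    -------
    points : (F * n^2, 3) array
    face_idx, u, v : flat arrays giving each sample's patch coordinates
    """
    n = int(n_per_edge)
    if interior:
        g = (np.arange(n) + 0.5) / n
    else:
        g = np.linspace(0.0, 1.0, n)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    F = mesh.n_faces
    fidx = np.repeat(np.arange(F), n * n)
    u = np.tile(uu.ravel(), F)
    v = np.tile(vv.ravel(), F)
    pts = _eval_many(mesh, fidx, u, v)
    return pts, fidx, u, v


# ---------------------------------------------------------------------------
# Topology checks


def _directed_edges(faces: np.ndarray):
    """Non-degenerate directed boundary edges of each quad (cycle 00-10-11-01)."""
    cyc = faces[:, [0, 1, 3, 2]]
    a = cyc
    b = np.roll(cyc, -1, axis=1)
    e = np.stack([a.ravel(), b.ravel()], axis=1)
    return e[e[:, 0] != e[:, 1]]


def euler_characteristic(mesh_or_topo) -> int:
    """V - E + F of the face complex (collapsed edges excluded)."""
    topo = mesh_or_topo.topology if isinstance(mesh_or_topo, HermiteMesh) else mesh_or_topo
    edges = _directed_edges(topo.faces)
    und = np.unique(np.sort(edges, axis=1), axis=0)
    V = len(np.unique(topo.faces))
    return V - len(und) + topo.n_faces


def check_closed(mesh_or_topo) -> None:
    """Raise TopologyError unless every edge is shared by exactly two faces
    with opposite orientation (closed, consistently oriented surface)."""
    topo = mesh_or_topo.topology if isinstance(mesh_or_topo, HermiteMesh) else mesh_or_topo
    edges = _directed_edges(topo.faces)
    keys = edges[:, 0] * (topo.n_nodes + 1) + edges[:, 1]
    rev = edges[:, 1] * (topo.n_nodes + 1) + edges[:, 0]
    k_sorted = np.sort(keys)
    r_sorted = np.sort(rev)
    if len(np.unique(keys)) != len(keys):
        raise TopologyError("duplicated directed edge: inconsistent orientation")
    if not np.array_equal(k_sorted, r_sorted):
        raise TopologyError("surface is not closed: unmatched edges found")


# ---------------------------------------------------------------------------
# Sphere template


def make_sphere_template(radius: float = 20.0, segments: int = 12, rings: int = 11) -> HermiteMesh:
    """Spherical Hermite template mesh (UV-sphere topology).

    The standard atlas template uses ``radius=20`` mm, 12 longitudinal
    segments and 11 latitude rings, giving 134 nodes and 144 faces (120
    quads and 24 pole triangles stored as collapsed quads).  Node 0 is the
    inferior pole (z = -radius), so the most inferior point of the anatomy
    always maps to the first node.

    Parameters
    ----------
    radius : sphere radius, mm (> 0)
    segments : number of longitudinal columns (>= 3)
    rings : number of latitude rings between the poles (>= 2)
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if segments < 3 or rings < 2:
        raise ValueError("need segments >= 3 and rings >= 2")

    r = float(radius)
    dtheta = 2 * np.pi / segments
    dphi = np.pi / (rings + 1)

    V = segments * rings + 2
    positions = np.zeros((V, 3))
    deriv_u = np.zeros((V, 3))
    deriv_v = np.zeros((V, 3))
    deriv_uv = np.zeros((V, 3))

    # phi measured from the inferior pole: P = r (sin phi cos th, sin phi sin th, -cos phi)
    positions[0] = (0.0, 0.0, -r)
    deriv_u[0] = (r, 0.0, 0.0)   # tangent-plane carrier e1
    deriv_v[0] = (0.0, r, 0.0)   # tangent-plane carrier e2
    for j in range(1, rings + 1):
        phi = j * dphi
        for i in range(segments):
            th = i * dtheta
            idx = 1 + (j - 1) * segments + i
            sp, cp = np.sin(phi), np.cos(phi)
            st, ct = np.sin(th), np.cos(th)
            positions[idx] = (r * sp * ct, r * sp * st, -r * cp)
            deriv_u[idx] = (-r * sp * st, r * sp * ct, 0.0)      # d/dtheta
            deriv_v[idx] = (r * cp * ct, r * cp * st, r * sp)    # d/dphi
            deriv_uv[idx] = (-r * cp * st, r * cp * ct, 0.0)     # d2/dth dphi
    top = V - 1
    positions[top] = (0.0, 0.0, r)
    deriv_u[top] = (r, 0.0, 0.0)
    deriv_v[top] = (0.0, r, 0.0)

    F = segments * (rings + 1)
    faces = np.zeros((F, 4), dtype=int)
    corner_maps = np.zeros((F, 4, 3, 3))
    reg = np.diag([dtheta, dphi, dtheta * dphi])

    def pole_map(theta_c: float, south: bool) -> np.ndarray:
        """Corner map at a pole: blends the two stored tangent carriers.

        For the analytic sphere, d/dphi at the pole equals
        cos(theta) e1 + sin(theta) e2 (south) or its mirrored form (north);
        the mixed partial is the theta-derivative of that blend.
        """
        ct, st = np.cos(theta_c), np.sin(theta_c)
        m = np.zeros((3, 3))
        if south:
            m[1] = (dphi * ct, dphi * st, 0.0)
            m[2] = (dtheta * dphi * -st, dtheta * dphi * ct, 0.0)
        else:
            m[1] = (-dphi * ct, -dphi * st, 0.0)
            m[2] = (dtheta * dphi * st, dtheta * dphi * -ct, 0.0)
        return m

    f = 0
    ring = lambda j, i: 1 + (j - 1) * segments + (i % segments)
    # inferior cap: v runs from the pole (v=0) to ring 1
    for i in range(segments):
        th0, th1 = i * dtheta, (i + 1) * dtheta
        faces[f] = (0, 0, ring(1, i), ring(1, i + 1))
        corner_maps[f, 0] = pole_map(th0, south=True)
        corner_maps[f, 1] = pole_map(th1, south=True)
        corner_maps[f, 2] = reg
        corner_maps[f, 3] = reg
        f += 1
    # bands
    for j in range(1, rings):
        for i in range(segments):
            faces[f] = (ring(j, i), ring(j, i + 1), ring(j + 1, i), ring(j + 1, i + 1))
            corner_maps[f] = reg
            f += 1
    # superior cap: v runs from ring `rings` (v=0) to the pole (v=1)
    for i in range(segments):
        th0, th1 = i * dtheta, (i + 1) * dtheta
        faces[f] = (ring(rings, i), ring(rings, i + 1), top, top)
        corner_maps[f, 0] = reg
        corner_maps[f, 1] = reg
        corner_maps[f, 2] = pole_map(th0, south=False)
        corner_maps[f, 3] = pole_map(th1, south=False)
        f += 1

    topo = MeshTopology(
        faces=faces,
        corner_maps=corner_maps,
        meta={"template": "uv-sphere", "segments": segments, "rings": rings,
              "radius": r, "dtheta": dtheta, "dphi": dphi},
    )
    mesh = HermiteMesh(positions, deriv_u, deriv_v, deriv_uv, topo)
    check_closed(mesh)
    return mesh


# ---------------------------------------------------------------------------
# Geometric integrals


def surface_integrals(mesh: HermiteMesh, quadrature_order: int = 4) -> dict:
    """Area, enclosed volume and volume centroid of a closed Hermite surface.

    Area is accumulated by tensor Gauss-Legendre quadrature per patch;
    volume uses the divergence theorem, V = (1/3) oint x . n dA, and the
    centroid the corresponding second-moment identity.  The surface must be
    closed with outward-pointing normals (positive volume); an inward
    orientation raises :class:`TopologyError`.
    """
    check_closed(mesh)
    q = int(quadrature_order)
    x, w = np.polynomial.legendre.leggauss(q)
    g = 0.5 * (x + 1.0)
    w = 0.5 * w
    uu, vv = np.meshgrid(g, g, indexing="ij")
    ww = np.outer(w, w).ravel()

    F = mesh.n_faces
    fidx = np.repeat(np.arange(F), q * q)
    u = np.tile(uu.ravel(), F)
    v = np.tile(vv.ravel(), F)
    S, Su, Sv = _eval_many(mesh, fidx, u, v, want_derivs=True)
    n = np.cross(Su, Sv)
    wts = np.tile(ww, F)
    dA = np.linalg.norm(n, axis=1)
    area = float(np.sum(wts * dA))
    volume = float(np.sum(wts * np.einsum("ij,ij->i", S, n)) / 3.0)
    if volume <= 0:
        raise TopologyError("non-positive enclosed volume: inward-facing orientation?")
    cent = np.array(
        [np.sum(wts * 0.5 * S[:, k] ** 2 * n[:, k]) for k in range(3)]
    ) / volume
    return {"area": area, "volume": volume, "centroid": cent}


# ---------------------------------------------------------------------------
# Shape-vector packing


def mesh_to_vector(mesh: HermiteMesh) -> np.ndarray:
    """Flatten node DOFs to the per-subject shape vector (length 12 V).

    Ordering is node-major, component-minor: for each node, position (3),
    deriv_u (3), deriv_v (3), deriv_uv (3).  The standard 134-node template
    yields a length-1608 vector.
    """
    return mesh.dof_matrix().ravel()


def vector_to_mesh(vector: np.ndarray, topology: MeshTopology,
                   n_nodes: int | None = None) -> HermiteMesh:
    """Rebuild a HermiteMesh from a shape vector and its template topology."""
    vec = np.asarray(vector, dtype=float).ravel()
    V = n_nodes if n_nodes is not None else topology.n_nodes
    if vec.size != DOF_PER_NODE * V:
        raise ValueError(
            f"vector length {vec.size} does not match {DOF_PER_NODE} x {V} DOF"
        )
    dof = vec.reshape(V, DOF_PER_NODE)
    return HermiteMesh(
        dof[:, 0:3].copy(), dof[:, 3:6].copy(), dof[:, 6:9].copy(),
        dof[:, 9:12].copy(), topology,
    )
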