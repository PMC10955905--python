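"""Harmonic flattening of the cut graft mesh onto a rectangle.

The cut tube is a topological disk; its interior vertices receive 2D
coordinates by solving the discrete Laplace equation with the boundary
pinned to a rectangle: the proximal ring maps to the top edge (PGD = 0),
the distal ring to the bottom edge, and the two copies of the longitudinal
seam to the left/right edges.  Edge weights are the Pinkall–Polthier
cotangent weights

    w_ij = (cot a_ij + cot b_ij) / 2,

a_ij and b_ij being the angles opposite edge ij in its two incident
triangles (one cotangent on boundary edges).  The Laplacian is assembled as
L = D - W with row sums zero and positive semi-definite sign convention;
the embedding solves L_II v_I = -L_IB v_B once per coordinate.  A uniform
weight (w_ij = 1, Tutte) variant is available for comparison: it is still a
bijection on a disk but distorts angles more on curved tubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .errors import MeshError, ParameterError
from .meshing import GraftMesh

__all__ = [
    "cotangent_laplacian",
    "uniform_laplacian",
    "embed_rectangle",
    "Parameterization",
    "quasi_conformal_error",
]


def _edge_face_counts(faces: np.ndarray, n_vertices: int) -> None:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise MeshError("mesh is non-manifold: an edge is shared by > 2 triangles")


def cotangent_laplacian(mesh: GraftMesh | tuple) -> sparse.csr_matrix:
    """Cotangent-weight Laplacian L = D - W of a triangle mesh.

    Off-diagonal entries are -w_ij on edges; the diagonal makes every row
    sum to zero.  L is symmetric positive semi-definite (for meshes without
    obtuse-triangle weight sign flips, and in the quadratic-form sense
    regardless, since it equals the Dirichlet energy matrix).
    """
    if isinstance(mesh, GraftMesh):
        vertices, faces = mesh.vertices, mesh.faces
    else:
        vertices, faces = mesh
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    _edge_face_counts(faces, len(vertices))

    i0, i1, i2 = faces[:, 0], faces[:, 1], faces[:, 2]
    v0, v1, v2 = vertices[i0], vertices[i1], vertices[i2]
    # cot of the angle at each corner, added to the opposite edge
    rows, cols, vals = [], [], []
    for (a, b, c), (pa, pb, pc) in (((i0, i1, i2), (v0, v1, v2)),
                                    ((i1, i2, i0), (v1, v2, v0)),
                                    ((i2, i0, i1), (v2, v0, v1))):
        u = pb - pa
        w = pc - pa
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        cross = np.where(cross < 1e-12, 1e-12, cross)
        cot = np.einsum("ij,ij->i", u, w) / cross   # cot(angle at a)
        half = 0.5 * cot
        rows.extend([b, c])
        cols.extend([c, b])
        vals.extend([half, half])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sparse.coo_matrix((vals, (rows, cols)), shape=(len(vertices),) * 2).tocsr()
    d = np.asarray(W.sum(axis=1)).ravel()
    return (sparse.diags(d) - W).tocsr()


def uniform_laplacian(mesh: GraftMesh | tuple) -> sparse.csr_matrix:
    """Graph (Tutte) Laplacian with unit edge weights."""
    if isinstance(mesh, GraftMesh):
        vertices, faces = mesh.vertices, mesh.faces
    else:
        vertices, faces = mesh
    faces = np.asarray(faces, dtype=np.int64)
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    n = len(np.asarray(vertices))
    W = sparse.coo_matrix((np.ones(2 * len(edges)),
                           (np.concatenate([edges[:, 0], edges[:, 1]]),
                            np.concatenate([edges[:, 1], edges[:, 0]]))),
                          shape=(n, n)).tocsr()
    d = np.asarray(W.sum(axis=1)).ravel()
    return (sparse.diags(d) - W).tocsr()


@dataclass
class Parameterization:
    """Bijective vertex map between the 3D graft mesh and a 2D rectangle."""

    uv: np.ndarray                          # (N, 2): (AL mm, PGD mm) per vertex
    al_extent: float
    pgd_extent: float
    flipped_faces: np.ndarray = field(default=None)
    boundary_spec: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "uv": self.uv.tolist(),
            "al_extent": self.al_extent,
            "pgd_extent": self.pgd_extent,
            "flipped_faces": self.flipped_faces.tolist(),
        }


def _chord_fractions(vertices: np.ndarray, idx: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(vertices[idx], axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum / cum[-1]


def embed_rectangle(mesh: GraftMesh, L: sparse.spmatrix,
                    rect: tuple[float, float]) -> Parameterization:
    """Solve the harmonic embedding with the boundary pinned to a rectangle.

    ``rect`` = (AL_extent, PGD_extent) in mm.  Boundary vertices are spaced
    chord-length-proportionally along their rectangle edge (reduces
    distortion on tapered grafts); interior vertices solve
    ``L_II v_I = -L_IB v_B`` per coordinate by sparse LU.  Faces whose 2D
    signed area is inverted relative to the majority orientation are
    reported in ``flipped_faces`` (empty for a valid bijection).
    """
    W, H = float(rect[0]), float(rect[1])
    if W <= 0 or H <= 0:
        raise ParameterError("rectangle extents must be positive")
    n = len(mesh.vertices)
    uv = np.zeros((n, 2))
    fixed = np.zeros(n, dtype=bool)

    top = mesh.boundary_proximal
    bottom = mesh.boundary_distal
    left = mesh.seam_vertices
    right = mesh.seam_vertices_right

    uv[top, 0] = _chord_fractions(mesh.vertices, top) * W
    uv[top, 1] = 0.0
    uv[bottom, 0] = _chord_fractions(mesh.vertices, bottom) * W
    uv[bottom, 1] = H
    uv[left, 0] = 0.0
    uv[left, 1] = _chord_fractions(mesh.vertices, left) * H
    uv[right, 0] = W
    uv[right, 1] = _chord_fractions(mesh.vertices, right) * H
    for idx in (top, bottom, left, right):
        fixed[idx] = True

    interior = np.flatnonzero(~fixed)
    boundary = np.flatnonzero(fixed)
    if len(interior):
        L = L.tocsr()
        L_II = L[interior][:, interior].tocsc()
        L_IB = L[interior][:, boundary]
        try:
            lu = splu(L_II)
        except RuntimeError as e:  # singular: disconnected interior
            raise MeshError(f"harmonic system is singular: {e}") from e
        rhs = -L_IB @ uv[boundary]
        uv[interior, 0] = lu.solve(rhs[:, 0])
        uv[interior, 1] = lu.solve(rhs[:, 1])

    f = mesh.faces
    p = uv[f]
    signed = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                    - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    majority = 1.0 if np.sum(signed > 0) >= len(signed) / 2 else -1.0
    flipped = np.flatnonzero(majority * signed <= 0)
    if len(flipped):
        import warnings
        warnings.warn(f"parameterization has {len(flipped)} flipped faces")
    return Parameterization(
        uv=uv, al_extent=W, pgd_extent=H, flipped_faces=flipped,
        boundary_spec={"top": top.tolist(), "bottom": bottom.tolist(),
                       "left": left.tolist(), "right": right.tolist(),
                       "corners": [int(top[0]), int(top[-1]),
                                   int(bottom[0]), int(bottom[-1])]},
    )


def quasi_conformal_error(mesh: GraftMesh, param: Parameterization) -> float:
    """Mean quasi-conformal distortion sigma1/sigma2 - 1 over all faces.

    0 for a perfectly angle-preserving (conformal) map; larger values mean
    more anisotropic stretching of triangles between 3D and 2D.
    """
    total, count = 0.0, 0
    V, F, uv = mesh.vertices, mesh.faces, param.uv
    e1_3d = V[F[:, 1]] - V[F[:, 0]]
    e2_3d = V[F[:, 2]] - V[F[:, 0]]
    e1_uv = uv[F[:, 1]] - uv[F[:, 0]]
    e2_uv = uv[F[:, 2]] - uv[F[:, 0]]
    for i in range(len(F)):
        # orthonormal 2D basis in the 3D triangle plane
        b1 = e1_3d[i]
        n1 = np.linalg.norm(b1)
        if n1 < 1e-12:
            continue
        b1 = b1 / n1
        b2 = e2_3d[i] - np.dot(e2_3d[i], b1) * b1
        n2 = np.linalg.norm(b2)
        if n2 < 1e-12:
            continue
        b2 = b2 / n2
        P = np.array([[np.dot(e1_3d[i], b1), np.dot(e2_3d[i], b1)],
                      [0.0, np.dot(e2_3d[i], b2)]])
        Q = np.array([e1_uv[i], e2_uv[i]]).T
        try:
            J = Q @ np.linalg.inv(P)
        except np.linalg.LinAlgError:
            continue
        svals = np.linalg.svd(J, compute_uv=False)
        if svals[1] > 1e-12:
            total += svals[0] / svals[1] - 1.0
            count += 1
    return total / max(count, 1)
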