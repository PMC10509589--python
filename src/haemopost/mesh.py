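"""Tetrahedral mesh container and geometric kernels.

The mesh is the shared computational domain for all field post-processing:
node positions in metres, tetrahedral connectivity, and an oriented
triangulated wall surface.  Linear (P1) shape functions are used for all
gradient evaluation; cell-wise gradients are exact for affine fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial import cKDTree


class MeshError(ValueError):
    """Invalid or degenerate mesh geometry."""


@dataclass
class Mesh:
    """Unstructured tetrahedral mesh with a labelled wall surface.

    Attributes
    ----------
    points : (n, 3) float array
        Node positions in metres.
    tets : (m, 4) int array
        Tetrahedral connectivity, positively oriented.
    wall_tris : (k, 3) int array
        Wall surface triangles, oriented so their normals point out of
        the fluid domain.  The wall carries the no-slip condition; inlet
        and outlet caps are not part of it.
    """

    points: np.ndarray
    tets: np.ndarray
    wall_tris: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.wall_tris = np.asarray(self.wall_tris, dtype=np.int64).reshape(-1, 3)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshError("points must be an (n, 3) array")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be an (m, 4) array")
        if self.tets.size and self.tets.max() >= len(self.points):
            raise MeshError("tet connectivity references missing nodes")
        if self.wall_tris.size and self.wall_tris.max() >= len(self.points):
            raise MeshError("wall triangles reference missing nodes")
        # canonicalize orientation: swap last two vertices of inverted tets
        vol = self._signed_volumes()
        neg = vol < 0
        if np.any(neg):
            self.tets[neg] = self.tets[neg][:, [0, 1, 3, 2]]
            vol = np.abs(vol)
        if np.any(vol <= 0):
            bad = np.flatnonzero(vol <= 0)
            raise MeshError(f"degenerate (zero-volume) tetrahedra: cells {bad[:10].tolist()}")

    def _signed_volumes(self) -> np.ndarray:
        p = self.points[self.tets]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    @cached_property
    def cell_volumes(self) -> np.ndarray:
        """Tet volumes in m^3 (all positive)."""
        return np.abs(self._signed_volumes())

    @cached_property
    def node_volumes(self) -> np.ndarray:
        """Lumped nodal volumes: each tet contributes a quarter of its volume."""
        nv = np.zeros(len(self.points))
        np.add.at(nv, self.tets.ravel(), np.repeat(self.cell_volumes / 4.0, 4))
        return nv

    @cached_property
    def cell_centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)

    @cached_property
    def shape_gradients(self) -> np.ndarray:
        """(m, 4, 3) gradients of the four linear shape functions per tet."""
        p = self.points[self.tets]
        e = p[:, 1:] - p[:, :1]  # (m, 3, 3) edge matrix rows
        inv = np.linalg.inv(e)  # columns are grad of phi_1..phi_3
        g = np.transpose(inv, (0, 2, 1))  # (m, 3(node), 3(dim))
        g0 = -g.sum(axis=1, keepdims=True)
        return np.concatenate([g0, g], axis=1)

    def cell_gradient(self, nodal: np.ndarray) -> np.ndarray:
        """Cell-wise gradient of a nodal field.

        For a scalar field (n,) returns (m, 3); for a vector field (n, c)
        returns (m, 3, c) with entry [cell, i, j] = d(value_j)/d(x_i).
        """
        vals = np.asarray(nodal, dtype=np.float64)
        scalar = vals.ndim == 1
        if scalar:
            vals = vals[:, None]
        v = vals[self.tets]  # (m, 4, c)
        g = np.einsum("mkd,mkc->mdc", self.shape_gradients, v)
        return g[:, :, 0] if scalar else g

    def node_average(self, cell_values: np.ndarray) -> np.ndarray:
        """Volume-weighted average of cell-centred values onto nodes."""
        cv = np.asarray(cell_values, dtype=np.float64)
        flat_shape = (len(self.points),) + cv.shape[1:]
        out = np.zeros(flat_shape)
        wsum = np.zeros(len(self.points))
        w = self.cell_volumes
        for k in range(4):
            idx = self.tets[:, k]
            np.add.at(out, idx, (cv.T * w).T if cv.ndim > 1 else cv * w)
            np.add.at(wsum, idx, w)
        shape = (-1,) + (1,) * (cv.ndim - 1)
        return out / wsum.reshape(shape)

    # -- wall surface -------------------------------------------------

    @cached_property
    def wall_node_ids(self) -> np.ndarray:
        return np.unique(self.wall_tris)

    @cached_property
    def wall_tri_normals(self) -> np.ndarray:
        """Unit outward normals of the wall triangles."""
        p = self.points[self.wall_tris]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        mag = np.linalg.norm(n, axis=1, keepdims=True)
        if np.any(mag == 0):
            raise MeshError("degenerate wall triangle")
        return n / mag

    @cached_property
    def wall_tri_areas(self) -> np.ndarray:
        p = self.points[self.wall_tris]
        return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    @cached_property
    def wall_node_normals(self) -> np.ndarray:
        """Area-weighted unit outward normals at wall nodes (aligned to wall_node_ids)."""
        acc = np.zeros((len(self.points), 3))
        w = (self.wall_tri_normals.T * self.wall_tri_areas).T
        for k in range(3):
            np.add.at(acc, self.wall_tris[:, k], w)
        n = acc[self.wall_node_ids]
        mag = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(mag == 0, 1.0, mag)

    @cached_property
    def wall_node_areas(self) -> np.ndarray:
        """Lumped wall areas per wall node (aligned to wall_node_ids), m^2."""
        acc = np.zeros(len(self.points))
        np.add.at(acc, self.wall_tris.ravel(), np.repeat(self.wall_tri_areas / 3.0, 3))
        return acc[self.wall_node_ids]

    # -- point location / interpolation -------------------------------

    @cached_property
    def _centroid_tree(self) -> cKDTree:
        return cKDTree(self.cell_centroids)

    def locate(self, pts: np.ndarray, k_candidates: int = 24) -> tuple[np.ndarray, np.ndarray]:
        """Find containing tets and barycentric coordinates for query points.

        Returns (cell_ids, bary) with cell_id -1 for points outside the
        mesh (these get nearest-cell barycentrics clipped to the simplex).
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        k = min(k_candidates, len(self.tets))
        _, cand = self._centroid_tree.query(pts, k=k)
        cand = np.atleast_2d(cand)
        cells = np.full(len(pts), -1, dtype=np.int64)
        bary = np.zeros((len(pts), 4))
        best_cell = cand[:, 0].copy()
        best_bary = None
        tol = -1e-9
        remaining = np.arange(len(pts))
        for j in range(k):
            if not len(remaining):
                break
            c = cand[remaining, j]
            b = self._barycentric(pts[remaining], c)
            inside = b.min(axis=1) >= tol
            hit = remaining[inside]
            cells[hit] = c[inside]
            bary[hit] = b[inside]
            if j == 0:
                best_bary = np.zeros((len(pts), 4))
                best_bary[remaining] = b
            remaining = remaining[~inside]
        if len(remaining):
            # outside points: fall back to the nearest cell, clipped
            c = best_cell[remaining]
            b = best_bary[remaining]
            b = np.clip(b, 0.0, None)
            b /= b.sum(axis=1, keepdims=True)
            bary[remaining] = b
            # cells stay -1 to signal extrapolation, but store nearest id negatively offset
            cells[remaining] = -c - 2
        return cells, bary

    def _barycentric(self, pts: np.ndarray, cells: np.ndarray) -> np.ndarray:
        p = self.points[self.tets[cells]]
        T = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))
        rhs = pts - p[:, 0]
        lam = np.linalg.solve(T, rhs[..., None])[..., 0]
        lam0 = 1.0 - lam.sum(axis=1, keepdims=True)
        return np.concatenate([lam0, lam], axis=1)

    def interpolate(self, nodal: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """Linearly interpolate a nodal field at arbitrary points.

        Points outside the mesh get nearest-cell extrapolation (clipped
        barycentric weights).
        """
        cells, bary = self.locate(pts)
        cid = np.where(cells >= 0, cells, -cells - 2)
        vals = np.asarray(nodal, dtype=np.float64)
        v = vals[self.tets[cid]]
        return np.einsum("pk,pk...->p...", bary, v)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        cells, _ = self.locate(pts)
        return cells >= 0

    def validate(self, rel_tol: float = 1e-10) -> None:
        """Check container invariants (volume consistency, wall indices)."""
        tot_c = self.cell_volumes.sum()
        tot_n = self.node_volumes.sum()
        if abs(tot_c - tot_n) > rel_tol * tot_c:
            raise MeshError("node volumes do not sum to cell volumes")


def merge_meshes(a: Mesh, b: Mesh) -> tuple[Mesh, np.ndarray]:
    """Concatenate two disjoint meshes; returns merged mesh and the node
    offset of the second mesh's points in the merged numbering."""
    off = len(a.points)
    pts = np.vstack([a.points, b.points])
    tets = np.vstack([a.tets, b.tets + off])
    tris = np.vstack([a.wall_tris, b.wall_tris + off])
    return Mesh(pts, tets, tris), np.int64(off)
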