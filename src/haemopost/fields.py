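"""Time-resolved field containers, analysis planes and flux integration.

Fields are node-centred on a tetrahedral :class:`~haemopost.mesh.Mesh` and
store exactly one cardiac cycle on a uniform snapshot grid, with the
periodic convention value(T) = value(0) (the closing snapshot is not
stored).  All values are SI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import Delaunay

from .mesh import Mesh
from .units import ML_PER_M3

SUBDOMAIN_LABELS = ("AA", "TLt", "FLt", "TLa", "FLa", "none")


class FieldError(ValueError):
    """Invalid field data or time metadata."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform snapshot times covering one cardiac cycle [t0, t0 + T)."""

    period: float
    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=np.float64))
        t = self.times
        if t.ndim != 1 or len(t) < 2:
            raise FieldError("TimeGrid needs at least 2 snapshots")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > 1e-9):
            raise FieldError("snapshot times must be uniformly spaced")
        if self.period <= 0:
            raise FieldError("period must be positive")
        # snapshots cover [t0, t0+T): the implied closing sample t0+T wraps to t0
        if abs(t[0] + self.period - (t[-1] + dt[0])) > 1e-9 + 1e-9 * self.period:
            raise FieldError("snapshots must tile exactly one cycle [t0, t0+T)")

    @classmethod
    def over_cycle(cls, period: float, n_snapshots: int, t0: float = 0.0) -> "TimeGrid":
        return cls(period, t0 + np.arange(n_snapshots) * (period / n_snapshots))

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return self.period / self.n_snapshots


def cyclic_trapezoid_weights(grid: TimeGrid) -> np.ndarray:
    """Trapezoidal quadrature weights over one closed cycle.

    With the periodic convention value(T) = value(0), the trapezoidal rule
    over [t0, t0+T] assigns every stored snapshot the same weight dt.
    """
    return np.full(grid.n_snapshots, grid.dt)


def time_integral(grid: TimeGrid, series: np.ndarray) -> np.ndarray:
    """Periodic-trapezoid integral over one cycle; series first axis is time."""
    w = cyclic_trapezoid_weights(grid)
    return np.tensordot(w, np.asarray(series), axes=(0, 0))


@dataclass
class VelocityField:
    """Time-resolved nodal velocity vectors v(x, t) in m/s."""

    mesh: Mesh
    grid: TimeGrid
    values: np.ndarray  # (n_t, n_nodes, 3)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.n_snapshots, len(self.mesh.points), 3):
            raise FieldError(
                f"values shape {self.values.shape} does not match grid/mesh "
                f"({self.grid.n_snapshots}, {len(self.mesh.points)}, 3)"
            )
        if not np.all(np.isfinite(self.values)):
            raise FieldError("velocity values must be finite")


@dataclass
class WallShearField:
    """Wall shear stress vector time series tau(x, t) at wall nodes, Pa."""

    wall_node_ids: np.ndarray
    grid: TimeGrid
    tau: np.ndarray  # (n_t, n_wall_nodes, 3)
    mesh: Mesh | None = None

    def __post_init__(self):
        self.wall_node_ids = np.asarray(self.wall_node_ids, dtype=np.int64)
        self.tau = np.asarray(self.tau, dtype=np.float64)
        if self.tau.shape != (self.grid.n_snapshots, len(self.wall_node_ids), 3):
            raise FieldError("tau shape does not match grid/wall nodes")
        if not np.all(np.isfinite(self.tau)):
            raise FieldError("tau values must be finite")


@dataclass
class SubdomainMask:
    """Per-cell region labels for the five analysis subdomains.

    Labels: ascending aorta (AA), thoracic true/false lumen (TLt/FLt),
    abdominal true/false lumen (TLa/FLa), plus 'none' for unlabelled cells.
    """

    labels: np.ndarray  # (n_cells,) of str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(np.unique(self.labels)) - set(SUBDOMAIN_LABELS)
        if bad:
            raise FieldError(f"invalid subdomain labels: {sorted(bad)}")

    def cells(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @property
    def used_labels(self) -> list[str]:
        return [l for l in SUBDOMAIN_LABELS[:-1] if np.any(self.labels == l)]


@dataclass
class FluidProperties:
    """Blood rheology: density and a Newtonian or Carreau–Yasuda viscosity.

    Defaults are density 1056 kg/m^3 and Newtonian mu = 3.5 mPa.s.
    Carreau–Yasuda parameters (mu0, mu_inf, lam, a, n) must be supplied
    by the user when model='carreau_yasuda'.
    """

    density: float = 1056.0
    model: Literal["newtonian", "carreau_yasuda"] = "newtonian"
    mu: float = 3.5e-3
    cy_params: dict | None = None

    def __post_init__(self):
        if self.density <= 0:
            raise FieldError("density must be positive")
        if self.model == "carreau_yasuda":
            required = {"mu0", "mu_inf", "lam", "a", "n"}
            if not self.cy_params or required - set(self.cy_params):
                raise FieldError(
                    "carreau_yasuda model requires user-supplied cy_params "
                    f"{sorted(required)}"
                )
        elif self.model != "newtonian":
            raise FieldError(f"unknown viscosity model {self.model!r}")

    def viscosity(self, gamma_dot) -> np.ndarray:
        """Dynamic viscosity mu(shear rate) in Pa.s."""
        g = np.asarray(gamma_dot, dtype=np.float64)
        if self.model == "newtonian":
            return np.full_like(g, self.mu)
        p = self.cy_params
        mu_inf, mu0, lam, a, n = p["mu_inf"], p["mu0"], p["lam"], p["a"], p["n"]
        return mu_inf + (mu0 - mu_inf) * (1.0 + (lam * g) ** a) ** ((n - 1.0) / a)


@dataclass
class PlaneSection:
    """An analysis plane with its own areal quadrature.

    Sample points and weights are generated once from the plane geometry
    (triangulated disc or polygon), independent of the mesh; the weights
    sum to the plane area.
    """

    origin: np.ndarray
    normal: np.ndarray
    points: np.ndarray  # (q, 3) quadrature points
    weights: np.ndarray  # (q,) areal weights, m^2
    lumen_tag: Literal["TL", "FL", "whole"] = "whole"
    name: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        n = np.asarray(self.normal, dtype=np.float64)
        mag = np.linalg.norm(n)
        if mag == 0:
            raise FieldError("plane normal must be nonzero")
        self.normal = n / mag
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if len(self.points) != len(self.weights) or not len(self.points):
            raise FieldError("plane must have matching, nonempty points/weights")
        if self.weights.sum() <= 0:
            raise FieldError("plane area must be positive")

    @property
    def area(self) -> float:
        return float(self.weights.sum())


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (e1, e2) such that (e1, e2, n) is right-handed."""
    n = np.asarray(normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def disk_plane(
    origin,
    normal,
    radius: float,
    n_rings: int = 12,
    lumen_tag: str = "whole",
    name: str = "",
) -> PlaneSection:
    """Circular analysis plane with centroid quadrature on a triangulated disc."""
    e1, e2 = plane_basis(normal)
    pts2 = [np.zeros(2)]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        m = max(6, int(round(6 * k)))
        th = 2 * np.pi * (np.arange(m) + 0.5 * (k % 2)) / m
        pts2.extend(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    pts2 = np.asarray(pts2)
    tri = Delaunay(pts2)
    simp = tri.simplices
    a, b, c = pts2[simp[:, 0]], pts2[simp[:, 1]], pts2[simp[:, 2]]
    u, w = b - a, c - a
    areas = 0.5 * np.abs(u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0])
    keep = areas > 1e-14 * radius**2
    cent2 = (a + b + c)[keep] / 3.0
    origin = np.asarray(origin, dtype=np.float64)
    pts3 = origin + cent2[:, :1] * e1 + cent2[:, 1:] * e2
    return PlaneSection(origin, normal, pts3, areas[keep], lumen_tag, name)


def polygon_plane(origin, normal, boundary2d: np.ndarray, lumen_tag="whole", name="") -> PlaneSection:
    """Plane bounded by a 2D polygon (in the plane basis), fan-triangulated."""
    e1, e2 = plane_basis(normal)
    tri = Delaunay(boundary2d)
    simp = tri.simplices
    a, b, c = (boundary2d[simp[:, k]] for k in range(3))
    u, w = b - a, c - a
    areas = 0.5 * np.abs(u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0])
    cent2 = (a + b + c) / 3.0
    origin = np.asarray(origin, dtype=np.float64)
    pts3 = origin + cent2[:, :1] * e1 + cent2[:, 1:] * e2
    return PlaneSection(origin, normal, pts3, areas, lumen_tag, name)


def plane_flux(field: VelocityField, plane: PlaneSection, time_index: int) -> float:
    """Volumetric flow through a plane at one snapshot, in ml/s.

    Computes sum over quadrature points of (v . n) * w; the sign follows
    the plane normal.  Raises if no sample point lies inside the mesh.
    """
    inside = field.mesh.contains(plane.points)
    if not np.any(inside):
        raise FieldError(f"plane {plane.name or ''} lies outside the mesh")
    v = field.mesh.interpolate(field.values[time_index], plane.points)
    q_si = float(np.dot(v @ plane.normal, plane.weights))
    return q_si * ML_PER_M3


def plane_flux_series(field: VelocityField, plane: PlaneSection) -> np.ndarray:
    """Flux waveform through a plane across all snapshots, ml/s."""
    inside = field.mesh.contains(plane.points)
    if not np.any(inside):
        raise FieldError(f"plane {plane.name or ''} lies outside the mesh")
    cells, bary = field.mesh.locate(plane.points)
    cid = np.where(cells >= 0, cells, -cells - 2)
    conn = field.mesh.tets[cid]
    vn = np.einsum("tpkc,c->tpk", field.values[:, conn, :], plane.normal)
    v_at = np.einsum("pk,tpk->tp", bary, vn)
    return (v_at @ plane.weights) * ML_PER_M3
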