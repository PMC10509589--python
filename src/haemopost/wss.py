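"""Wall shear stress extraction and the four disturbed-shear indices.

Indices over one cardiac cycle of the wall shear vector tau(x, t):

* TAWSS = (1/T) * integral of |tau| dt
* OSI   = 0.5 * (1 - |integral of tau dt| / integral of |tau| dt), in [0, 0.5]
* RRT   = 1 / ((1 - 2*OSI) * TAWSS) = 1 / |time-mean shear vector|
* ECAP  = OSI / TAWSS

Time integration is trapezoidal with periodic closure (value(T) = value(0)).
Wall shear is recovered from the velocity field with linear shape-function
gradients in wall-adjacent tetrahedra, volume-weighted to wall nodes; the
viscous traction 2 mu(gamma_dot) D . n is projected onto the wall tangent
plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import (
    FieldError,
    FluidProperties,
    VelocityField,
    WallShearField,
    cyclic_trapezoid_weights,
)


@dataclass
class WallIndexMaps:
    """Per-wall-node shear indices.  Nodes where the shear vanishes for the
    whole cycle are flagged ``undefined`` (indices NaN there); RRT is +inf
    where the time-mean shear vector is zero but the magnitude is not."""

    wall_node_ids: np.ndarray
    tawss: np.ndarray  # Pa
    osi: np.ndarray  # dimensionless
    rrt: np.ndarray  # 1/Pa
    ecap: np.ndarray  # 1/Pa
    undefined: np.ndarray  # bool

    INDEX_NAMES = ("tawss", "osi", "rrt", "ecap")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.wall_node_ids,
                "tawss": self.tawss,
                "osi": self.osi,
                "rrt": self.rrt,
                "ecap": self.ecap,
                "undefined": self.undefined,
            }
        )


def wall_shear_from_field(field: VelocityField, fluid: FluidProperties) -> WallShearField:
    """Compute the wall shear vector time series from a velocity field.

    The velocity gradient at each wall node is the volume-weighted average
    of the (exact, piecewise-constant) linear-element gradients over its
    adjacent tetrahedra; the traction of the viscous stress 2 mu D on the
    outward wall normal is projected tangentially.  The viscosity may be
    shear-thinning (evaluated at the nodal shear rate).
    """
    mesh = field.mesh
    wall_ids = mesh.wall_node_ids
    if not len(wall_ids):
        raise FieldError("mesh has no wall surface")
    n_pts = len(mesh.points)
    is_wall = np.zeros(n_pts, dtype=bool)
    is_wall[wall_ids] = True
    cidx, kidx = np.nonzero(is_wall[mesh.tets])
    nid = mesh.tets[cidx, kidx]
    w = mesh.cell_volumes[cidx]
    wsum = np.zeros(n_pts)
    np.add.at(wsum, nid, w)
    normals = mesh.wall_node_normals  # aligned with wall_ids

    n_t = field.grid.n_snapshots
    tau = np.empty((n_t, len(wall_ids), 3))
    for j in range(n_t):
        G = mesh.cell_gradient(field.values[j])  # (m, 3, 3): [i, a, b]=d v_b/d x_a
        acc = np.zeros((n_pts, 3, 3))
        np.add.at(acc, nid, G[cidx] * w[:, None, None])
        Gn = acc[wall_ids] / wsum[wall_ids][:, None, None]
        D = 0.5 * (Gn + np.transpose(Gn, (0, 2, 1)))
        gamma_dot = np.sqrt(2.0 * np.einsum("kab,kab->k", D, D))
        mu = fluid.viscosity(gamma_dot)
        traction = 2.0 * mu[:, None] * np.einsum("kab,kb->ka", D, normals)
        tau[j] = traction - np.einsum("ka,ka->k", traction, normals)[:, None] * normals
    return WallShearField(wall_ids, field.grid, tau, mesh=mesh)


def compute_wss_indices(tau_field: WallShearField) -> WallIndexMaps:
    """TAWSS, OSI, RRT and ECAP from a wall shear vector time series."""
    grid = tau_field.grid
    wt = cyclic_trapezoid_weights(grid)
    T = grid.period
    tau = tau_field.tau
    mean_vec = np.tensordot(wt, tau, axes=(0, 0)) / T  # (k, 3)
    mag = np.linalg.norm(tau, axis=2)  # (n_t, k)
    tawss = wt @ mag / T  # (k,)
    mean_vec_mag = np.linalg.norm(mean_vec, axis=1)

    undefined = tawss <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        osi = 0.5 * (1.0 - mean_vec_mag / tawss)
        osi = np.clip(osi, 0.0, 0.5)
        rrt = np.where(mean_vec_mag > 0.0, 1.0 / mean_vec_mag, np.inf)
        ecap = osi / tawss
    osi[undefined] = np.nan
    rrt[undefined] = np.nan
    ecap[undefined] = np.nan
    return WallIndexMaps(tau_field.wall_node_ids, tawss, osi, rrt, ecap, undefined)


def circumferential_profile(
    maps: WallIndexMaps,
    wall_points: np.ndarray,
    stations: np.ndarray,
    axis_origin,
    axis_direction,
    band_width: float | None = None,
    lumen_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Circumferentially averaged indices at stations along a straight
    centreline axis.

    Wall nodes are binned into bands of ``band_width`` (default: the station
    spacing) centred on each station's arc length from ``axis_origin``;
    the mean of each index over the band is reported.  Bands without nodes
    are flagged missing (NaN values, n_nodes = 0), never zero.
    """
    stations = np.asarray(stations, dtype=np.float64)
    if band_width is None:
        if len(stations) < 2:
            raise FieldError("band_width required for a single station")
        band_width = float(np.min(np.diff(stations)))
    d = np.asarray(axis_direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    s = (wall_points - np.asarray(axis_origin, dtype=np.float64)) @ d
    sel = ~maps.undefined
    if lumen_mask is not None:
        sel = sel & np.asarray(lumen_mask, dtype=bool)
    rows = []
    for st in stations:
        band = sel & (np.abs(s - st) <= band_width / 2.0)
        row = {"station": st, "n_nodes": int(band.sum()), "missing": not band.any()}
        for name in WallIndexMaps.INDEX_NAMES:
            vals = getattr(maps, name)[band]
            vals = vals[np.isfinite(vals)]
            row[name] = float(vals.mean()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def difference_stats(
    candidate: WallIndexMaps,
    baseline: WallIndexMaps,
    region_mask: np.ndarray | None = None,
    rel_guard: float = 1e-6,
) -> pd.DataFrame:
    """Pointwise case-minus-baseline difference statistics per index.

    Reports min/max/mean of the difference and two relative summaries:
    ``mean_pct`` (mean of pointwise differences relative to the local
    baseline value, excluding nodes whose baseline is below
    max(1e-12, rel_guard * regional maximum)) and ``mean_pct_of_means``
    (100 * mean difference / mean baseline).  Non-finite values (e.g. RRT
    at zero-mean-shear nodes) are excluded pointwise.
    """
    if not np.array_equal(candidate.wall_node_ids, baseline.wall_node_ids):
        raise FieldError("candidate and baseline are not on the same wall nodes")
    if region_mask is None:
        region_mask = np.ones(len(baseline.wall_node_ids), dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    rows = []
    for name in WallIndexMaps.INDEX_NAMES:
        c = getattr(candidate, name)[region_mask]
        b = getattr(baseline, name)[region_mask]
        ok = np.isfinite(c) & np.isfinite(b)
        c, b = c[ok], b[ok]
        delta = c - b
        guard = max(1e-12, rel_guard * (np.nanmax(np.abs(b)) if len(b) else 0.0))
        rel_ok = np.abs(b) > guard
        mean_pct = float(100.0 * np.mean(delta[rel_ok] / b[rel_ok])) if rel_ok.any() else np.nan
        mean_b = float(b.mean()) if len(b) else np.nan
        rows.append(
            {
                "index": name,
                "min": float(delta.min()) if len(delta) else np.nan,
                "max": float(delta.max()) if len(delta) else np.nan,
                "mean": float(delta.mean()) if len(delta) else np.nan,
                "mean_pct": mean_pct,
                "mean_pct_of_means": float(100.0 * delta.mean() / mean_b)
                if len(delta) and mean_b
                else np.nan,
                "n_nodes": int(len(delta)),
            }
        )
    return pd.DataFrame(rows)
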