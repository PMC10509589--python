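"""Flow helicity: vorticity, helicity time series, local normalized helicity
(LNH) and the bulk indices h1-h3 by subdomain and cycle phase.

Helicity density H_k(x, t) = v . omega quantifies the local alignment of
velocity and vorticity; its volume integral H(t) identifies streamwise
vortical structures, while |H|(t) (integral of |H_k|) measures helical
strength regardless of handedness.  The bulk indices are time-volume
averages over a region V and window of duration Tw:

* h1 = (1/(Tw V)) * double integral of H_k   (signed balance; 0 for
  reflection-symmetric structures)
* h2 = same of |H_k|                          (total helical strength)
* h3 = h1 / h2 in [-1, 1]                     (handedness balance)

Integration is cell-centred: vorticity from the exact linear-element curl,
velocity at the cell centroid, cell-volume weighting.  Node-centred
vorticity/LNH (volume-averaged) is provided for visualization and plane
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import (
    FieldError,
    PlaneSection,
    SubdomainMask,
    TimeGrid,
    VelocityField,
    cyclic_trapezoid_weights,
)


def cell_vorticity(field: VelocityField, time_index: int) -> np.ndarray:
    """Curl of the velocity per cell (exact for the linear interpolant), 1/s."""
    G = field.mesh.cell_gradient(field.values[time_index])  # [c, a, b] = d v_b / d x_a
    return np.stack(
        [
            G[:, 1, 2] - G[:, 2, 1],
            G[:, 2, 0] - G[:, 0, 2],
            G[:, 0, 1] - G[:, 1, 0],
        ],
        axis=1,
    )


def vorticity_field(field: VelocityField) -> np.ndarray:
    """Node-centred vorticity (n_t, n_nodes, 3): cell curls volume-averaged."""
    mesh = field.mesh
    out = np.empty((field.grid.n_snapshots, len(mesh.points), 3))
    for j in range(field.grid.n_snapshots):
        out[j] = mesh.node_average(cell_vorticity(field, j))
    return out


def _cell_helicity_density(field: VelocityField) -> np.ndarray:
    """(n_t, n_cells) helicity density at cell centroids, m/s^2."""
    mesh = field.mesh
    n_t = field.grid.n_snapshots
    Hk = np.empty((n_t, len(mesh.tets)))
    for j in range(n_t):
        v_c = field.values[j][mesh.tets].mean(axis=1)
        w_c = cell_vorticity(field, j)
        Hk[j] = np.einsum("ca,ca->c", v_c, w_c)
    return Hk


def helicity_timeseries(
    field: VelocityField, mask: SubdomainMask | None = None, regions: list[str] | None = None
) -> dict[str, dict[str, np.ndarray]]:
    """H(t) and |H|(t) per region, m^4/s^2.

    With no mask, a single region 'whole' covers the mesh.
    """
    mesh = field.mesh
    Hk = _cell_helicity_density(field)
    vol = mesh.cell_volumes
    out = {}
    if mask is None:
        sel = {"whole": np.arange(len(mesh.tets))}
    else:
        labels = regions if regions is not None else mask.used_labels
        sel = {lab: mask.cells(lab) for lab in labels}
    for lab, cells in sel.items():
        if not len(cells):
            raise FieldError(f"region {lab!r} has no cells")
        out[lab] = {
            "H": Hk[:, cells] @ vol[cells],
            "absH": np.abs(Hk[:, cells]) @ vol[cells],
        }
    return out


def plane_helicity(field: VelocityField, plane: PlaneSection) -> dict[str, np.ndarray]:
    """Area-integrated and area-averaged helicity density on a plane.

    Velocity and node-averaged vorticity are interpolated at the plane's
    quadrature points.
    """
    mesh = field.mesh
    omega = vorticity_field(field)
    n_t = field.grid.n_snapshots
    H = np.empty(n_t)
    absH = np.empty(n_t)
    for j in range(n_t):
        v = mesh.interpolate(field.values[j], plane.points)
        w = mesh.interpolate(omega[j], plane.points)
        hk = np.einsum("pa,pa->p", v, w)
        H[j] = hk @ plane.weights
        absH[j] = np.abs(hk) @ plane.weights
    return {"H": H, "absH": absH, "H_mean": H / plane.area, "absH_mean": absH / plane.area}


@dataclass
class LNHField:
    """Local normalized helicity, dimensionless in [-1, 1]; zero by
    convention where |v||omega| falls below the guard."""

    grid: TimeGrid
    values: np.ndarray  # (n_t, n_nodes)
    guard: float


def lnh_field(field: VelocityField, guard: float = 1e-12) -> LNHField:
    """LNH = H_k / (|v| |omega|), node-centred, clamped to [-1, 1]."""
    omega = vorticity_field(field)
    v = field.values
    hk = np.einsum("tna,tna->tn", v, omega)
    denom = np.linalg.norm(v, axis=2) * np.linalg.norm(omega, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnh = np.where(denom > guard, hk / denom, 0.0)
    return LNHField(field.grid, np.clip(lnh, -1.0, 1.0), guard)


def default_windows(grid: TimeGrid, q_in: np.ndarray | None = None) -> dict[str, tuple[float, float]]:
    """Systole/diastole split.

    Systole ends at the first down-crossing of Q_in through 5% of its peak
    after peak systole; without a waveform (or if no crossing exists) the
    split falls back to 0.35 T.  'full' always covers the whole cycle.
    """
    t0 = float(grid.times[0])
    T = grid.period
    t_split = t0 + 0.35 * T
    if q_in is not None:
        q = np.asarray(q_in, dtype=np.float64)
        ipk = int(np.argmax(q))
        thr = 0.05 * q[ipk]
        for j in range(ipk + 1, grid.n_snapshots):
            if q[j] <= thr:
                t_split = float(grid.times[j])
                break
    return {
        "systole": (t0, t_split),
        "diastole": (t_split, t0 + T),
        "full": (t0, t0 + T),
    }


def _window_weights(grid: TimeGrid, t0: float, t1: float) -> tuple[np.ndarray, float]:
    """Snapshot indices' trapezoid weights for a window [t0, t1] and its span.

    The full cycle uses periodic closure; partial windows use the snapshots
    they contain with an open trapezoid.
    """
    if t1 <= t0:
        raise FieldError("window of zero or negative length")
    T = grid.period
    eps = 1e-9 * T
    if t1 - t0 >= T - eps:
        return cyclic_trapezoid_weights(grid), T
    sel = np.flatnonzero((grid.times >= t0 - eps) & (grid.times <= t1 + eps))
    if len(sel) < 2:
        raise FieldError("window contains fewer than 2 snapshots")
    w = np.zeros(grid.n_snapshots)
    ts = grid.times[sel]
    dw = np.diff(ts)
    w[sel[:-1]] += dw / 2.0
    w[sel[1:]] += dw / 2.0
    return w, float(ts[-1] - ts[0])


def bulk_helicity_indices(
    field: VelocityField,
    mask: SubdomainMask | None,
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """h1, h2, h3 per (region, window).

    Returns a tidy frame with columns region, window, h1, h2, h3 (h1/h2 in
    m/s^2, h3 dimensionless; h3 is NaN when h2 = 0).
    """
    if windows is None:
        windows = default_windows(field.grid)
    mesh = field.mesh
    Hk = _cell_helicity_density(field)
    vol = mesh.cell_volumes
    if mask is None:
        sel = {"whole": np.arange(len(mesh.tets))}
    else:
        sel = {lab: mask.cells(lab) for lab in mask.used_labels}
    rows = []
    for wname, (t0, t1) in windows.items():
        wts, span = _window_weights(field.grid, t0, t1)
        for lab, cells in sel.items():
            if not len(cells):
                raise FieldError(f"region {lab!r} has no cells")
            V = vol[cells].sum()
            h_of_t = Hk[:, cells] @ vol[cells]
            a_of_t = np.abs(Hk[:, cells]) @ vol[cells]
            h1 = float(wts @ h_of_t / (span * V))
            h2 = float(wts @ a_of_t / (span * V))
            h3 = h1 / h2 if h2 > 0 else np.nan
            rows.append({"region": lab, "window": wname, "h1": h1, "h2": h2, "h3": h3})
    return pd.DataFrame(rows)
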