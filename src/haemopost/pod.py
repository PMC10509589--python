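"""Snapshot proper orthogonal decomposition (POD) of fluctuating fields.

The fluctuation v'(x, t) = v(x, t) - vbar(x) is decomposed as
v'(x, t) = sum_k a_k(t) Phi_k(x) with modes orthonormal under a weighted
inner product (u, w)_W = sum_i W_i u_i . w_i.  The default weighting is the
lumped nodal volume (wall-node area for wall fields), which makes modal
energy mesh-independent; uniform weighting is available.

Eigenvalues use the snapshot-sum convention lambda_k = sum_t a_k(t)^2, so
sum_k lambda_k equals the total weighted fluctuating energy of the snapshot
set and truncation error obeys the eigenvalue tail sum (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import FieldError, TimeGrid, VelocityField, WallShearField
from .wss import WallIndexMaps, compute_wss_indices


@dataclass
class PODResult:
    """Mean field, orthonormal spatial modes, temporal coefficients and the
    (non-increasing) energy eigenvalues of a snapshot POD."""

    kind: str  # "velocity" | "wall_shear"
    mean: np.ndarray  # (n, 3)
    modes: np.ndarray  # (k, n, 3), orthonormal under the weights
    coeffs: np.ndarray  # (n_t, k)
    eigenvalues: np.ndarray  # (n_t,) including trailing zeros
    weights: np.ndarray  # (n,)
    grid: TimeGrid
    mesh: object = None
    wall_node_ids: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        """Number of numerically nonzero modes (trailing zero modes are
        flagged by exclusion, not errored)."""
        return self.modes.shape[0]

    @property
    def energy_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues

    def inner(self, a: np.ndarray, b: np.ndarray) -> float:
        return float(np.einsum("na,na,n->", a, b, self.weights))


def _field_data(field):
    if isinstance(field, VelocityField):
        w = field.mesh.node_volumes
        return "velocity", field.values, w, field.mesh, None
    if isinstance(field, WallShearField):
        if field.mesh is not None:
            ids = field.wall_node_ids
            all_ids = field.mesh.wall_node_ids
            areas = np.zeros(len(field.mesh.points))
            areas[all_ids] = field.mesh.wall_node_areas
            w = areas[ids]
        else:
            w = np.ones(field.tau.shape[1])
        return "wall_shear", field.tau, w, field.mesh, field.wall_node_ids
    raise FieldError("snapshot_pod expects a VelocityField or WallShearField")


def snapshot_pod(field, weighting: str = "volume") -> PODResult:
    """Snapshot-method POD under a volume- (default) or uniform-weighted
    inner product.

    The temporal correlation (Gram) matrix of the mean-subtracted snapshots
    is eigen-decomposed; modes are normalized, ordered by non-increasing
    eigenvalue, and sign-fixed so each mode's largest-magnitude component is
    positive.  Snapshots that are rank-deficient to machine precision yield
    trailing zero modes (flagged by truncation), not an error.
    """
    kind, values, w, mesh, wall_ids = _field_data(field)
    if weighting == "uniform":
        w = np.ones(values.shape[1])
    elif weighting != "volume":
        raise FieldError("weighting must be 'volume' or 'uniform'")
    if not np.all(np.isfinite(values)):
        raise FieldError("snapshots must be finite")
    n_t = values.shape[0]
    mean = values.mean(axis=0)
    X = (values - mean).reshape(n_t, -1)  # (n_t, 3n)
    Wf = np.repeat(w, 3)
    C = (X * Wf) @ X.T  # (n_t, n_t)
    C = 0.5 * (C + C.T)
    lam, V = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    lam = np.clip(lam, 0.0, None)
    tol = lam[0] * 1e-12 if lam[0] > 0 else 0.0
    rank = int(np.sum(lam > tol))
    modes = np.empty((rank, values.shape[1], 3))
    coeffs = np.empty((n_t, rank))
    for k in range(rank):
        phi = X.T @ V[:, k] / np.sqrt(lam[k])
        a = np.sqrt(lam[k]) * V[:, k]
        # sign convention: largest-|component| of the mode is positive
        imax = np.argmax(np.abs(phi))
        if phi[imax] < 0:
            phi, a = -phi, -a
        modes[k] = phi.reshape(-1, 3)
        coeffs[:, k] = a
    return PODResult(kind, mean, modes, coeffs, lam, w, field.grid, mesh, wall_ids)


def energy_spectrum(result: PODResult, k_list=None, threshold: float = 0.98) -> dict:
    """Normalized modal kinetic energy and cumulative sums.

    Fractions are lambda_k / sum(lambda); ``k_at_threshold`` is the smallest
    mode count whose cumulative normalized energy reaches ``threshold``
    (default 98%).
    """
    frac = result.energy_fractions
    cum = np.cumsum(frac)
    if k_list is None:
        k_list = np.arange(1, len(frac) + 1)
    k_list = np.asarray(k_list, dtype=int)
    if k_list.max(initial=0) > len(frac):
        raise FieldError("k_list exceeds mode count")
    reached = np.flatnonzero(cum >= threshold - 1e-12)
    k_thr = int(reached[0] + 1) if len(reached) else None
    table = pd.DataFrame(
        {
            "mode": k_list,
            "fraction": frac[k_list - 1],
            "cumulative": cum[k_list - 1],
        }
    )
    return {
        "fractions": frac,
        "cumulative": cum,
        "k_at_threshold": k_thr,
        "threshold": threshold,
        "table": table,
    }


def reconstruct(result: PODResult, k: int):
    """Rank-k reconstruction vbar + sum_{j<=k} a_j(t) Phi_j(x); k = 0 is the
    (time-constant) mean field."""
    if not 0 <= k <= result.n_modes:
        raise FieldError(f"k must be in [0, {result.n_modes}]")
    n_t = result.coeffs.shape[0]
    vals = np.broadcast_to(result.mean, (n_t,) + result.mean.shape).copy()
    if k:
        vals += np.einsum("tk,kna->tna", result.coeffs[:, :k], result.modes[:k])
    if result.kind == "velocity":
        return VelocityField(result.mesh, result.grid, vals)
    return WallShearField(result.wall_node_ids, result.grid, vals, mesh=result.mesh)


def reconstruction_error(result: PODResult, k: int) -> float:
    """Relative weighted-L2 truncation error at rank k; equals the Parseval
    tail sqrt(sum_{j>k} lambda_j / sum lambda)."""
    lam = result.eigenvalues
    tot = lam.sum()
    if tot == 0:
        return 0.0
    return float(np.sqrt(lam[k:].sum() / tot))


def wss_indices_from_modes(tau_pod: PODResult, k: int) -> tuple[WallIndexMaps, dict]:
    """Shear indices from a rank-k reconstruction of the wall shear field.

    POD is applied to the wall shear vector snapshots directly; TAWSS/OSI/
    RRT/ECAP are computed from the truncated reconstruction and compared
    with the full-rank (complete) indices.  Returns (maps_k, errors) where
    errors maps index name to the relative L2 error over finite nodes.
    """
    if tau_pod.kind != "wall_shear":
        raise FieldError("wss_indices_from_modes requires a wall-shear POD")
    maps_k = compute_wss_indices(reconstruct(tau_pod, k))
    maps_full = compute_wss_indices(reconstruct(tau_pod, tau_pod.n_modes))
    errors = {}
    for name in WallIndexMaps.INDEX_NAMES:
        a = getattr(maps_k, name)
        b = getattr(maps_full, name)
        ok = np.isfinite(a) & np.isfinite(b)
        denom = np.linalg.norm(b[ok])
        errors[name] = float(np.linalg.norm(a[ok] - b[ok]) / denom) if denom > 0 else 0.0
    return maps_k, errors
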