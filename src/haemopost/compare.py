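"""Case-to-case comparison metrics.

Quantities used to compare simulation cases (different inlet conditions)
and to relate haemodynamics to aneurysmal growth:

* Pearson correlation of paired field samples (e.g. shear-index maps or
  plane-sampled velocity components) between two cases.
* Transmural pressure TMP(t) = P_TL(t) - P_FL(t) at paired stations.
* False-lumen ejection fraction FLEF = 100 * (retrograde volume through the
  primary entry tear over one cycle) / (stroke volume), with the tear
  normal oriented true lumen -> false lumen so retrograde flow (FL -> TL)
  is the negative part of the flux waveform.
* Cross-sectional growth between two imaging time points,
  100 * (A2 - A1) / A1 per station.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import (
    FieldError,
    PlaneSection,
    TimeGrid,
    VelocityField,
    cyclic_trapezoid_weights,
    plane_flux_series,
)
from .units import mmhg_convert


@dataclass
class CorrelationResult:
    """Pearson correlation of two paired samples; ``degenerate`` flags a
    zero-variance input (r is NaN there, never silently 0 or 1)."""

    r: float
    n: int
    degenerate: bool


def pearson_fields(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> CorrelationResult:
    """Pearson correlation between two paired samples, optionally weighted.

    Non-finite pairs are excluded.  Inputs of any shape are flattened;
    vector fields correlate component-wise as one pooled sample.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise FieldError("samples must be paired (same shape)")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=np.float64).ravel()
        if w.shape != a.shape:
            raise FieldError("weights must match the sample shape")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b, w = a[ok], b[ok], w[ok]
    n = int(len(a))
    if n < 2:
        raise FieldError("correlation needs at least 2 finite pairs")
    wsum = w.sum()
    da = a - (w @ a) / wsum
    db = b - (w @ b) / wsum
    va = w @ da**2
    vb = w @ db**2
    if va <= 0 or vb <= 0:
        return CorrelationResult(np.nan, n, True)
    return CorrelationResult(float((w @ (da * db)) / np.sqrt(va * vb)), n, False)


def pearson_planes(
    field_a: VelocityField, field_b: VelocityField, plane: PlaneSection
) -> CorrelationResult:
    """Correlation of two cases' velocity sampled at a plane's quadrature
    points, pooled over snapshots and components, area-weighted."""
    if field_a.grid.n_snapshots != field_b.grid.n_snapshots:
        raise FieldError("cases must share the snapshot count")
    va = np.stack([field_a.mesh.interpolate(v, plane.points) for v in field_a.values])
    vb = np.stack([field_b.mesh.interpolate(v, plane.points) for v in field_b.values])
    w = np.broadcast_to(plane.weights[None, :, None], va.shape)
    return pearson_fields(va, vb, w)


def transmural_pressure(
    grid: TimeGrid,
    p_tl: np.ndarray,
    p_fl: np.ndarray,
    units: str = "mmHg",
) -> dict:
    """TMP(t) = P_TL - P_FL at a paired TL/FL station and its cycle mean.

    Pressures may be given in 'mmHg' or 'Pa'; the output is always mmHg.
    The cycle mean uses periodic trapezoid weights.
    """
    p_tl = np.asarray(p_tl, dtype=np.float64)
    p_fl = np.asarray(p_fl, dtype=np.float64)
    if p_tl.shape != (grid.n_snapshots,) or p_fl.shape != (grid.n_snapshots,):
        raise FieldError("pressure series must have one value per snapshot")
    if units == "Pa":
        p_tl = mmhg_convert(p_tl, "to_mmHg")
        p_fl = mmhg_convert(p_fl, "to_mmHg")
    elif units != "mmHg":
        raise FieldError("units must be 'mmHg' or 'Pa'")
    tmp = p_tl - p_fl
    w = cyclic_trapezoid_weights(grid)
    return {
        "tmp_mmhg": tmp,
        "mean_tmp_mmhg": float(w @ tmp / grid.period),
        "min_tmp_mmhg": float(tmp.min()),
        "max_tmp_mmhg": float(tmp.max()),
    }


def false_lumen_ejection_fraction(
    grid: TimeGrid,
    q_tear_ml_s: np.ndarray,
    stroke_volume_ml: float,
) -> dict:
    """FLEF (%) from the primary-entry-tear flux waveform.

    ``q_tear_ml_s`` must be signed with the tear normal pointing from the
    true into the false lumen; the retrograde volume is the integral of the
    negative part.  Raises if the stroke volume is not positive.
    """
    q = np.asarray(q_tear_ml_s, dtype=np.float64)
    if q.shape != (grid.n_snapshots,):
        raise FieldError("tear flux must have one value per snapshot")
    if stroke_volume_ml <= 0:
        raise FieldError("stroke volume must be positive")
    w = cyclic_trapezoid_weights(grid)
    retro_ml = float(w @ np.clip(-q, 0.0, None))
    ante_ml = float(w @ np.clip(q, 0.0, None))
    return {
        "flef_pct": 100.0 * retro_ml / stroke_volume_ml,
        "retrograde_volume_ml": retro_ml,
        "antegrade_volume_ml": ante_ml,
        "net_volume_ml": ante_ml - retro_ml,
    }


def tear_flef(
    field: VelocityField,
    tear_plane: PlaneSection,
    stroke_volume_ml: float,
) -> dict:
    """FLEF computed directly from a velocity field and a tear plane whose
    normal points TL -> FL."""
    q = plane_flux_series(field, tear_plane)
    out = false_lumen_ejection_fraction(field.grid, q, stroke_volume_ml)
    out["q_tear_ml_s"] = q
    return out


def growth_profile(
    stations: np.ndarray,
    area_t1: np.ndarray,
    area_t2: np.ndarray,
) -> pd.DataFrame:
    """Percent cross-sectional area growth 100*(A2 - A1)/A1 per station.

    Areas must be positive at the first time point; matching stations are
    assumed already aligned (see :func:`align_profiles`).
    """
    stations = np.asarray(stations, dtype=np.float64)
    a1 = np.asarray(area_t1, dtype=np.float64)
    a2 = np.asarray(area_t2, dtype=np.float64)
    if not (stations.shape == a1.shape == a2.shape):
        raise FieldError("stations and areas must have matching shapes")
    if np.any(a1 <= 0):
        raise FieldError("baseline areas must be positive")
    return pd.DataFrame(
        {
            "station": stations,
            "area_t1": a1,
            "area_t2": a2,
            "growth_pct": 100.0 * (a2 - a1) / a1,
        }
    )


def align_profiles(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    station_col: str = "station",
    suffixes: tuple[str, str] = ("_a", "_b"),
    max_offset: float | None = None,
) -> pd.DataFrame:
    """Join two station-indexed profiles by nearest station.

    Each station of ``profile_a`` is matched to the nearest station of
    ``profile_b`` within ``max_offset`` (default: half the minimum station
    spacing of ``profile_b``); unmatched stations are dropped.  Useful for
    relating haemodynamic profiles to growth measured at other stations.
    """
    sa = np.asarray(profile_a[station_col], dtype=np.float64)
    sb = np.asarray(profile_b[station_col], dtype=np.float64)
    if len(sb) < 1 or len(sa) < 1:
        raise FieldError("profiles must be nonempty")
    if max_offset is None:
        if len(sb) < 2:
            raise FieldError("max_offset required when profile_b has one station")
        max_offset = 0.5 * float(np.min(np.diff(np.sort(sb))))
    order = np.argsort(sb)
    pos = np.searchsorted(sb[order], sa)
    rows = []
    for i, p in enumerate(pos):
        cands = [j for j in (p - 1, p) if 0 <= j < len(sb)]
        j = min(cands, key=lambda j: abs(sb[order[j]] - sa[i]))
        if abs(sb[order[j]] - sa[i]) <= max_offset:
            rows.append((i, order[j]))
    if not rows:
        raise FieldError("no stations matched within max_offset")
    ia, ib = zip(*rows)
    left = profile_a.iloc[list(ia)].reset_index(drop=True)
    right = profile_b.iloc[list(ib)].reset_index(drop=True).drop(columns=[station_col])
    merged = left.join(right, lsuffix=suffixes[0], rsuffix=suffixes[1])
    return merged
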