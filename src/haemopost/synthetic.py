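"""Synthetic analytic flows with known ground truth.

Every generator returns its ground truth alongside the data, so each
downstream metric can be checked against a closed form:

* :func:`womersley_field` — pulsatile pipe flow (Womersley's Bessel-function
  solution) with closed-form flow rate and wall shear waveforms;
* :func:`helical_cylinder_field` — solid-body rotation plus axial drift,
  with uniform helicity density 2*Omega*W;
* :func:`mri_like_inlet` — coarse-voxel, noisy, moving-contour resampling of
  an inlet plane, emulating a 4D-flow-MRI export;
* :func:`two_lumen_phantom` — a two-channel dissection analogue with a tear
  plane and prescribed transmural pressure and retrograde tear volume.

All randomness flows from a caller-provided seed; there is no global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import Delaunay
from scipy.special import jv

from .fields import FieldError, SubdomainMask, TimeGrid, VelocityField
from .ivp import InletFrame, InletFrameSeries
from .mesh import Mesh, merge_meshes
from .units import M3_PER_ML, ML_PER_M3

# ------------------------------------------------------------- cylinder mesh

# orientation-preserving prism vertex permutations placing each slot at 0
_PRISM_PERMS = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ]
)


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms into 3 tets each with conforming quad-face diagonals.

    Uses the minimum-global-index rule: each quad face is cut by the diagonal
    through its smallest vertex id, which guarantees a consistent, feasible
    decomposition across neighbouring prisms.
    """
    pos = np.argmin(prisms, axis=1)
    perm = _PRISM_PERMS[pos]
    I = np.take_along_axis(prisms, perm, axis=1)
    cond = np.minimum(I[:, 1], I[:, 5]) < np.minimum(I[:, 2], I[:, 4])
    tets = np.empty((len(prisms), 3, 4), dtype=np.int64)
    a = I[cond]
    tets[cond] = np.stack(
        [a[:, [0, 1, 2, 5]], a[:, [0, 1, 5, 4]], a[:, [0, 4, 5, 3]]], axis=1
    )
    b = I[~cond]
    tets[~cond] = np.stack(
        [b[:, [0, 1, 2, 4]], b[:, [0, 4, 2, 5]], b[:, [0, 4, 5, 3]]], axis=1
    )
    return tets.reshape(-1, 4)


def _disk_points(radius: float, n_rings: int, n_theta: int):
    """Graded concentric-ring point layout, clustered toward the wall.

    Ring radii follow r_k = R sin(pi k / (2 n)), so the outermost spacing is
    O(R / n^2) — fine enough to resolve near-wall velocity gradients that
    dominate wall-shear accuracy.  Returns (points2d, boundary_index_array).
    """
    pts = [np.zeros((1, 2))]
    counts = [1]
    for k in range(1, n_rings + 1):
        r = radius * np.sin(0.5 * np.pi * k / n_rings)
        m = max(8, int(round(n_theta * min(1.0, r / radius * 2.0))))
        m += m % 2  # even counts keep the layout mirror-symmetric
        th = 2 * np.pi * (np.arange(m) + 0.5 * (k % 2)) / m
        pts.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        counts.append(m)
    pts2 = np.vstack(pts)
    boundary = np.arange(len(pts2) - counts[-1], len(pts2))
    return pts2, boundary


def cylinder_mesh(
    radius: float = 0.01,
    length: float = 0.02,
    n_rings: int = 10,
    n_theta: int = 36,
    n_axial: int = 3,
    z0: float = 0.0,
) -> Mesh:
    """Structured tetrahedral mesh of a z-aligned cylinder.

    The disc triangulation is extruded into prisms and split into
    tetrahedra; lateral-surface triangles form the (outward-oriented) wall.
    End caps are open (inlet/outlet), not wall.
    """
    pts2, boundary = _disk_points(radius, n_rings, n_theta)
    tri = Delaunay(pts2)
    simp = tri.simplices
    a, b, c = pts2[simp[:, 0]], pts2[simp[:, 1]], pts2[simp[:, 2]]
    u, w = b - a, c - a
    areas = 0.5 * (u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0])
    simp = simp[np.abs(areas) > 1e-14 * radius**2]
    n2 = len(pts2)
    zs = z0 + np.linspace(0.0, length, n_axial + 1)
    points = np.vstack([np.column_stack([pts2, np.full(n2, z)]) for z in zs])
    prisms = []
    for l in range(n_axial):
        lo, hi = l * n2, (l + 1) * n2
        prisms.append(np.hstack([simp + lo, simp + hi]))
    tets = _split_prisms(np.vstack(prisms))
    # lateral wall quads -> oriented triangles
    nb = len(boundary)
    tris = []
    for l in range(n_axial):
        lo, hi = l * n2, (l + 1) * n2
        for j in range(nb):
            A, B = boundary[j] + lo, boundary[(j + 1) % nb] + lo
            C, D = boundary[(j + 1) % nb] + hi, boundary[j] + hi
            tris.append([A, B, C])
            tris.append([A, C, D])
    return Mesh(points, tets, np.array(tris, dtype=np.int64))


# ---------------------------------------------------------------- Womersley


@dataclass
class WomersleySpec:
    """Pulsatile pipe-flow specification.

    ``harmonic_amplitudes[n]`` and ``harmonic_phases[n]`` define the flow
    waveform Q(t) = Re{ sum_n A_n e^{i phi_n} e^{i n omega t} } in ml/s
    (n = 0 is the steady component; its phase is ignored).
    """

    radius: float = 0.01
    length: float = 0.02
    density: float = 1056.0
    viscosity: float = 3.5e-3
    period: float = 60.0 / 94.0  # heart rate of 94 bpm
    harmonic_amplitudes: np.ndarray = dc_field(default_factory=lambda: np.array([60.0, 30.0]))
    harmonic_phases: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0]))
    n_rings: int = 10
    n_theta: int = 36
    n_axial: int = 3

    def __post_init__(self):
        if min(self.radius, self.period, self.viscosity, self.density) <= 0:
            raise FieldError("radius, period, viscosity and density must be positive")
        self.harmonic_amplitudes = np.atleast_1d(np.asarray(self.harmonic_amplitudes, float))
        self.harmonic_phases = np.atleast_1d(np.asarray(self.harmonic_phases, float))
        if len(self.harmonic_phases) != len(self.harmonic_amplitudes):
            raise FieldError("amplitudes and phases must have equal length")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    @property
    def alpha(self) -> float:
        """Womersley number of the fundamental harmonic, R*sqrt(rho*omega/mu)."""
        return self.radius * np.sqrt(self.density * self.omega / self.viscosity)

    @property
    def complex_harmonics(self) -> np.ndarray:
        q = self.harmonic_amplitudes * np.exp(1j * self.harmonic_phases)
        q[0] = self.harmonic_amplitudes[0]
        return q


@dataclass
class WomersleyResult:
    field: VelocityField
    spec: WomersleySpec
    q_exact: np.ndarray  # ml/s at snapshot times
    tau_exact: np.ndarray  # Pa at snapshot times (axial wall shear, flow-positive)
    alpha: float

    def q_at(self, t) -> np.ndarray:
        return _wom_series(self.spec, np.asarray(t), "q")

    def tau_at(self, t) -> np.ndarray:
        return _wom_series(self.spec, np.asarray(t), "tau")


def _wom_coeffs(spec: WomersleySpec):
    """Per-harmonic profile shapes, flux normalization and wall-shear factors."""
    R, mu = spec.radius, spec.viscosity
    out = []
    for n, q_ml in enumerate(spec.complex_harmonics):
        q_si = q_ml * M3_PER_ML
        if n == 0:
            out.append((n, q_si.real, None, None, 4.0 * mu * q_si.real / (np.pi * R**3)))
            continue
        alpha_n = R * np.sqrt(spec.density * n * spec.omega / mu)
        lam = 1j**1.5 * alpha_n
        j0 = jv(0, lam)
        denom = 1.0 - 2.0 * jv(1, lam) / (lam * j0)
        tau_n = -mu * q_si * lam * jv(1, lam) / (np.pi * R**3 * j0 * denom)
        out.append((n, q_si, lam, denom, tau_n))
    return out


def _wom_series(spec: WomersleySpec, t: np.ndarray, which: str) -> np.ndarray:
    """Closed-form Q(t) in ml/s ("q") or wall shear tau(t) in Pa ("tau")."""
    t = np.asarray(t, dtype=np.float64)
    acc = np.zeros_like(t)
    for n, q_si, lam, denom, tau_n in _wom_coeffs(spec):
        ph = np.exp(1j * n * spec.omega * t)
        if which == "q":
            acc = acc + np.real(q_si * ph) * ML_PER_M3
        else:
            acc = acc + np.real(tau_n * ph)
    return acc


def womersley_velocity(spec: WomersleySpec, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Closed-form axial velocity u(r, t); r and t broadcast to (len(t), len(r))."""
    R = spec.radius
    r = np.asarray(r, dtype=np.float64)
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    u = np.zeros((len(t), len(r)))
    area = np.pi * R**2
    for n, q_si, lam, denom, _ in _wom_coeffs(spec):
        if n == 0:
            u += (2.0 * q_si / area) * (1.0 - (r / R) ** 2)[None, :] * np.ones((len(t), 1))
        else:
            shape = (1.0 - jv(0, lam * r / R) / jv(0, lam)) / denom
            ph = np.exp(1j * n * spec.omega * t)
            u += np.real((q_si / area) * ph[:, None] * shape[None, :])
    return u


def womersley_field(
    spec: WomersleySpec, n_snapshots: int, mesh: Mesh | None = None
) -> WomersleyResult:
    """Generate a Womersley pipe-flow velocity field on a cylinder mesh,
    together with the closed-form flow-rate and wall-shear waveforms used
    as oracles downstream."""
    if n_snapshots < 8:
        raise FieldError("need at least 8 snapshots to represent the cycle")
    if spec.alpha > 50:
        warnings.warn(
            f"Womersley number {spec.alpha:.1f} > 50: the Stokes layer may be "
            "unresolved on the default mesh",
            stacklevel=2,
        )
    if mesh is None:
        mesh = cylinder_mesh(spec.radius, spec.length, spec.n_rings, spec.n_theta, spec.n_axial)
    grid = TimeGrid.over_cycle(spec.period, n_snapshots)
    r = np.linalg.norm(mesh.points[:, :2], axis=1)
    r = np.minimum(r, spec.radius)
    u = womersley_velocity(spec, r, grid.times)
    values = np.zeros((n_snapshots, len(mesh.points), 3))
    values[:, :, 2] = u
    q = _wom_series(spec, grid.times, "q")
    tau = _wom_series(spec, grid.times, "tau")
    return WomersleyResult(VelocityField(mesh, grid, values), spec, q, tau, spec.alpha)


# ------------------------------------------------------------ helical flow


def helical_cylinder_field(
    omega_rot: float,
    w_axial: float,
    mesh: Mesh,
    grid: TimeGrid | None = None,
) -> VelocityField:
    """Steady helical flow v = Omega r theta_hat + W z_hat on a z-aligned
    cylinder; vorticity is 2 Omega z_hat and helicity density 2 Omega W
    everywhere."""
    if grid is None:
        grid = TimeGrid.over_cycle(1.0, 8)
    x, y = mesh.points[:, 0], mesh.points[:, 1]
    v = np.column_stack([-omega_rot * y, omega_rot * x, np.full(len(x), w_axial)])
    values = np.broadcast_to(v, (grid.n_snapshots,) + v.shape).copy()
    return VelocityField(mesh, grid, values)


# --------------------------------------------------------- MRI-like inlet


@dataclass
class MriInletResult:
    series: InletFrameSeries
    clean_velocities: list[np.ndarray]  # noise-free voxel velocities per frame
    voxel: float
    seed: int


def mri_like_inlet(
    field: VelocityField,
    n_frames: int = 16,
    voxel: float = 2.25e-3,
    noise_sd: float = 0.0,
    motion_amplitude: float = 0.0,
    seed: int = 0,
) -> MriInletResult:
    """Emulate a 4D-flow-MRI export of the inlet plane of a velocity field.

    The inlet plane (minimum-z cap) is sampled on a coarse voxel grid at
    ``n_frames`` uniformly spaced times; the inlet contour translates and
    dilates sinusoidally with amplitude ``motion_amplitude`` (voxel sample
    positions move with it and velocities are read at the inverse-mapped
    location); additive Gaussian noise of ``noise_sd`` m/s is applied per
    velocity component.  Fully reproducible for a fixed seed.
    """
    if n_frames < 4:
        raise FieldError("need at least 4 frames")
    mesh = field.mesh
    z0 = mesh.points[:, 2].min()
    cap = mesh.points[np.abs(mesh.points[:, 2] - z0) < 1e-12 + 1e-9 * abs(z0)]
    centre = cap[:, :2].mean(axis=0)
    R = np.linalg.norm(cap[:, :2] - centre, axis=1).max()
    if voxel >= R:
        raise FieldError(f"voxel size {voxel} exceeds inlet radius {R}")
    rng = np.random.default_rng(seed)
    T = field.grid.period
    t0 = field.grid.times[0]
    gx = np.arange(-R, R + voxel, voxel)
    GX, GY = np.meshgrid(gx, gx, indexing="ij")
    grid2 = np.column_stack([GX.ravel(), GY.ravel()]) + centre
    n_c = 64
    th = np.linspace(0, 2 * np.pi, n_c, endpoint=False)
    circle = np.column_stack([np.cos(th), np.sin(th)])
    om = 2 * np.pi / T
    frames, clean = [], []
    for j in range(n_frames):
        t = j * T / n_frames
        offset = motion_amplitude * np.array([np.sin(om * t), 0.0])
        dil = 1.0 + 0.3 * (motion_amplitude / R) * (1.0 - np.cos(om * t))
        contour2 = centre + offset + dil * R * circle
        # voxels whose inverse-mapped position lies inside the resting lumen
        inv = (grid2 - centre - offset) / dil + centre
        r_inv = np.linalg.norm(inv - centre, axis=1)
        keep = r_inv <= 0.995 * R
        pts_inv = inv[keep]
        pts_moved = grid2[keep]
        # temporal linear interpolation between snapshots (periodic)
        s = np.mod(t + t0 - field.grid.times[0], T) / field.grid.dt
        i0 = int(np.floor(s)) % field.grid.n_snapshots
        i1 = (i0 + 1) % field.grid.n_snapshots
        w1 = s - np.floor(s)
        pts3 = np.column_stack([pts_inv, np.full(len(pts_inv), z0)])
        v0 = mesh.interpolate(field.values[i0], pts3)
        v1 = mesh.interpolate(field.values[i1], pts3)
        v = (1 - w1) * v0 + w1 * v1
        clean.append(v.copy())
        v = v + rng.normal(0.0, noise_sd, v.shape) if noise_sd > 0 else v
        contour3 = np.column_stack([contour2, np.full(n_c, z0)])
        moved3 = np.column_stack([pts_moved, np.full(len(pts_moved), z0)])
        frames.append(InletFrame(t, contour3, moved3, v))
    return MriInletResult(InletFrameSeries(T, frames), clean, voxel, seed)


# ------------------------------------------------------ two-lumen phantom


@dataclass
class PhantomSpec:
    """Two parallel lumens with a tear plane, emulating dissection topology.

    Prescribed quantities are the oracles for the clinical metrics: a
    constant transmural pressure offset (TL - FL), a tear flow waveform
    with known retrograde volume, and a stroke volume.
    """

    tl_radius: float = 0.010
    fl_radius: float = 0.012
    length: float = 0.20
    separation: float = 0.035
    period: float = 60.0 / 94.0
    n_snapshots: int = 32
    stroke_volume_ml: float = 70.0
    retrograde_volume_ml: float = 1.5
    antegrade_volume_ml: float = 7.0
    tmp_mmhg: float = 2.0
    base_pressure_mmhg: float = 93.0
    pulse_mmhg: float = 46.0
    tl_flow_fraction: float = 0.7
    station_spacing: float = 5e-3
    n_rings: int = 4
    n_theta: int = 16
    n_axial: int = 10

    def __post_init__(self):
        if self.stroke_volume_ml <= 0:
            raise FieldError("stroke volume must be positive")
        if self.separation <= self.tl_radius + self.fl_radius:
            raise FieldError("lumens overlap: increase separation")


@dataclass
class PhantomResult:
    mesh: Mesh
    mask: SubdomainMask
    field: VelocityField
    grid: TimeGrid
    stations: np.ndarray  # arc length from the tear, m
    p_tl: np.ndarray  # (n_t, n_stations) mmHg
    p_fl: np.ndarray  # (n_t, n_stations) mmHg
    tear_flow: np.ndarray  # (n_t,) ml/s, normal oriented TL -> FL
    stroke_volume_ml: float
    oracles: dict


def two_lumen_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build the dissection phantom with its prescribed clinical oracles."""
    tl = cylinder_mesh(spec.tl_radius, spec.length, spec.n_rings, spec.n_theta, spec.n_axial)
    fl = cylinder_mesh(spec.fl_radius, spec.length, spec.n_rings, spec.n_theta, spec.n_axial)
    fl_pts = fl.points.copy()
    fl_pts[:, 0] += spec.separation
    fl = Mesh(fl_pts, fl.tets, fl.wall_tris)
    mesh, _ = merge_meshes(tl, fl)

    cent = mesh.cell_centroids
    in_fl = cent[:, 0] > spec.separation / 2.0
    z = cent[:, 2]
    z_tear = 0.15 * spec.length
    z_abd = 0.60 * spec.length
    labels = np.empty(len(cent), dtype=object)
    labels[~in_fl & (z < z_tear)] = "AA"
    labels[~in_fl & (z >= z_tear) & (z < z_abd)] = "TLt"
    labels[~in_fl & (z >= z_abd)] = "TLa"
    labels[in_fl & (z < z_abd)] = "FLt"
    labels[in_fl & (z >= z_abd)] = "FLa"
    mask = SubdomainMask(labels)

    grid = TimeGrid.over_cycle(spec.period, spec.n_snapshots)
    T, om = spec.period, 2 * np.pi / spec.period
    # inflow waveform with net cycle volume = stroke volume
    q_mean = spec.stroke_volume_ml / T
    q_in = q_mean * (1.0 + 0.8 * np.sin(om * grid.times))
    # parabolic axial flow in each lumen
    values = np.zeros((spec.n_snapshots, len(mesh.points), 3))
    for lum, radius, cx, frac in (
        ("tl", spec.tl_radius, 0.0, spec.tl_flow_fraction),
        ("fl", spec.fl_radius, spec.separation, 1.0 - spec.tl_flow_fraction),
    ):
        r = np.linalg.norm(mesh.points[:, :2] - np.array([cx, 0.0]), axis=1)
        in_lum = r <= radius * (1 + 1e-9)
        shape = np.where(in_lum, 1.0 - np.minimum(r / radius, 1.0) ** 2, 0.0)
        area = np.pi * radius**2
        for j in range(spec.n_snapshots):
            values[j, :, 2] += 2.0 * (frac * q_in[j] * M3_PER_ML / area) * shape
    field = VelocityField(mesh, grid, values)

    n_st = max(2, int(np.floor((z_abd - z_tear) / spec.station_spacing)) + 1)
    stations = np.arange(n_st) * spec.station_spacing
    p_wave = spec.base_pressure_mmhg + 0.5 * spec.pulse_mmhg * np.sin(om * grid.times)
    p_tl = np.repeat(p_wave[:, None], n_st, axis=1)
    p_fl = p_tl - spec.tmp_mmhg

    # tear flow: triangular antegrade (TL->FL) lobe on [0, T/2] and triangular
    # retrograde lobe on [T/2, T]; piecewise-linear with kinks on snapshot
    # times (n_snapshots is a multiple of 4), so the trapezoidal cycle
    # integral reproduces the prescribed lobe volumes exactly.
    if spec.n_snapshots % 4:
        raise FieldError("phantom n_snapshots must be a multiple of 4")
    q_f = 4.0 * spec.antegrade_volume_ml / T
    q_r = 4.0 * spec.retrograde_volume_ml / T
    phase = np.mod(grid.times, T) / T
    tri = 1.0 - np.abs(4.0 * np.mod(phase, 0.5) - 1.0)  # unit triangle per half-cycle
    tear_flow = np.where(phase < 0.5, q_f * tri, -q_r * tri)

    flef = 100.0 * spec.retrograde_volume_ml / spec.stroke_volume_ml
    oracles = {
        "tmp_mmhg": spec.tmp_mmhg,
        "flef_pct": flef,
        "stroke_volume_ml": spec.stroke_volume_ml,
        "retrograde_volume_ml": spec.retrograde_volume_ml,
    }
    return PhantomResult(
        mesh, mask, field, grid, stations, p_tl, p_fl, tear_flow,
        spec.stroke_volume_ml, oracles,
    )
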