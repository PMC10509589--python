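import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haemopost.fields import FieldError, PlaneSection, TimeGrid, disk_plane, plane_flux
from haemopost.synthetic import (
    PhantomSpec,
    WomersleySpec,
    _split_prisms,
    cylinder_mesh,
    helical_cylinder_field,
    mri_like_inlet,
    two_lumen_phantom,
    womersley_field,
    womersley_velocity,
)


# ------------------------------------------------------------- prism split


def _faces(tet):
    return {frozenset(f) for f in (tet[[0, 1, 2]], tet[[0, 1, 3]], tet[[0, 2, 3]], tet[[1, 2, 3]])}


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_prism_split_conforms_on_shared_quads(base):
    """Two prisms sharing a quad face must receive the same diagonal."""
    # prisms (a,b,c | a',b',c') and (b,a,d | b',a',d') share quad (a,b,b',a')
    a, b, c, d = base, base + 7, base + 3, base + 11
    p1 = np.array([[a, b, c, a + 100, b + 100, c + 100]])
    p2 = np.array([[b, a, d, b + 100, a + 100, d + 100]])
    t1 = _split_prisms(p1)
    t2 = _split_prisms(p2)
    f1 = set().union(*[_faces(t) for t in t1])
    f2 = set().union(*[_faces(t) for t in t2])
    quad = {a, b, a + 100, b + 100}
    tri1 = {f for f in f1 if f <= quad}
    tri2 = {f for f in f2 if f <= quad}
    assert tri1 == tri2 and len(tri1) == 2


def test_prism_split_covers_volume():
    pts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1], [0, 1, 1]], dtype=float
    )
    tets = _split_prisms(np.array([[0, 1, 2, 3, 4, 5]]))
    from haemopost.mesh import Mesh

    m = Mesh(pts, tets)
    assert np.isclose(m.cell_volumes.sum(), 0.5)  # prism volume = area * height


# ------------------------------------------------------------- cylinder mesh


def test_cylinder_mesh_is_mirror_symmetric():
    m = cylinder_mesh(0.01, 0.02, 4, 16, 2)
    # integral of x over the mesh must vanish by symmetry of the point layout
    ix = m.cell_volumes @ m.cell_centroids[:, 0]
    assert abs(ix) < 1e-12 * m.cell_volumes.sum() / 0.01


def test_cylinder_wall_excludes_caps(small_cylinder):
    z = small_cylinder.points[small_cylinder.wall_node_ids][:, 2]
    r = np.linalg.norm(small_cylinder.points[small_cylinder.wall_node_ids][:, :2], axis=1)
    assert np.allclose(r, 0.01, rtol=1e-9)
    assert z.min() == 0.0 and np.isclose(z.max(), 0.02)  # caps share the rim only


# ----------------------------------------------------------------- Womersley


def test_womersley_flux_oracle_matches_mesh_integral(womersley):
    """The mesh-integrated flux through a mid-plane must reproduce the
    closed-form Q(t) (independent oracle for the velocity synthesis)."""
    spec = womersley.spec
    plane = disk_plane([0, 0, spec.length / 2], [0, 0, 1], spec.radius, n_rings=24)
    for j in [0, 5, 11]:
        q = plane_flux(womersley.field, plane, j)
        assert q == pytest.approx(womersley.q_exact[j], rel=0.02, abs=0.05)


def test_womersley_steady_limit_is_poiseuille():
    spec = WomersleySpec(harmonic_amplitudes=np.array([10.0]), harmonic_phases=np.array([0.0]))
    r = np.linspace(0, spec.radius, 20)
    u = womersley_velocity(spec, r, np.array([0.0, 0.3]))
    u_exact = 2.0 * (10e-6 / (np.pi * spec.radius**2)) * (1 - (r / spec.radius) ** 2)
    assert np.allclose(u, u_exact[None, :], atol=1e-12)
    tau_exact = 4 * spec.viscosity * 10e-6 / (np.pi * spec.radius**3)
    res = womersley_field(spec, 8)
    assert np.allclose(res.tau_exact, tau_exact)


def test_womersley_velocity_vanishes_at_wall(womersley):
    spec = womersley.spec
    u = womersley_velocity(spec, np.array([spec.radius]), womersley.field.grid.times)
    assert np.allclose(u, 0.0, atol=1e-12)


def test_womersley_high_alpha_warns():
    spec = WomersleySpec(radius=0.05, period=0.1)
    assert spec.alpha > 50
    with pytest.warns(UserWarning, match="Stokes layer"):
        womersley_field(spec, 8, mesh=cylinder_mesh(0.05, 0.02, 3, 12, 1))


def test_womersley_too_few_snapshots():
    with pytest.raises(FieldError, match="8 snapshots"):
        womersley_field(WomersleySpec(), 4)


# ------------------------------------------------------------- helical flow


def test_helical_field_values(helical):
    pts = helical.mesh.points
    v = helical.values[0]
    assert np.allclose(v[:, 0], -10.0 * pts[:, 1])
    assert np.allclose(v[:, 1], 10.0 * pts[:, 0])
    assert np.allclose(v[:, 2], 0.5)


# ----------------------------------------------------------- MRI-like inlet


def test_mri_inlet_reproducible(womersley):
    a = mri_like_inlet(womersley.field, n_frames=6, voxel=1e-3, noise_sd=0.05, seed=11)
    b = mri_like_inlet(womersley.field, n_frames=6, voxel=1e-3, noise_sd=0.05, seed=11)
    c = mri_like_inlet(womersley.field, n_frames=6, voxel=1e-3, noise_sd=0.05, seed=12)
    for fa, fb in zip(a.series.frames, b.series.frames):
        assert np.array_equal(fa.velocities, fb.velocities)
    assert not all(
        np.array_equal(fa.velocities, fc.velocities)
        for fa, fc in zip(a.series.frames, c.series.frames)
    )


def test_mri_inlet_clean_matches_field(womersley):
    """With zero noise and no motion, voxel velocities are plain samples of
    the underlying field at the inlet plane."""
    res = mri_like_inlet(womersley.field, n_frames=8, voxel=1e-3, seed=0)
    f0 = res.series.frames[0]
    direct = womersley.field.mesh.interpolate(womersley.field.values[0], f0.points)
    assert np.allclose(f0.velocities, direct, atol=1e-12)


def test_mri_inlet_voxel_too_coarse(womersley):
    with pytest.raises(FieldError, match="voxel"):
        mri_like_inlet(womersley.field, voxel=1.0)


# --------------------------------------------------------- two-lumen phantom


def test_phantom_tear_volumes_exact(phantom):
    """Trapezoid integration of the tear waveform must reproduce the
    prescribed antegrade/retrograde volumes exactly (kinks on snapshots)."""
    dt = phantom.grid.dt
    retro = np.clip(-phantom.tear_flow, 0, None).sum() * dt
    ante = np.clip(phantom.tear_flow, 0, None).sum() * dt
    assert retro == pytest.approx(phantom.oracles["retrograde_volume_ml"], rel=1e-12)
    assert ante == pytest.approx(7.0, rel=1e-12)


def test_phantom_pressure_offset_constant(phantom):
    assert np.allclose(phantom.p_tl - phantom.p_fl, phantom.oracles["tmp_mmhg"])


def test_phantom_subdomains_cover_mesh(phantom):
    assert set(phantom.mask.used_labels) == {"AA", "TLt", "FLt", "TLa", "FLa"}
    assert not np.any(phantom.mask.labels == "none")


def test_phantom_snapshot_multiple_of_four():
    with pytest.raises(FieldError, match="multiple of 4"):
        two_lumen_phantom(PhantomSpec(n_snapshots=30))
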