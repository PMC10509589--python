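import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haemopost.fields import TimeGrid
from haemopost.ivp import (
    InletProfile,
    RegistrationError,
    build_4d_ivp,
    inlet_patch_from_mesh,
    make_flat_ivp,
    make_tp_ivp,
    register_frames,
    scale_ivp,
)
from haemopost.synthetic import mri_like_inlet, womersley_field


@pytest.fixture(scope="module")
def patch(womersley):
    return inlet_patch_from_mesh(womersley.field.mesh, [0, 0, 0], [0, 0, 1])


@pytest.fixture(scope="module")
def reference_ivp(womersley, patch):
    """The Womersley inlet-plane velocities as a 'measured' reference profile."""
    grid = womersley.field.grid
    values = womersley.field.values[:, patch.node_ids, :]
    return InletProfile(patch, grid, values)


def test_patch_area_close_to_disc(patch):
    assert patch.area == pytest.approx(np.pi * 0.004**2, rel=0.01)


def test_patch_boundary_is_rim(patch):
    r = np.linalg.norm(patch.points[patch.boundary_mask][:, :2], axis=1)
    assert np.allclose(r, 0.004, rtol=1e-9)


def test_reference_flux_matches_oracle(womersley, reference_ivp):
    """Patch-quadrature flux of the analytic profile matches the closed form
    Q(t) within the polygonal-area discretization error."""
    q = reference_ivp.flux_series()
    scale = np.abs(womersley.q_exact).max()
    assert np.allclose(q, womersley.q_exact, atol=0.02 * scale)


def test_flat_ivp_flux_matches_reference(reference_ivp):
    flat = make_flat_ivp(reference_ivp)
    q_ref, q_flat = reference_ivp.flux_si(), flat.flux_si()
    assert np.allclose(q_flat, q_ref, rtol=1e-10, atol=1e-18)
    # spatially uniform by construction
    v = flat.values
    assert np.allclose(v, v[:, :1, :])


def test_tp_ivp_flux_bitwise(reference_ivp):
    tp = make_tp_ivp(reference_ivp)
    assert np.array_equal(tp.flux_si(), reference_ivp.flux_si())
    # in-plane components are zero
    e1, e2 = reference_ivp.patch.basis
    assert np.allclose(tp.values @ e1, 0.0, atol=1e-18)
    assert np.allclose(tp.values @ e2, 0.0, atol=1e-18)


def test_scaled_ivp_stroke_volume_exact(reference_ivp):
    scaled = scale_ivp(reference_ivp, 1.25)
    assert scaled.stroke_volume_ml() == pytest.approx(
        1.25 * reference_ivp.stroke_volume_ml(), rel=1e-14
    )


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.floats(0.1, 4.0))
def test_scale_property(reference_ivp, factor):
    scaled = scale_ivp(reference_ivp, factor)
    assert np.allclose(scaled.flux_si(), factor * reference_ivp.flux_si(), rtol=1e-12)


# ----------------------------------------------------------- registration


def test_registration_recovers_similarity(womersley, patch):
    """Frames translated and dilated rigidly must map back onto the patch
    with near-zero residual and an inverse similarity transform."""
    res = mri_like_inlet(womersley.field, n_frames=6, voxel=4e-4, motion_amplitude=8e-4, seed=5)
    mappings = register_frames(res.series, patch, nonrigid=False)
    for mp in mappings:
        assert mp.residual_rms < 0.02 * patch.mean_radius
        assert mp.fold_over_free
    # frame 0 has zero offset and unit dilation: identity transform
    assert mappings[0].scale == pytest.approx(1.0, rel=1e-2)
    assert np.allclose(mappings[0].translation, 0.0, atol=1e-5)


def test_registration_nonrigid_reduces_residual(womersley, patch):
    res = mri_like_inlet(womersley.field, n_frames=6, voxel=4e-4, motion_amplitude=8e-4, seed=5)
    rigid = register_frames(res.series, patch, nonrigid=False)
    soft = register_frames(res.series, patch, rigidity=0.1)
    for a, b in zip(soft, rigid):
        assert a.residual_rms <= b.residual_rms + 1e-12


def test_registration_rejects_garbage(womersley, patch):
    res = mri_like_inlet(womersley.field, n_frames=6, voxel=4e-4, seed=5)
    # corrupt one contour anisotropically (a similarity transform absorbs
    # uniform scaling and offsets, so the distortion must be non-uniform)
    bad = res.series
    c = bad.frames[2].contour.mean(axis=0)
    bad.frames[2].contour = c + (bad.frames[2].contour - c) * np.array([6.0, 1.0, 1.0])
    with pytest.raises(RegistrationError):
        register_frames(bad, patch, nonrigid=False)


# --------------------------------------------------------------- 4D build


def test_build_4d_ivp_reconstructs_flux(womersley, patch):
    """End-to-end: voxelized noiseless frames -> registration -> 4D IVP.
    The rebuilt profile's flow waveform must track the analytic Q(t)."""
    res = mri_like_inlet(womersley.field, n_frames=16, voxel=4e-4, seed=1)
    mappings = register_frames(res.series, patch, nonrigid=False)
    grid = TimeGrid.over_cycle(womersley.spec.period, 16)
    ivp = build_4d_ivp(res.series, mappings, patch, grid)
    q = ivp.flux_series()
    scale = np.abs(womersley.q_exact).max()
    assert np.allclose(q, womersley.q_exact, atol=0.08 * scale)
    # no-slip rim
    assert np.allclose(ivp.values[:, patch.boundary_mask, :], 0.0)
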