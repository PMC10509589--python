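import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haemopost.fields import FieldError, TimeGrid, VelocityField, WallShearField
from haemopost.pod import (
    energy_spectrum,
    reconstruct,
    reconstruction_error,
    snapshot_pod,
    wss_indices_from_modes,
)
from haemopost.wss import compute_wss_indices, wall_shear_from_field


def _field(mesh, values, period=1.0):
    grid = TimeGrid.over_cycle(period, values.shape[0])
    return VelocityField(mesh, grid, values)


def _random_field(mesh, n_t, seed, rank=None):
    rng = np.random.default_rng(seed)
    n = len(mesh.points)
    if rank is None:
        vals = rng.standard_normal((n_t, n, 3))
    else:
        A = rng.standard_normal((n_t, rank))
        B = rng.standard_normal((rank, n * 3))
        vals = (A @ B).reshape(n_t, n, 3)
    return _field(mesh, vals)


def test_rank_one_field_needs_one_mode(small_cylinder):
    rng = np.random.default_rng(1)
    shape = rng.standard_normal((len(small_cylinder.points), 3))
    a = np.array([1.0, -2.0, 0.5, 3.0, -1.5, 0.0, 2.0, -2.0])
    vals = a[:, None, None] * shape
    pod = snapshot_pod(_field(small_cylinder, vals))
    assert pod.n_modes == 1
    rec = reconstruct(pod, 1)
    assert np.allclose(rec.values, vals, atol=1e-10 * np.abs(vals).max())


def test_modes_orthonormal_and_coeffs_consistent(small_cylinder):
    field = _random_field(small_cylinder, 10, seed=2)
    pod = snapshot_pod(field)
    G = np.einsum("kna,lna,n->kl", pod.modes, pod.modes, pod.weights)
    assert np.allclose(G, np.eye(pod.n_modes), atol=1e-9)
    # eigenvalues are the coefficient energies
    assert np.allclose((pod.coeffs**2).sum(axis=0), pod.eigenvalues[: pod.n_modes], rtol=1e-9)


def test_uniform_weight_pod_matches_svd_oracle(small_cylinder):
    """Under uniform weighting, snapshot-POD eigenvalues must equal the
    squared singular values of the mean-subtracted snapshot matrix."""
    field = _random_field(small_cylinder, 9, seed=3)
    pod = snapshot_pod(field, weighting="uniform")
    X = (field.values - field.values.mean(axis=0)).reshape(9, -1)
    sv = np.linalg.svd(X, compute_uv=False)
    assert np.allclose(pod.eigenvalues[: len(sv)], sv**2, rtol=1e-9)


def test_full_reconstruction_exact(small_cylinder):
    field = _random_field(small_cylinder, 8, seed=4)
    pod = snapshot_pod(field)
    rec = reconstruct(pod, pod.n_modes)
    assert np.abs(rec.values - field.values).max() < 1e-8 * np.abs(field.values).max()


def test_parseval_truncation_identity(small_cylinder):
    """The actual weighted-L2 truncation error must match the eigenvalue
    tail sum for every rank (Parseval)."""
    field = _random_field(small_cylinder, 8, seed=5)
    pod = snapshot_pod(field)
    X = field.values - field.values.mean(axis=0)
    Wf = pod.weights
    total = np.einsum("tna,tna,n->", X, X, Wf)
    for k in range(pod.n_modes + 1):
        rec = reconstruct(pod, k)
        E = rec.values - field.values
        err = np.sqrt(np.einsum("tna,tna,n->", E, E, Wf) / total)
        assert err == pytest.approx(reconstruction_error(pod, k), abs=1e-8)


def test_energy_spectrum_threshold(small_cylinder):
    field = _random_field(small_cylinder, 12, seed=6, rank=6)
    pod = snapshot_pod(field)
    spec = energy_spectrum(pod, threshold=0.98)
    cum = spec["cumulative"]
    k = spec["k_at_threshold"]
    assert cum[k - 1] >= 0.98 - 1e-12
    assert k == 1 or cum[k - 2] < 0.98
    assert spec["fractions"].sum() == pytest.approx(1.0)
    assert (np.diff(spec["fractions"][: pod.n_modes]) <= 1e-12).all()


def test_mode_sign_convention(small_cylinder):
    field = _random_field(small_cylinder, 6, seed=7)
    pod = snapshot_pod(field)
    for phi in pod.modes:
        flat = phi.ravel()
        assert flat[np.argmax(np.abs(flat))] > 0


@settings(derandomize=True, max_examples=10, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_pod_energy_conservation_property(small_cylinder, seed):
    field = _random_field(small_cylinder, 6, seed=seed)
    pod = snapshot_pod(field)
    X = field.values - field.values.mean(axis=0)
    total = np.einsum("tna,tna,n->", X, X, pod.weights)
    assert pod.eigenvalues.sum() == pytest.approx(total, rel=1e-9)


def test_wall_shear_pod_and_index_errors(poiseuille, womersley_fluid, womersley):
    tau = wall_shear_from_field(womersley.field, womersley_fluid)
    pod = snapshot_pod(tau)
    maps_full = compute_wss_indices(tau)
    rec = reconstruct(pod, pod.n_modes)
    maps_rec = compute_wss_indices(rec)
    assert np.allclose(maps_rec.tawss, maps_full.tawss, rtol=1e-8)
    _, errors = wss_indices_from_modes(pod, pod.n_modes)
    assert max(errors.values()) < 1e-8
    _, errors1 = wss_indices_from_modes(pod, 1)
    assert errors1["tawss"] >= 0.0  # truncation error is reported, not hidden


def test_pod_rejects_velocity_for_wss_indices(small_cylinder):
    field = _random_field(small_cylinder, 6, seed=8)
    pod = snapshot_pod(field)
    with pytest.raises(FieldError, match="wall-shear"):
        wss_indices_from_modes(pod, 1)


def test_reconstruct_bad_rank(small_cylinder):
    field = _random_field(small_cylinder, 6, seed=9)
    pod = snapshot_pod(field)
    with pytest.raises(FieldError):
        reconstruct(pod, pod.n_modes + 1)
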