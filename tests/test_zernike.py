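import numpy as np
import pytest
from scipy.integrate import quad

from zpocket import zernike as zk
from zpocket.synthetic import rotate_cloud, sample_shape


def test_descriptor_count_formula():
    assert len(zk.descriptor_index(10)) == 36
    for order in (0, 1, 2, 5, 7):
        expected = sum(n // 2 + 1 for n in range(order + 1))
        assert len(zk.descriptor_index(order)) == expected


def test_radial_r00_constant():
    r = np.linspace(0, 1, 7)
    vals = zk.radial_polynomial(0, 0, r)
    np.testing.assert_allclose(vals, vals[0])


def test_radial_orthonormality_by_quadrature():
    pairs = zk.descriptor_index(10)
    for n, l in pairs:
        for n2, l2 in pairs:
            if l2 != l or n2 < n:
                continue
            val, _ = quad(
                lambda r: zk.radial_polynomial(n, l, r)
                * zk.radial_polynomial(n2, l, r) * r * r,
                0.0, 1.0,
            )
            assert val == pytest.approx(1.0 if n == n2 else 0.0, abs=1e-6)


def test_radial_parity_validation():
    with pytest.raises(ValueError):
        zk.radial_polynomial(3, 2, 0.5)
    with pytest.raises(ValueError):
        zk.radial_polynomial(2, 3, 0.5)


def _constant_grid(L=32):
    ax = 2.0 * (np.arange(L) + 0.5) / L - 1.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = X**2 + Y**2 + Z**2
    c0 = float(np.real(zk.zernike_function(0, 0, 0, 0.3, 0.1, 0.2)))
    return zk.VoxelGrid(np.where(r2 <= 1.0, c0, 0.0))


def test_moments_of_constant_field_project_onto_z000():
    m = zk.compute_moments(_constant_grid(), order=4)
    assert m[(0, 0, 0)].real == pytest.approx(1.0, abs=0.01)  # |Z00|^2 integral
    for (n, l), row in m.items():
        if (n, l) != (0, 0):
            assert np.max(np.abs(row)) < 0.02


def test_zero_grid_gives_zero_moments():
    m = zk.compute_moments(zk.VoxelGrid(np.zeros((32, 32, 32))), order=6)
    for _, row in m.items():
        np.testing.assert_allclose(row, 0.0)


def test_conjugate_symmetry_of_real_field():
    rng = np.random.default_rng(2)
    grid = zk.voxelize(rng.normal(scale=3.0, size=(300, 3)), 32, mode="density")
    m = zk.compute_moments(grid, order=6)
    for (n, l), row in m.items():
        for mm in range(-l, l + 1):
            lhs = row[-mm + l]
            rhs = (-1) ** mm * np.conj(row[mm + l])
            assert abs(lhs - rhs) < 1e-10


def test_voxelize_two_point_cloud_occupancy():
    grid = zk.voxelize(np.array([[0.0, 0, 0], [4.0, 0, 0]]), 32)
    assert np.count_nonzero(grid.values) in (1, 2)
    assert set(np.unique(grid.values)) <= {0.0, 1.0}


def test_voxelize_respects_fill_fraction():
    pts = sample_shape("blob", n_points=3000, seed=1)
    grid = zk.voxelize(pts, 32, 0.7)
    X, Y, Z = grid.voxel_centers_unit()
    r = np.sqrt(X**2 + Y**2 + Z**2)[grid.values > 0]
    assert r.max() <= 0.7 + np.sqrt(3.0) * (2.0 / 32)


def test_voxelize_sphere_gives_thin_shell():
    rng = np.random.default_rng(0)
    u = rng.normal(size=(20000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    grid = zk.voxelize(5.0 * u, 32, 0.7)
    X, Y, Z = grid.voxel_centers_unit()
    r = np.sqrt(X**2 + Y**2 + Z**2)[grid.values > 0]
    diag = np.sqrt(3.0) * (2.0 / 32)
    assert r.min() >= 0.7 - 2 * diag and r.max() <= 0.7 + 2 * diag


def test_voxelize_degenerate_cloud_errors():
    with pytest.raises(ValueError, match="degenerate"):
        zk.voxelize(np.zeros((5, 3)), 32)


def test_density_mode_field_integrates_to_one():
    pts = sample_shape("dumbbell", n_points=5000, seed=3)
    grid = zk.voxelize(pts, 32, mode="density")
    assert grid.values.sum() * grid.voxel_volume == pytest.approx(1.0, abs=1e-12)


def test_descriptor_translation_invariance():
    pts = sample_shape("ellipsoid", n_points=5000, seed=5)
    d0 = zk.describe_points(pts, grid_side=32)
    d1 = zk.describe_points(pts + np.array([123.4, -56.7, 8.9]), grid_side=32)
    np.testing.assert_allclose(d0.values, d1.values, atol=1e-12)


def test_descriptor_rotation_invariance_small_grid():
    pts = sample_shape("blob", n_points=20000, seed=9)
    ref = zk.describe_points(pts, grid_side=32).values
    for k in range(3):
        rot = zk.describe_points(rotate_cloud(pts, seed=40 + k), grid_side=32).values
        assert np.max(np.abs(rot - ref)) <= 0.02 * ref.max()


def test_invariants_nonnegative_and_ordered(toy_surface):
    d = zk.describe_points(toy_surface.positions[:2000], order=10, grid_side=32)
    assert len(d) == 36
    assert np.all(d.values >= 0)
    assert d.index == zk.descriptor_index(10)


def test_zero_moments_give_zero_descriptor_and_field():
    zero = zk.ZernikeMoments(4, {nl: np.zeros(2 * nl[1] + 1, dtype=complex)
                                 for nl in zk.descriptor_index(4)})
    assert np.all(zk.invariants(zero).values == 0)
    assert np.all(zk.reconstruct(zero, 16).values == 0)


def test_reconstruction_error_monotone_in_order():
    # smooth radial bump on the ball
    L = 32
    ax = 2.0 * (np.arange(L) + 0.5) / L - 1.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = X**2 + Y**2 + Z**2
    field = np.where(r2 <= 1.0, np.exp(-4.0 * ((X - 0.2) ** 2 + Y**2 + Z**2)), 0.0)
    grid = zk.VoxelGrid(field)
    mask = r2 <= 1.0
    errors = []
    for order in (2, 4, 6, 8, 10):
        rec = zk.reconstruct(zk.compute_moments(grid, order), L)
        errors.append(float(np.sqrt(np.mean((rec.values[mask] - field[mask]) ** 2))))
    assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))


def test_projection_idempotence():
    pts = sample_shape("sphere", n_points=20000, seed=2)
    grid = zk.voxelize(pts, 32, mode="density")
    m1 = zk.compute_moments(grid, order=6)
    rec = zk.reconstruct(m1, 32)
    m2 = zk.compute_moments(rec, order=6)
    ref = np.concatenate([m1.coefficients[nl] for nl in zk.descriptor_index(6)])
    got = np.concatenate([m2.coefficients[nl] for nl in zk.descriptor_index(6)])
    scale = np.abs(ref).max()
    assert np.max(np.abs(got - ref)) <= 0.05 * scale


def test_optimized_moments_match_naive_sum():
    rng = np.random.default_rng(8)
    values = np.zeros((32, 32, 32))
    # a sparse random in-ball field keeps the reference triple loop cheap
    idx = rng.integers(8, 24, size=(60, 3))
    values[idx[:, 0], idx[:, 1], idx[:, 2]] = rng.uniform(0.5, 2.0, size=60)
    grid = zk.VoxelGrid(values)
    fast = zk.compute_moments(grid, order=6)
    slow = zk.compute_moments_naive(grid, order=6)
    for nl in zk.descriptor_index(6):
        np.testing.assert_allclose(fast.coefficients[nl], slow.coefficients[nl],
                                   atol=1e-10)


def test_high_order_warns():
    grid = _constant_grid(16)
    with pytest.warns(UserWarning, match="stability"):
        zk.compute_moments(grid, order=21)
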