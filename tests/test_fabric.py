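"""MIL fabric analysis: orientation sampling, exact line casting (against a
brute-force voxel walker), ellipsoid fitting and anisotropy recovery."""

import numpy as np
import pytest

from paleofract.fabric import (
    alignment_angle,
    analyze_fabric,
    cast_lines,
    degree_of_anisotropy,
    fit_fabric_tensor,
    FabricTensor,
    mean_intercept_length,
    sample_orientations,
)
from paleofract.phantoms import ImageVolume, generate_trabecular_volume


# ------------------------------------------------------------------ orientations


class TestOrientations:
    def test_count_norms_and_hemisphere(self):
        d = sample_orientations(2049, seed=3)
        assert d.shape == (2049, 3)
        assert np.abs(np.linalg.norm(d, axis=1) - 1.0).max() < 1e-12
        assert np.all(d[:, 2] >= 0)  # antipodes identified

    def test_second_moment_is_isotropic(self):
        d = sample_orientations(2049, seed=0)
        M = d.T @ d / len(d)
        assert np.linalg.norm(M - np.eye(3) / 3.0) < 1e-3

    def test_deterministic_and_seed_sensitive(self):
        assert np.array_equal(sample_orientations(64, 1), sample_orientations(64, 1))
        assert not np.array_equal(sample_orientations(64, 1), sample_orientations(64, 2))

    def test_minimum_pairwise_angle_bounded(self):
        d = sample_orientations(128, seed=0)
        g = np.abs(d @ d.T)  # antipodal-invariant
        np.fill_diagonal(g, 0.0)
        min_angle = np.degrees(np.arccos(np.clip(g.max(), -1, 1)))
        assert min_angle > 2.0

    def test_too_few_orientations_rejected(self):
        with pytest.raises(ValueError):
            sample_orientations(8)


# ------------------------------------------------------------------ line casting


def _brute_cast(volume, spacing, direction, points):
    """Scalar voxel-walk oracle: one ray at a time, axis-priority tie-breaks.

    Written independently of the vectorised implementation; must agree on
    crossing counts exactly."""
    vol = np.asarray(volume).astype(bool)
    dims = np.array(vol.shape, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    w = np.array([d[2], d[1], d[0]]) / np.asarray(spacing, dtype=float)
    lengths, crossings = [], []
    for q in np.asarray(points, dtype=float):
        with np.errstate(divide="ignore"):
            t0 = (0.0 - q) / w
            t1 = (dims - q) / w
        lo = np.where(np.isfinite(t0), np.minimum(t0, t1), -np.inf)
        hi = np.where(np.isfinite(t0), np.maximum(t0, t1), np.inf)
        t_enter, t_exit = lo.max(), hi.min()
        lengths.append(t_exit - t_enter)
        step = np.sign(w).astype(np.int64)
        with np.errstate(divide="ignore"):
            t_delta = np.where(w != 0.0, 1.0 / np.abs(w), np.inf)
        pos = q + t_enter * w
        v = np.clip(np.floor(pos).astype(np.int64), 0, (dims - 1).astype(np.int64))
        bound = v + (step > 0).astype(np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_max = np.where(w != 0.0, t_enter + (bound - pos) / w, np.inf)
        n_cross = 0
        phase = vol[v[0], v[1], v[2]]
        while True:
            axis = 0
            if t_max[1] < t_max[axis]:
                axis = 1
            if t_max[2] < t_max[axis]:
                axis = 2
            v[axis] += step[axis]
            if v[axis] < 0 or v[axis] >= int(dims[axis]):
                break
            new = vol[v[0], v[1], v[2]]
            n_cross += int(new != phase)
            phase = new
            t_max[axis] += t_delta[axis]
        crossings.append(n_cross)
    return np.array(lengths), np.array(crossings, dtype=np.int64)


def _thirteen_directions():
    dirs = []
    for v in [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
    ]:
        a = np.array(v, dtype=float)
        dirs.append(a / np.linalg.norm(a))
    return dirs


def test_crossing_counts_match_brute_force_exactly(rng):
    """Optimised traversal vs exhaustive walker on a random 16^3 volume."""
    vol = rng.random((16, 16, 16)) < 0.4
    spacing = np.array([0.1, 0.1, 0.1])
    pts = rng.uniform(0.5, 15.5, size=(40, 3))
    for d in _thirteen_directions():
        L1, c1 = cast_lines(vol, spacing, d, pts)
        L2, c2 = _brute_cast(vol, spacing, d, pts)
        assert np.array_equal(c1, c2), f"crossing mismatch along {d}"
        assert np.allclose(L1, L2)


def test_mil_of_alternating_slabs_is_spacing():
    """1-voxel slabs perpendicular to z: a crossing every layer, so MIL = s."""
    s = 0.1
    slab = np.zeros((32, 32, 32), dtype=bool)
    slab[::2] = True
    vol = ImageVolume(slab, spacing=s)
    mil = mean_intercept_length(vol, [0, 0, 1], n_points=500, seed=1)
    assert abs(mil - s) <= s / 2


def test_solid_volume_raises_phase_pure():
    vol = ImageVolume(np.ones((8, 8, 8), dtype=bool), spacing=0.1)
    with pytest.raises(ValueError, match="phase-pure"):
        mean_intercept_length(vol, [0, 0, 1], n_points=50, seed=0)


def test_mil_converged_in_point_count():
    v = generate_trabecular_volume([0, 0, 1], 1.0, 0.3, (64, 64, 64), seed=0)
    d = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
    m1 = mean_intercept_length(v, d, n_points=1000, seed=4)
    m2 = mean_intercept_length(v, d, n_points=2000, seed=4)
    assert abs(m2 - m1) / m1 < 0.02


# ---------------------------------------------------------------- tensor fitting


class TestFit:
    def test_isotropic_mils_give_unit_da(self):
        d = sample_orientations(129, 0)
        fab = fit_fabric_tensor(d, np.full(len(d), 0.42))
        assert fab.eigenvalues == pytest.approx([0.42] * 3)
        assert degree_of_anisotropy(fab) == pytest.approx(1.0)

    def test_known_ellipsoid_recovered(self):
        """Forward-generate MILs from ellipsoid with axes (3, 2, 1), invert."""
        axes = np.array([3.0, 2.0, 1.0])
        rot = np.linalg.qr(np.random.default_rng(5).normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        H = rot @ np.diag(1.0 / axes**2) @ rot.T
        d = sample_orientations(2049, 1)
        mils = 1.0 / np.sqrt(np.einsum("ni,ij,nj->n", d, H, d))
        fab = fit_fabric_tensor(d, mils)
        assert fab.eigenvalues == pytest.approx(axes, rel=0.01)
        for i in range(3):
            cosang = abs(fab.eigenvectors[i] @ rot[:, i])
            assert np.degrees(np.arccos(np.clip(cosang, 0, 1))) < 1.0

    def test_underdetermined_and_coplanar_rejected(self):
        d9 = sample_orientations(16, 0)[:8]
        with pytest.raises(ValueError, match="rank"):
            fit_fabric_tensor(d9, np.ones(8))
        theta = np.linspace(0, np.pi, 12, endpoint=False)
        coplanar = np.stack(
            [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1
        )
        with pytest.raises(ValueError, match="rank"):
            fit_fabric_tensor(coplanar, np.ones(12))

    def test_alignment_angle_endpoints(self):
        fab = FabricTensor(
            tensor=np.diag([1 / 9.0, 1 / 4.0, 1.0]),
            eigenvalues=np.array([3.0, 2.0, 1.0]),
            eigenvectors=np.eye(3),
        )
        assert alignment_angle(fab, [1, 0, 0]) == pytest.approx(0.0)
        assert alignment_angle(fab, [0, 0, 1]) == pytest.approx(90.0)
        assert alignment_angle(fab, [-1, 0, 0]) == pytest.approx(0.0)  # antipodal
        with pytest.raises(ValueError):
            alignment_angle(fab, [0, 0, 0])

    def test_da_of_listed_magnitudes(self):
        fab = FabricTensor(
            tensor=np.diag([1 / 1.27**2, 1 / 1.1**2, 1.0]),
            eigenvalues=np.array([1.27, 1.1, 1.0]),
            eigenvectors=np.eye(3),
        )
        assert degree_of_anisotropy(fab) == pytest.approx(1.27)


# ------------------------------------------------------------ pipeline recovery


def test_aligned_phantom_recovers_axis_and_da():
    v = generate_trabecular_volume([0, 0, 1], 3.0, 0.3, (64, 64, 64), seed=0)
    fab = analyze_fabric(v, n_orientations=129, n_points=300, seed=0)
    assert fab.DA > 1.2
    assert alignment_angle(fab, [0, 0, 1]) <= 10.0


def test_rotation_equivariance_quarter_turn():
    """Rotating the volume 90 degrees about z rotates the primary axis with it."""
    axis = np.array([np.sin(np.pi / 6), 0.0, np.cos(np.pi / 6)])
    v = generate_trabecular_volume(axis, 3.0, 0.3, (48, 48, 48), seed=2)
    fab = analyze_fabric(v, n_orientations=257, n_points=400, seed=0)
    # rot90 on (y, x) axes maps world (x, y) -> (-y, x)
    v_rot = ImageVolume(np.rot90(v.voxels, k=1, axes=(1, 2)), spacing=v.spacing)
    fab_rot = analyze_fabric(v_rot, n_orientations=257, n_points=400, seed=0)
    Rz = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    expected = Rz @ fab.primary_axis
    cosang = abs(fab_rot.primary_axis @ expected)
    assert np.degrees(np.arccos(np.clip(cosang, 0, 1))) <= 2.0


def test_da_monotone_in_generator_anisotropy():
    """Expected DA never decreases as the generator ratio increases."""
    means = []
    for ratio in (1.0, 2.0, 3.0):
        das = []
        for seed in range(3):
            v = generate_trabecular_volume([0, 0, 1], ratio, 0.3, (48, 48, 48), seed=seed)
            das.append(analyze_fabric(v, n_orientations=65, n_points=250, seed=seed).DA)
        means.append(np.mean(das))
    assert means[0] < means[1] < means[2]
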