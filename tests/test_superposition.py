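"""Kabsch superposition against constructed transforms and a grid oracle."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from eeftraj.io_model import Trajectory
from eeftraj.superposition import (
    DegenerateGeometryError,
    apply_transform,
    kabsch_superpose,
    rmsd,
    rmsd_series,
    rmsd_series_by_ss,
)

from conftest import random_rotation, static_trajectory


def brute_force_min_rmsd(mobile, reference):
    """Independent oracle: Euler-grid scan + simplex refinement.

    Optimal translation for any fixed rotation aligns the centroids, so the
    search is over rotations only.  Never touches the SVD solution path.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(euler_deg):
        rot = Rotation.from_euler("zyx", euler_deg, degrees=True).as_matrix()
        return np.sqrt(np.mean(np.sum((mob @ rot.T - ref) ** 2, axis=1)))

    grid = [
        (z, y, x)
        for z in range(0, 360, 30)
        for y in range(-90, 91, 30)
        for x in range(0, 360, 30)
    ]
    starts = sorted(grid, key=cost)[:3]
    best = np.inf
    for s in starts:
        res = minimize(cost, s, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-12})
        best = min(best, res.fun)
    return best


def test_self_superposition_is_identity():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(6, 3))
    res = kabsch_superpose(pts, pts)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(res.translation, 0.0, atol=1e-12)
    assert res.rmsd_after == pytest.approx(0.0, abs=1e-12)


def test_known_rotation_translation_recovered():
    """90° about z plus (5,0,0): fitted RMSD is 0 and the transform inverts."""
    rng = np.random.default_rng(1)
    ref = rng.normal(size=(8, 3))
    rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    mobile = ref @ rot90.T + np.array([5.0, 0.0, 0.0])
    res = kabsch_superpose(mobile, ref)
    assert res.rmsd_after == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(res.rotation @ rot90, np.eye(3), atol=1e-10)
    assert np.allclose(apply_transform(mobile, res), ref, atol=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_kabsch_matches_rotation_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    ref = rng.normal(size=(5, 3)) * 4.0
    mobile = ref + rng.normal(scale=0.5, size=ref.shape)
    mobile = mobile @ random_rotation(rng).T + rng.normal(size=3)
    res = kabsch_superpose(mobile, ref)
    oracle = brute_force_min_rmsd(mobile, ref)
    assert abs(res.rmsd_after - oracle) <= 1e-3


def test_rotation_is_always_proper():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        res = kabsch_superpose(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(res.rotation.T @ res.rotation, np.eye(3), atol=1e-10)


def test_fitted_rmsd_never_exceeds_unfitted():
    rng = np.random.default_rng(7)
    for _ in range(10):
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        assert kabsch_superpose(a, b).rmsd_after <= rmsd(a, b) + 1e-12


def test_superposition_rmsd_rigid_invariance():
    rng = np.random.default_rng(11)
    a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
    base = kabsch_superpose(a, b).rmsd_after
    moved = a @ random_rotation(rng).T + rng.normal(size=3)
    assert kabsch_superpose(moved, b).rmsd_after == pytest.approx(base, abs=1e-8)


def test_degenerate_inputs_raise():
    with pytest.raises(DegenerateGeometryError, match="≥3"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(DegenerateGeometryError, match="collinear"):
        kabsch_superpose(line, line)


def test_rmsd_values_and_symmetry():
    a = np.zeros((3, 3))
    b = np.array([[1.0, 0, 0], [0, 2.0, 0], [0, 0, 2.0]])
    assert rmsd(a, a) == 0.0
    assert rmsd(a, b) == pytest.approx(np.sqrt(3.0))
    assert rmsd(a, b) == rmsd(b, a)
    assert rmsd(np.zeros((1, 3)), np.array([[0, 0, 2.0]])) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        rmsd(a, b[:2])


def test_rmsd_series_static_and_rigid_motion():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(10, 3)) * 5
    static = static_trajectory(base, n_frames=4)
    idx = np.arange(10)
    assert np.allclose(rmsd_series(static, 0, idx, idx), 0.0)
    # pure rigid motion: fitted RMSD stays at zero
    frames = [base]
    for k in range(1, 5):
        frames.append(base @ random_rotation(rng).T + rng.normal(size=3))
    traj = Trajectory(np.array(frames), 25.0 * np.arange(5))
    series = rmsd_series(traj, 0, idx, idx)
    assert np.max(series) <= 1e-6


def test_rmsd_series_by_ss_ordering(dimer, ca_idx, ambient_run):
    """Flexible (loop/tail) residues out-fluctuate the rigid core."""
    traj, _ = ambient_run
    series = rmsd_series_by_ss(traj, dimer, 0, ca_idx)
    rigid, other = series["helix_sheet"], series["other"]
    assert rigid is not None and other is not None
    assert rigid[0] == pytest.approx(0.0, abs=1e-9)
    burn = 10
    assert np.all(other[burn:] > rigid[burn:])


def test_rmsd_series_by_ss_all_helix_partition_absent():
    rng = np.random.default_rng(3)
    from conftest import toy_structure

    s = toy_structure(rng.normal(size=(6, 3)) * 4, ss="helix")
    traj = static_trajectory(s.coords, 3)
    series = rmsd_series_by_ss(traj, s, 0, np.arange(6))
    assert series["other"] is None
    assert series["helix_sheet"] is not None
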