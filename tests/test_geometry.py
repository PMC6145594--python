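"""Axis fits, bend angle, elongation, distances, mean structure, MSD."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from eeftraj.geometry import (
    SampleDistribution,
    bend_angle,
    bend_angle_series,
    distance_series,
    elongation,
    elongation_series,
    fit_axis,
    mean_structure,
    msd,
)
from eeftraj.io_model import SelectionSpec, Trajectory, resolve_selection
from eeftraj.superposition import DegenerateGeometryError
from eeftraj.synthetic import generate_trajectory

from conftest import random_rotation, static_trajectory, toy_structure


# -- fit_axis ---------------------------------------------------------------


def brute_force_axis_angle(points, found_direction):
    """Grid + simplex minimisation of perpendicular distances, independent of SVD."""
    pts = points - points.mean(axis=0)

    def cost(angles):
        th, ph = angles
        d = np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        perp = pts - np.outer(pts @ d, d)
        return np.sum(perp**2)

    grid = [
        (th, ph)
        for th in np.linspace(0, np.pi, 19)
        for ph in np.linspace(0, 2 * np.pi, 37)
    ]
    start = min(grid, key=cost)
    res = minimize(cost, start, method="Nelder-Mead", options={"xatol": 1e-9})
    th, ph = res.x
    d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    cosang = abs(d @ found_direction)
    return np.degrees(np.arccos(np.clip(cosang, -1, 1)))


def test_collinear_points_give_exact_axis():
    pts = np.array([[0.0, 0, 0], [0, 0, 1.5], [0, 0, 3.0], [0, 0, 4.5]])
    line = fit_axis(pts)
    assert abs(abs(line.direction[2]) - 1.0) < 1e-12
    assert np.allclose(line.point, pts.mean(axis=0))
    # sign follows input ordering
    assert line.direction[2] > 0
    assert fit_axis(pts[::-1]).direction[2] < 0


def test_ideal_helix_axis_within_two_degrees():
    k = np.arange(20)
    ang = np.radians(100.0 * k)
    helix = np.stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * k], axis=1)
    line = fit_axis(helix)
    tilt = np.degrees(np.arccos(abs(line.direction[2])))
    assert tilt < 2.0


def test_fit_axis_matches_grid_oracle():
    rng = np.random.default_rng(0)
    for _ in range(5):
        pts = rng.normal(size=(3, 3)) * np.array([4.0, 1.0, 0.5])
        line = fit_axis(pts)
        assert brute_force_axis_angle(pts, line.direction) <= 0.5


def test_fit_axis_degenerate_inputs():
    with pytest.raises(DegenerateGeometryError, match="coincident"):
        fit_axis(np.zeros((3, 3)))
    # isotropic cloud: regular tetrahedron has no dominant axis
    tetra = np.array(
        [[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
    )
    with pytest.raises(DegenerateGeometryError, match="dominant axis"):
        fit_axis(tetra)


# -- bend angle -------------------------------------------------------------


def test_bend_angle_of_reference_is_zero(dimer, h7_idx):
    a, b = h7_idx
    for mode in ("combined", "beta_only"):
        assert bend_angle(dimer.coords, dimer.coords, a, b, mode) == pytest.approx(
            0.0, abs=1e-6
        )


def test_constructed_beta_rotation_recovered_in_beta_only_mode(dimer, h7_idx):
    """Rotating the β monomer 10° about a perpendicular axis reads back as 10°."""
    a, b = h7_idx
    beta = (dimer.atoms["monomer"] == "beta").to_numpy()
    study = dimer.coords.copy()
    pivot = study[b].mean(axis=0)
    rot = Rotation.from_euler("y", 10.0, degrees=True).as_matrix()
    study[beta] = (study[beta] - pivot) @ rot.T + pivot
    measured = bend_angle(study, dimer.coords, a, b, "beta_only")
    assert measured == pytest.approx(10.0, abs=0.2)
    # the symmetric (inverse) rotation folds to the same line angle
    study_inv = dimer.coords.copy()
    study_inv[beta] = (study_inv[beta] - pivot) @ rot + pivot
    measured_inv = bend_angle(study_inv, dimer.coords, a, b, "beta_only")
    assert measured_inv == pytest.approx(measured, abs=0.2)


def test_bend_angle_invariant_under_rigid_transform_of_study(dimer, h7_idx):
    a, b = h7_idx
    rng = np.random.default_rng(8)
    beta = (dimer.atoms["monomer"] == "beta").to_numpy()
    study = dimer.coords.copy()
    rot = Rotation.from_euler("y", 7.0, degrees=True).as_matrix()
    pivot = study[b].mean(axis=0)
    study[beta] = (study[beta] - pivot) @ rot.T + pivot
    base = bend_angle(study, dimer.coords, a, b, "combined")
    moved = study @ random_rotation(rng).T + rng.normal(size=3) * 20
    assert bend_angle(moved, dimer.coords, a, b, "combined") == pytest.approx(
        base, abs=1e-6
    )


def test_noiseless_zero_bend_series(dimer, tiny_params, h7_idx):
    p = dataclasses.replace(
        tiny_params,
        bend_mean=0.0,
        bend_sd=0.0,
        elong_sd=0.0,
        ou_sigma_core=0.0,
        ou_sigma_loop=0.0,
        diffusion_coefficient=0.0,
        n_frames=4,
    )
    traj, _ = generate_trajectory(dimer, p)
    a, b = h7_idx
    dist = bend_angle_series(traj, dimer.coords, a, b, "combined")
    assert np.allclose(dist.samples, 0.0, atol=1e-6)


# -- elongation -------------------------------------------------------------


def test_elongation_of_two_point_sets():
    coords = np.array([[0.0, 0, 0], [0, 40.0, 0]])
    s = toy_structure(coords, monomer=["alpha", "beta"])
    assert elongation(coords, np.array([0]), np.array([1]), s.masses) == pytest.approx(
        40.0
    )


def test_elongation_rigid_invariance(dimer, helix_idx):
    ha, hb = helix_idx
    rng = np.random.default_rng(9)
    base = elongation(dimer.coords, ha, hb, dimer.masses)
    moved = dimer.coords @ random_rotation(rng).T + rng.normal(size=3) * 15
    assert elongation(moved, ha, hb, dimer.masses) == pytest.approx(base, abs=1e-9)


def test_noiseless_elongation_equals_parameter(dimer, tiny_params, helix_idx):
    p = dataclasses.replace(
        tiny_params,
        bend_sd=0.0,
        elong_mean=47.5,
        elong_sd=0.0,
        ou_sigma_core=0.0,
        ou_sigma_loop=0.0,
        diffusion_coefficient=0.0,
        n_frames=3,
    )
    traj, _ = generate_trajectory(dimer, p)
    ha, hb = helix_idx
    dist = elongation_series(traj, ha, hb, dimer.masses)
    assert np.allclose(dist.samples, 47.5, atol=1e-9)


# -- distances & distributions ---------------------------------------------


def test_static_probe_distance_and_quartiles():
    coords = np.array([[0.0, 0, 0], [12.0, 0, 0]])
    s = toy_structure(coords)
    traj = static_trajectory(coords, 6)
    dist = distance_series(traj, s, np.array([0]), np.array([1]))
    assert np.allclose(dist.samples, 12.0)
    assert dist.quartiles == pytest.approx((12.0, 12.0, 12.0))


def test_distance_series_deterministic_for_fixed_seed(dimer, tiny_params):
    probe = np.array([0])
    target = np.array([dimer.n_atoms - 1])
    t1, _ = generate_trajectory(dimer, tiny_params)
    t2, _ = generate_trajectory(dimer, tiny_params)
    d1 = distance_series(t1, dimer, probe, target)
    d2 = distance_series(t2, dimer, probe, target)
    assert np.array_equal(d1.samples, d2.samples)


def test_quartiles_are_order_statistics_and_histogram_normalised():
    rng = np.random.default_rng(10)
    samples = rng.normal(5, 2, size=500)
    d1 = SampleDistribution(samples)
    d2 = SampleDistribution(rng.permutation(samples))
    assert d1.quartiles == d2.quartiles
    assert d1.mean == pytest.approx(d2.mean)
    edges, dens = d1.histogram(bins=30)
    assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)
    q1, med, q3 = d1.quartiles
    assert q1 <= med <= q3


# -- mean structure ---------------------------------------------------------


def test_mean_structure_static_equals_frame(dimer):
    traj = static_trajectory(dimer.coords, 4)
    mean = mean_structure(traj, np.arange(dimer.n_atoms))
    assert np.allclose(mean, dimer.coords, atol=1e-12)


def test_mean_structure_two_symmetric_frames_gives_midpoint():
    rng = np.random.default_rng(12)
    base = rng.normal(size=(8, 3)) * 5
    delta = np.zeros_like(base)
    delta[3] = [1.0, -0.5, 0.25]  # one atom oscillates about the midpoint
    frames = np.array([base + delta, base - delta])
    traj = Trajectory(frames, np.array([0.0, 25.0]))
    mean = mean_structure(traj, np.array([0, 1, 2, 4, 5, 6, 7]))
    assert np.allclose(mean, base, atol=1e-9)


# -- MSD --------------------------------------------------------------------


def test_msd_static_zero(dimer, ca_idx):
    traj = static_trajectory(dimer.coords, 10)
    _, vals = msd(traj, ca_idx, dimer.masses)
    assert np.allclose(vals, 0.0)


def test_msd_ballistic_closed_form(dimer, ca_idx):
    """Uniform drift at v: MSD(τ) = (vτ)² exactly, sliding origins or not."""
    v = np.array([0.02, 0.0, -0.01])  # Å/ps
    n = 40
    times = 25.0 * np.arange(n)
    frames = dimer.coords[None] + times[:, None, None] * v[None, None, :]
    traj = Trajectory(frames, times)
    speed2 = v @ v
    for sliding in (True, False):
        lag, vals = msd(traj, ca_idx, dimer.masses, sliding=sliding)
        assert np.allclose(vals, speed2 * lag**2, rtol=1e-10)
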