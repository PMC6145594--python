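"""Dipole identities, field axes, unit conversion, salt-bridge detection."""

import itertools

import numpy as np
import pytest

from eeftraj.electrostatics import (
    ACIDIC_O_NAMES,
    BASIC_N_NAMES,
    DEBYE_PER_E_ANGSTROM,
    FieldSpec,
    compute_axes,
    convert_field,
    dipole_moment,
    dipole_series,
    salt_bridges,
)
from eeftraj.synthetic import build_salt_bridge_fixture

from conftest import random_rotation, static_trajectory, toy_structure


def test_unit_neutral_pair_is_one_debye_constant():
    """±1e separated by 1 Å along x → 4.80321 D along +x, any reference."""
    coords = np.array([[0.5, 0, 0], [-0.5, 0, 0]])
    charges = np.array([1.0, -1.0])
    masses = np.array([12.0, 12.0])
    for ref in ("com", "origin", "charge_centroid"):
        rec = dipole_moment(coords, charges, masses, ref)
        assert rec.magnitude_debye == pytest.approx(DEBYE_PER_E_ANGSTROM, rel=1e-9)
        assert np.allclose(rec.vector, [1.0, 0.0, 0.0], atol=1e-12)


def test_zero_charges_zero_dipole():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(6, 3))
    rec = dipole_moment(coords, np.zeros(6), np.ones(6))
    assert np.allclose(rec.vector, 0.0)


def test_neutral_system_translation_invariance():
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(8, 3)) * 5
    charges = rng.normal(size=8)
    charges -= charges.mean()  # exactly neutral
    masses = np.ones(8)
    p0 = dipole_moment(coords, charges, masses, "origin").vector
    p1 = dipole_moment(coords + [100.0, -50.0, 3.0], charges, masses, "origin").vector
    assert np.max(np.abs(p0 - p1)) <= 1e-10


def test_net_charge_reference_shift_identity():
    """Two reference points Δr apart differ by exactly q_net · Δr."""
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(5, 3)) * 4
    charges = rng.normal(size=5) + 0.5
    q_net = charges.sum()
    masses = np.ones(5)
    p_origin = dipole_moment(coords, charges, masses, "origin").vector
    p_com = dipole_moment(coords, charges, masses, "com").vector
    r_com = masses @ coords / masses.sum()
    assert np.allclose(p_origin - p_com, q_net * r_com, rtol=1e-9)


def test_dipole_magnitude_rotation_covariance():
    rng = np.random.default_rng(3)
    coords = rng.normal(size=(7, 3)) * 3
    charges = rng.normal(size=7)
    masses = np.ones(7)
    rot = random_rotation(rng)
    p = dipole_moment(coords, charges, masses, "com").vector
    p_rot = dipole_moment(coords @ rot.T, charges, masses, "com").vector
    assert np.linalg.norm(p_rot) == pytest.approx(np.linalg.norm(p), rel=1e-10)
    assert np.allclose(p_rot, p @ rot.T, atol=1e-9)


def test_dipole_series_static_is_constant(dimer):
    traj = static_trajectory(dimer.coords, 4)
    recs = dipole_series(traj, dimer.charges, dimer.masses)
    mags = [r.magnitude_debye for r in recs]
    assert np.ptp(mags) == 0.0


def test_compute_axes_constructed_dimer():
    # β COM at origin, α COM at +40z; a ±1e pair inside β gives a +y dipole
    coords = np.array(
        [[0.0, 1.0, 0], [0, -1.0, 0], [0, 1.0, 40.0], [0, -1.0, 40.0]]
    )
    s = toy_structure(
        coords,
        monomer=["beta", "beta", "alpha", "alpha"],
        charges=[1.0, -1.0, 0.0, 0.0],
    )
    transverse, longitudinal = compute_axes(s)
    assert np.allclose(longitudinal, [0, 0, 1], atol=1e-12)
    assert np.allclose(transverse, [0, 1, 0], atol=1e-12)


def test_field_spec_negative_rule_is_exact_negation(dimer):
    pos = FieldSpec("transverse_pos", 100.0, (0.0, 1000.0)).direction(dimer)
    neg = FieldSpec("transverse_neg", 100.0, (0.0, 1000.0)).direction(dimer)
    assert np.array_equal(neg, -pos)


def test_convert_field_values_and_round_trip():
    assert convert_field(750.0, "kV/cm", "V/A") == pytest.approx(0.0075, rel=1e-12)
    assert convert_field(0.0, "kV/cm", "V/m") == 0.0
    x = 123.456
    back = convert_field(convert_field(x, "kV/cm", "V/m"), "V/m", "kV/cm")
    assert back == pytest.approx(x, rel=1e-12)
    with pytest.raises(ValueError, match="unknown field unit"):
        convert_field(1.0, "kV/cm", "furlong")


# -- salt bridges -----------------------------------------------------------


def _bridge_pair(distance):
    coords = np.array(
        [[0.0, 0, 0], [4.0, 0, 0], [30.0, 0, 0], [4.0 + distance, 0, 0]]
    )
    return toy_structure(
        coords,
        atom_names=["CA", "NZ", "CA", "OD1"],
        charges=[0.0, 1.0, 0.0, -1.0],
    )


def test_bridge_inside_cutoff_detected():
    s = _bridge_pair(3.1)
    out = salt_bridges(s.coords, s, cutoff=3.2)
    assert out == [(("alpha", 4), ("alpha", 2), pytest.approx(3.1))]


def test_bridge_outside_cutoff_excluded():
    s = _bridge_pair(3.3)
    assert salt_bridges(s.coords, s, cutoff=3.2) == []


def test_cutoff_comparison_is_inclusive():
    s = _bridge_pair(3.2)
    assert len(salt_bridges(s.coords, s, cutoff=3.2)) == 1


def test_planted_tubulin_analog_pairs_recovered_exactly():
    fix = build_salt_bridge_fixture()
    found = {(a, b) for a, b, _ in salt_bridges(fix.coords, fix, 3.2)}
    assert found == {
        (("alpha", 447), ("alpha", 311)),
        (("beta", 445), ("beta", 292)),
    }


def brute_force_bridges(frame, structure, cutoff, basic_names):
    """All-pairs O(N²) scan over atoms, independent of the library grouping."""
    df = structure.atoms
    best = {}
    for i, j in itertools.product(range(len(df)), repeat=2):
        if df.iloc[i]["atom_name"] not in ACIDIC_O_NAMES:
            continue
        if df.iloc[j]["atom_name"] not in basic_names:
            continue
        ra = (df.iloc[i]["monomer"], int(df.iloc[i]["residue_index"]))
        rb = (df.iloc[j]["monomer"], int(df.iloc[j]["residue_index"]))
        if ra == rb:
            continue
        d = float(np.linalg.norm(frame[i] - frame[j]))
        key = (ra, rb)
        if key not in best or d < best[key]:
            best[key] = d
    return sorted((a, b, d) for (a, b), d in best.items() if d <= cutoff)


def test_detection_matches_brute_force_scan(dimer):
    got = salt_bridges(dimer.coords, dimer, cutoff=6.0, strict=False)
    expected = brute_force_bridges(dimer.coords, dimer, 6.0, BASIC_N_NAMES)
    assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in expected]
    assert np.allclose([d for *_, d in got], [d for *_, d in expected])


def test_strict_mode_requires_sidechain_atoms():
    s = toy_structure(np.random.default_rng(5).normal(size=(4, 3)))
    with pytest.raises(ValueError, match="lacks"):
        salt_bridges(s.coords, s, 3.2, strict=True)
    assert salt_bridges(s.coords, s, 3.2, strict=False) == []


def test_histidine_excluded_by_default():
    coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [30.0, 0, 0], [30.0, 3.0, 0]])
    s = toy_structure(
        coords,
        atom_names=["OD1", "ND1", "CA", "CA"],
        charges=[-1.0, 0.0, 0.0, 0.0],
    )
    assert salt_bridges(s.coords, s, 3.2, strict=False) == []
    assert len(salt_bridges(s.coords, s, 3.2, include_histidine=True)) == 1
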