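"""Shared fixtures: small synthetic dimers and hand-built toy structures."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from eeftraj.io_model import ATOM_COLUMNS, AnnotatedStructure, SelectionSpec, Trajectory, resolve_selection
from eeftraj.synthetic import build_synthetic_dimer, generate_trajectory, preset


@pytest.fixture(scope="session")
def tiny_params():
    return preset("ambient", 0.0, n_frames=50, seed=3)


@pytest.fixture(scope="session")
def dimer(tiny_params):
    return build_synthetic_dimer(tiny_params)


@pytest.fixture(scope="session")
def ambient_run(dimer, tiny_params):
    return generate_trajectory(dimer, tiny_params)


@pytest.fixture(scope="session")
def ca_idx(dimer):
    return resolve_selection(SelectionSpec("ca", atom_names=["CA"]), dimer)


@pytest.fixture(scope="session")
def h7_idx(dimer):
    a = resolve_selection(SelectionSpec("a", monomer="alpha", region="H7"), dimer)
    b = resolve_selection(SelectionSpec("b", monomer="beta", region="H7"), dimer)
    return a, b


@pytest.fixture(scope="session")
def helix_idx(dimer):
    a = resolve_selection(SelectionSpec("a", monomer="alpha", ss_class="helix"), dimer)
    b = resolve_selection(SelectionSpec("b", monomer="beta", ss_class="helix"), dimer)
    return a, b


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    """The canonical tiny fixture set (17 conditions, 50 frames each)."""
    from eeftraj.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(out, scale="tiny", seed=1234)
    return out


def toy_structure(
    coords,
    monomer="alpha",
    atom_names=None,
    ss="coil",
    charges=None,
    residue_index=None,
    region="",
) -> AnnotatedStructure:
    """One-atom-per-residue structure for hand-built geometry tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    monomers = [monomer] * n if isinstance(monomer, str) else list(monomer)
    names = atom_names or ["CA"] * n
    sss = [ss] * n if isinstance(ss, str) else list(ss)
    qs = charges if charges is not None else [0.0] * n
    # residue numbering restarts per monomer to honour the contiguity contract
    if residue_index is None:
        residue_index, counter = [], {}
        for m in monomers:
            counter[m] = counter.get(m, 0) + 1
            residue_index.append(counter[m])
    regions = [region] * n if isinstance(region, str) else list(region)
    rows = [
        (
            i + 1,
            names[i],
            names[i][0],
            residue_index[i],
            monomers[i],
            regions[i],
            sss[i],
            qs[i],
            12.011,
            "ALA",
        )
        for i in range(n)
    ]
    return AnnotatedStructure(pd.DataFrame(rows, columns=ATOM_COLUMNS), coords)


def static_trajectory(coords, n_frames=5, dt=25.0) -> Trajectory:
    frames = np.repeat(np.asarray(coords, dtype=float)[None], n_frames, axis=0)
    return Trajectory(frames, dt * np.arange(n_frames), dt)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
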