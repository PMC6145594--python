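"""Fixed-charge electrostatics observables and field bookkeeping.

The dipole moment is computed purely from the distribution of fixed partial
charges, p = Σ qᵢ(rᵢ − r_ref).  For a globally neutral system the choice of
reference point is immaterial; the heterodimer carries a net charge, so the
reference (system COM by default) is recorded on every output and two
reference choices differ exactly by q_net·Δr_ref.

Field axes follow the convention of the simulation protocol being analysed:
the positive transverse direction is the dimer's dipole at the reference
frame, and the positive longitudinal direction runs from the β to the α
monomer's centre of mass; negative directions are exact negations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import AnnotatedStructure, Trajectory

__all__ = [
    "FieldSpec",
    "DipoleRecord",
    "DEBYE_PER_E_ANGSTROM",
    "dipole_moment",
    "dipole_series",
    "compute_axes",
    "convert_field",
    "salt_bridges",
]

#: 1 e·Å in Debye
DEBYE_PER_E_ANGSTROM = 4.80321

DIRECTION_RULES = (
    "transverse_pos",
    "transverse_neg",
    "longitudinal_pos",
    "longitudinal_neg",
    "explicit_vector",
)

REFERENCE_POINTS = ("com", "origin", "charge_centroid")

#: acidic side-chain oxygens and basic side-chain nitrogens for salt bridges
ACIDIC_O_NAMES = frozenset(["OD1", "OD2", "OE1", "OE2", "OXT"])
BASIC_N_NAMES = frozenset(["NZ", "NE", "NH1", "NH2"])
HISTIDINE_N_NAMES = frozenset(["ND1", "NE2"])


@dataclass
class FieldSpec:
    """External-field condition: direction rule, magnitude, on-window.

    ``magnitude`` is in kV/cm; ``window`` is ``(t_on, t_off)`` in ps with the
    field active on the half-open interval [t_on, t_off).  When
    ``direction_rule`` is ``explicit_vector`` the stored vector is
    unit-normalised.
    """

    direction_rule: str
    magnitude: float
    window: tuple[float, float]
    vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.direction_rule not in DIRECTION_RULES:
            raise ValueError(f"unknown direction rule {self.direction_rule!r}")
        if self.magnitude < 0:
            raise ValueError("field magnitude must be ≥ 0")
        t_on, t_off = self.window
        if not t_on < t_off:
            raise ValueError(f"field window ({t_on}, {t_off}) requires t_on < t_off")
        if self.vector is not None:
            v = np.asarray(self.vector, dtype=float)
            norm = np.linalg.norm(v)
            if norm == 0:
                raise ValueError("explicit field vector must be non-zero")
            self.vector = v / norm
        elif self.direction_rule == "explicit_vector":
            raise ValueError("explicit_vector rule requires a vector")

    def is_on(self, time_ps: float) -> bool:
        return self.window[0] <= time_ps < self.window[1]

    def direction(self, structure: AnnotatedStructure) -> np.ndarray:
        """Resolve the rule to a unit vector against a reference structure."""
        if self.vector is not None:
            return self.vector
        transverse, longitudinal = compute_axes(structure)
        return {
            "transverse_pos": transverse,
            "transverse_neg": -transverse,
            "longitudinal_pos": longitudinal,
            "longitudinal_neg": -longitudinal,
        }[self.direction_rule]


@dataclass(frozen=True)
class DipoleRecord:
    """Dipole vector (e·Å) at one time point, with its reference convention."""

    time: float
    vector: np.ndarray
    reference_point: str

    @property
    def magnitude_debye(self) -> float:
        return float(np.linalg.norm(self.vector) * DEBYE_PER_E_ANGSTROM)


def _reference(coords, charges, masses, reference_point) -> np.ndarray:
    if reference_point == "origin":
        return np.zeros(3)
    if reference_point == "com":
        return masses @ coords / masses.sum()
    if reference_point == "charge_centroid":
        absq = np.abs(charges)
        if absq.sum() == 0:
            raise ValueError("charge centroid undefined for an uncharged system")
        return absq @ coords / absq.sum()
    raise ValueError(f"unknown reference point {reference_point!r}")


def dipole_moment(
    frame: np.ndarray,
    charges: np.ndarray,
    masses: np.ndarray,
    reference_point: str = "com",
    time: float = 0.0,
) -> DipoleRecord:
    """Fixed-charge dipole p = Σ qᵢ(rᵢ − r_ref) in e·Å."""
    frame = np.asarray(frame, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if np.any(~np.isfinite(charges)):
        bad = np.nonzero(~np.isfinite(charges))[0]
        raise ValueError(f"missing charges for atoms {bad[:5].tolist()}")
    r_ref = _reference(frame, charges, np.asarray(masses, dtype=float), reference_point)
    vec = charges @ (frame - r_ref)
    return DipoleRecord(time=time, vector=vec, reference_point=reference_point)


def dipole_series(
    traj: Trajectory,
    charges: np.ndarray,
    masses: np.ndarray,
    reference_point: str = "com",
    window: tuple[float, float] | None = None,
) -> list[DipoleRecord]:
    idx = traj.window_frames(window)
    return [
        dipole_moment(
            traj.coords[i], charges, masses, reference_point, time=traj.times[i]
        )
        for i in idx
    ]


def compute_axes(structure: AnnotatedStructure) -> tuple[np.ndarray, np.ndarray]:
    """(transverse, longitudinal) unit axes of a reference structure.

    Transverse: direction of the fixed-charge dipole about the system COM.
    Longitudinal: from the β to the α monomer COM.
    """
    dip = dipole_moment(
        structure.coords, structure.charges, structure.masses, "com"
    ).vector
    norm = np.linalg.norm(dip)
    if norm < 1e-9:
        raise ValueError("zero dipole: transverse axis undefined")
    df = structure.atoms
    coms = {}
    for monomer in ("alpha", "beta"):
        mask = (df["monomer"] == monomer).to_numpy()
        if not mask.any():
            raise ValueError(f"monomer {monomer!r} absent; axes undefined")
        m = structure.masses[mask]
        coms[monomer] = m @ structure.coords[mask] / m.sum()
    longitudinal = coms["alpha"] - coms["beta"]
    return dip / norm, longitudinal / np.linalg.norm(longitudinal)


# value of 1 kV/cm expressed in each unit: 1 kV/cm = 1e3 V / 1e8 Å = 1e5 V/m
_FIELD_UNITS = {"kV/cm": 1.0, "V/A": 1e-5, "V/Å": 1e-5, "V/m": 1e5}


def convert_field(magnitude: float, from_unit: str, to_unit: str) -> float:
    """Exact linear conversion between kV/cm, V/Å and V/m."""
    for unit in (from_unit, to_unit):
        if unit not in _FIELD_UNITS:
            raise ValueError(f"unknown field unit {unit!r}")
    in_kv_cm = magnitude / _FIELD_UNITS[from_unit]
    return in_kv_cm * _FIELD_UNITS[to_unit]


def salt_bridges(
    frame: np.ndarray,
    structure: AnnotatedStructure,
    cutoff: float = 3.2,
    include_histidine: bool = False,
    strict: bool = True,
) -> list[tuple[tuple[str, int], tuple[str, int], float]]:
    """Salt bridges in one frame: acidic-O within ``cutoff`` of basic-N.

    A residue pair is reported once, with the minimum O–N distance over all
    its acidic-oxygen / basic-nitrogen atom pairs; the comparison is
    inclusive (≤ cutoff).  Histidine nitrogens are excluded by default (the
    delta-protonated tautomer is neutral); ``include_histidine`` adds them.
    In strict mode a structure with no recognisable acidic oxygens or basic
    nitrogens is an error; in lenient mode the result is simply empty.
    """
    df = structure.atoms
    basic_names = BASIC_N_NAMES | (HISTIDINE_N_NAMES if include_histidine else set())
    acid_mask = df["atom_name"].isin(ACIDIC_O_NAMES).to_numpy()
    base_mask = df["atom_name"].isin(basic_names).to_numpy()
    if not acid_mask.any() or not base_mask.any():
        if strict:
            raise ValueError(
                "structure lacks acidic-oxygen and/or basic-nitrogen atom names"
            )
        return []
    keys = list(zip(df["monomer"], df["residue_index"].astype(int)))
    best: dict[tuple, float] = {}
    acid_idx = np.nonzero(acid_mask)[0]
    base_idx = np.nonzero(base_mask)[0]
    diffs = frame[acid_idx][:, None, :] - frame[base_idx][None, :, :]
    dists = np.linalg.norm(diffs, axis=2)
    for i, ai in enumerate(acid_idx):
        for j, bi in enumerate(base_idx):
            acid_res, base_res = keys[ai], keys[bi]
            if acid_res == base_res:
                continue  # intra-residue contacts are not bridges
            pair = (acid_res, base_res)
            d = float(dists[i, j])
            if pair not in best or d < best[pair]:
                best[pair] = d
    return sorted(
        [(a, b, d) for (a, b), d in best.items() if d <= cutoff],
        key=lambda t: (t[0], t[1]),
    )
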