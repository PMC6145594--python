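"""Per-residue fluctuations: RMSF, ΔRMSF, and secondary-structure counts.

RMSF is computed about the iterated mean structure: frames are first fitted
to the plain frame average, the average is recomputed from the fitted
frames, and frames are fitted once more to that refined mean.  One
refinement pass removes the rigid-body inflation a raw average would leave
behind.  ΔRMSF = RMSF_field − RMSF_ambient, so a positive value means the
field increased that residue's fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AnnotatedStructure, Trajectory
from .superposition import apply_transform, kabsch_superpose

__all__ = ["ResidueSeries", "rmsf", "delta_rmsf", "ss_counts"]


@dataclass
class ResidueSeries:
    """One scalar per residue, keyed by ``(monomer, residue_index)``.

    The common output contract of RMSF, ΔRMSF and final-displacement stages.
    ``values`` is a pandas Series with a two-level index.
    """

    values: pd.Series
    label: str = ""
    units: str = "A"

    def __post_init__(self) -> None:
        if self.values.index.nlevels != 2:
            raise ValueError("ResidueSeries requires a (monomer, residue_index) index")
        self.values.index = self.values.index.set_names(
            ["monomer", "residue_index"]
        )

    def to_frame(self, column: str) -> pd.DataFrame:
        df = self.values.rename(column).reset_index()
        return df

    def __len__(self) -> int:
        return len(self.values)


def _residue_groups(structure: AnnotatedStructure, atom_idx: np.ndarray):
    """Group an atom index array by residue, preserving residue order."""
    df = structure.atoms.iloc[atom_idx]
    keys = list(zip(df["monomer"], df["residue_index"].astype(int)))
    groups: dict[tuple[str, int], list[int]] = {}
    for pos, key in zip(atom_idx, keys):
        groups.setdefault(key, []).append(int(pos))
    return groups


def superpose_frames(
    frames: np.ndarray, fit_idx: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Fit every frame onto ``reference`` using the fit atoms; returns copies."""
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        res = kabsch_superpose(frame[fit_idx], reference[fit_idx])
        out[i] = apply_transform(frame, res)
    return out


def iterated_mean_frames(
    frames: np.ndarray, fit_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-pass iterated alignment: returns (aligned frames, mean structure)."""
    mean0 = frames.mean(axis=0)
    aligned = superpose_frames(frames, fit_idx, mean0)
    mean1 = aligned.mean(axis=0)
    aligned = superpose_frames(frames, fit_idx, mean1)
    return aligned, aligned.mean(axis=0)


def rmsf(
    traj: Trajectory,
    structure: AnnotatedStructure,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray,
    window: tuple[float, float] | None = None,
    label: str = "",
) -> ResidueSeries:
    """Per-residue RMSF over a time window.

    RMSFᵢ = √⟨|xᵢ − ⟨xᵢ⟩|²⟩ with the average over window frames (and over a
    residue's atoms when the measure selection has more than one atom per
    residue), after superposition on the iterated window-mean structure.
    """
    idx = traj.window_frames(window)
    if idx.size < 2:
        raise ValueError("RMSF window must contain at least 2 frames")
    fit_idx = np.asarray(fit_selection, dtype=int)
    meas_idx = np.asarray(measure_selection, dtype=int)
    aligned, mean = iterated_mean_frames(traj.coords[idx], fit_idx)
    sq_dev = np.sum((aligned - mean) ** 2, axis=2).mean(axis=0)  # per atom
    groups = _residue_groups(structure, meas_idx)
    keys, vals = [], []
    for key, atoms in groups.items():
        keys.append(key)
        vals.append(float(np.sqrt(np.mean(sq_dev[atoms]))))
    series = pd.Series(
        vals, index=pd.MultiIndex.from_tuples(keys, names=["monomer", "residue_index"])
    )
    return ResidueSeries(series, label=label or "rmsf", units="A")


def delta_rmsf(rmsf_eef: ResidueSeries, rmsf_amb: ResidueSeries) -> ResidueSeries:
    """ΔRMSF = RMSF under field − RMSF ambient, residue by residue.

    Requires identical residue key sets; missing keys are reported.
    """
    a, b = rmsf_eef.values, rmsf_amb.values
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            "residue key mismatch between conditions: "
            f"missing from ambient {list(only_a)[:5]}, "
            f"missing from field {list(only_b)[:5]}"
        )
    return ResidueSeries(a - b.reindex(a.index), label="delta_rmsf", units="A")


# ---------------------------------------------------------------------------
# secondary-structure occupancy
# ---------------------------------------------------------------------------

# Cα-geometry classification thresholds (Å), P-SEA-style; locked by tests on
# ideal helix and extended-chain geometries.
_HELIX_D13 = (4.8, 6.2)
_HELIX_D14 = (5.8, 7.2)
_SHEET_D13 = (6.4, 7.4)
_SHEET_DIHEDRAL_MIN = 135.0  # |pseudo-dihedral| degrees for an extended run


def _classify_chain(ca: np.ndarray) -> np.ndarray:
    """Classify one monomer's Cα trace; returns codes h/s/- per residue."""
    n = len(ca)
    codes = np.full(n, "-", dtype="<U1")
    if n < 5:
        raise ValueError("geometric classification needs chains of ≥5 residues")
    d = lambda i, j: np.linalg.norm(ca[i] - ca[j])
    helix_start = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        d13, d14 = d(i, i + 3), d(i, i + 4)
        if _HELIX_D13[0] <= d13 <= _HELIX_D13[1] and _HELIX_D14[0] <= d14 <= _HELIX_D14[1]:
            helix_start[i] = True
    # a 4-residue run of satisfied starts marks residues i..i+4 helical
    for i in range(n - 4):
        if helix_start[i]:
            codes[i : i + 5] = "h"
    for i in range(n - 2):
        if not (_SHEET_D13[0] <= d(i, i + 2) <= _SHEET_D13[1]):
            continue
        if 1 <= i and i + 2 < n:
            ang = _pseudo_dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
            if ang is None or abs(ang) < _SHEET_DIHEDRAL_MIN:
                continue
        for j in range(i, i + 3):
            if codes[j] == "-":
                codes[j] = "s"
    return codes


def _pseudo_dihedral(p0, p1, p2, p3) -> float | None:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        return None  # collinear: dihedral undefined
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def ss_counts(
    traj: Trajectory,
    structure: AnnotatedStructure,
    classifier: str = "labels",
) -> pd.DataFrame:
    """Per-frame counts of helix and sheet residues.

    ``labels`` mode trusts the static annotations (so the series is
    constant); ``ca_geometry`` classifies each frame from Cα pseudo-geometry
    and can pick up frame-to-frame changes.
    """
    if classifier not in ("labels", "ca_geometry"):
        raise ValueError(f"unknown classifier {classifier!r}")
    df = structure.atoms
    if classifier == "labels":
        res = df.drop_duplicates(["monomer", "residue_index"])
        n_helix = int((res["ss_class"] == "helix").sum())
        n_sheet = int((res["ss_class"] == "sheet").sum())
        return pd.DataFrame(
            {
                "time_ps": traj.times,
                "n_helix": n_helix,
                "n_sheet": n_sheet,
            }
        )
    ca_by_monomer = {}
    for monomer in ("alpha", "beta"):
        mask = (df["monomer"] == monomer) & (df["atom_name"] == "CA")
        idx = np.nonzero(mask.to_numpy())[0]
        if idx.size:
            order = np.argsort(df.iloc[idx]["residue_index"].to_numpy())
            ca_by_monomer[monomer] = idx[order]
    rows = []
    for t, frame in zip(traj.times, traj.coords):
        n_helix = n_sheet = 0
        for idx in ca_by_monomer.values():
            codes = _classify_chain(frame[idx])
            n_helix += int(np.sum(codes == "h"))
            n_sheet += int(np.sum(codes == "s"))
        rows.append((t, n_helix, n_sheet))
    return pd.DataFrame(rows, columns=["time_ps", "n_helix", "n_sheet"])
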