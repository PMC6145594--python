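"""Optimal rigid-body superposition and RMSD.

The workhorse is the SVD-based Kabsch algorithm: given paired point sets it
returns the proper rotation (reflections are excluded by construction) and
translation minimising the weighted RMSD.  Weights default to uniform, the
common convention for Cα RMSD/RMSF; mass weighting is available by passing
the masses explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import AnnotatedStructure, Trajectory

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "apply_transform",
    "rmsd",
    "rmsd_series",
    "rmsd_series_by_ss",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Raised when a rotation is under-determined (too few / collinear points)."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rigid transform mapping mobile onto reference.

    Applying ``x @ rotation.T + translation`` to the mobile coordinates
    minimises the weighted RMSD against the reference; ``rmsd_after`` is that
    minimum in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after: float
    n_atoms_fit: int


def _weights(n: int, weights) -> np.ndarray:
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"weights shape {w.shape} does not match {n} points")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    return w / w.sum()


def rmsd(coords_a, coords_b, weights=None) -> float:
    """Weighted RMSD √(Σ wᵢ|aᵢ−bᵢ|² / Σ wᵢ) in Å, without fitting."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    w = _weights(a.shape[0], weights)
    return float(np.sqrt(np.sum(w * np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile_coords, reference_coords, weights=None
) -> SuperpositionResult:
    """Least-squares proper rigid superposition of ``mobile`` onto ``reference``.

    Requires ≥3 non-collinear points; otherwise the rotation is
    under-determined and a :class:`DegenerateGeometryError` is raised.  A
    reflection solution (det = −1) is corrected by flipping the smallest
    singular vector, so the result is always a proper rotation.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError(f"coordinate shapes differ: {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need ≥3 points to fit a rotation, got {n}")
    w = _weights(n, weights)
    mob_c = mob - w @ mob
    ref_c = ref - w @ ref
    # collinearity: a point set spanning <2 dimensions cannot pin down a rotation
    for label, pts in (("mobile", mob_c), ("reference", ref_c)):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(
                f"{label} points are collinear; rotation under-determined"
            )
    cov = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = (w @ ref) - rot @ (w @ mob)
    fitted = mob @ rot.T + trans
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd_after=rmsd(fitted, ref, weights),
        n_atoms_fit=n,
    )


def apply_transform(coords, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted transform to an arbitrary coordinate array."""
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def _reference_coords(traj: Trajectory, reference_frame) -> np.ndarray:
    if isinstance(reference_frame, (int, np.integer)):
        return traj.coords[int(reference_frame)]
    ref = np.asarray(reference_frame, dtype=float)
    if ref.shape != traj.coords.shape[1:]:
        raise ValueError("reference frame shape does not match trajectory")
    return ref


def rmsd_series(
    traj: Trajectory,
    reference_frame,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray,
    weights=None,
) -> np.ndarray:
    """Per-frame RMSD after fitting each frame to the reference.

    Each frame is superimposed on the reference using the ``fit_selection``
    atoms, then the RMSD is reported over ``measure_selection``.  Both
    selections are atom index arrays resolved against the shared topology.
    The reference may be a frame index into ``traj`` or a coordinate array.
    """
    fit_idx = np.asarray(fit_selection, dtype=int)
    meas_idx = np.asarray(measure_selection, dtype=int)
    if fit_idx.size == 0 or meas_idx.size == 0:
        raise ValueError("empty selection passed to rmsd_series")
    ref = _reference_coords(traj, reference_frame)
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        fit = kabsch_superpose(frame[fit_idx], ref[fit_idx], weights)
        fitted = apply_transform(frame[meas_idx], fit)
        out[i] = rmsd(fitted, ref[meas_idx])
    return out


def rmsd_series_by_ss(
    traj: Trajectory,
    structure: AnnotatedStructure,
    reference_frame,
    fit_selection: np.ndarray,
) -> dict[str, np.ndarray | None]:
    """Cα RMSD series split into rigid (helix+sheet) vs other residues.

    Both partitions share one fit (the ``fit_selection`` atoms) per frame, so
    the two series are directly comparable.  An empty partition yields
    ``None`` for that series rather than an error.
    """
    df = structure.atoms
    ca = (df["atom_name"] == "CA").to_numpy()
    rigid = ca & df["ss_class"].isin(["helix", "sheet"]).to_numpy()
    other = ca & ~df["ss_class"].isin(["helix", "sheet"]).to_numpy()
    ref = _reference_coords(traj, reference_frame)
    fit_idx = np.asarray(fit_selection, dtype=int)
    series: dict[str, np.ndarray | None] = {}
    for key, mask in (("helix_sheet", rigid), ("other", other)):
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            series[key] = None
            continue
        series[key] = rmsd_series(traj, ref, fit_idx, idx)
    return series
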