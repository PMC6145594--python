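"""Low-frequency conformational observables of the heterodimer.

This module implements the curvature (intradimer bend angle), elongation,
loop distance distributions, windowed mean structures, and mean squared
displacement.  The bend angle follows the helix-axis construction: the study
frame is superimposed on a straight reference using the α:H7 atoms only, a
best-fit line (total least squares, i.e. the first principal axis of the
centred atom cloud) is drawn through designated H7 atoms of each structure,
and the angle between the two lines — folded to [0°, 90°] since lines have
no sense — is the bend.  ``combined`` mode draws one line through
α:H7 ∪ β:H7 per structure; ``beta_only`` uses each structure's β:H7 alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import AnnotatedStructure, Trajectory
from .superposition import DegenerateGeometryError, apply_transform, kabsch_superpose

__all__ = [
    "Line3D",
    "SampleDistribution",
    "fit_axis",
    "bend_angle",
    "bend_angle_series",
    "elongation",
    "elongation_series",
    "distance_series",
    "mean_structure",
    "msd",
]

BEND_MODES = ("combined", "beta_only")
PROBE_MODES = ("residue_com", "sidechain_tip", "ca")

#: side-chain tip atom names recognised by ``probe_mode="sidechain_tip"``
TIP_ATOM_NAMES = frozenset(
    ["NZ", "NE", "NH1", "NH2", "OD1", "OD2", "OE1", "OE2", "OXT", "ND1", "NE2"]
)


@dataclass(frozen=True)
class Line3D:
    """A line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError("direction must be unit length")


@dataclass
class SampleDistribution:
    """Scalar samples with summary statistics and a normalised histogram.

    Quartiles use the linear-interpolation (inclusive) convention.  The
    histogram is a probability density: Σ density·bin_width = 1.
    """

    samples: np.ndarray
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size == 0:
            raise ValueError("SampleDistribution requires at least one sample")

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def quartiles(self) -> tuple[float, float, float]:
        q1, med, q3 = np.percentile(self.samples, [25, 50, 75])
        return float(q1), float(med), float(q3)

    def histogram(self, bins: int = 40) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, densities) of the normalised histogram."""
        dens, edges = np.histogram(self.samples, bins=bins, density=True)
        return edges, dens

    def summary(self) -> dict:
        q1, med, q3 = self.quartiles
        return {
            "n": int(self.samples.size),
            "mean": self.mean,
            "q1": q1,
            "median": med,
            "q3": q3,
            "units": self.units,
        }


def fit_axis(coords) -> Line3D:
    """Total-least-squares line through a point cloud.

    Returns the centroid and the dominant principal direction of the centred
    coordinates.  The direction sign is canonicalised along the input
    ordering (first → last point), so selections listed α-before-β give the
    α→β sense.  Coincident points or an isotropic cloud (eigengap below
    1e-6) are degenerate.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise DegenerateGeometryError("fit_axis needs ≥2 points in 3D")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    scale = np.max(np.linalg.norm(centred, axis=1))
    if scale < 1e-10:
        raise DegenerateGeometryError("all points coincident; no axis")
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if len(s) > 1 and (s[0] - s[1]) <= 1e-6 * s[0]:
        raise DegenerateGeometryError(
            "point cloud has no dominant axis (eigengap below tolerance)"
        )
    direction = vt[0]
    span = pts[-1] - pts[0]
    if direction @ span < 0:
        direction = -direction
    return Line3D(point=centroid, direction=direction / np.linalg.norm(direction))


def _line_angle_deg(a: Line3D, b: Line3D) -> float:
    cosang = abs(float(a.direction @ b.direction))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def bend_angle(
    study_coords: np.ndarray,
    reference_coords: np.ndarray,
    alpha_h7_idx: np.ndarray,
    beta_h7_idx: np.ndarray,
    mode: str = "combined",
) -> float:
    """Intradimer bend angle of a study frame against a straight reference.

    The study frame is superimposed on the reference by the α:H7 atoms only,
    anchoring the α monomer; the angle between best-fit H7 lines of the two
    structures (per ``mode``) is reported in degrees, folded to [0°, 90°].
    """
    if mode not in BEND_MODES:
        raise ValueError(f"unknown bend mode {mode!r}")
    a_idx = np.asarray(alpha_h7_idx, dtype=int)
    b_idx = np.asarray(beta_h7_idx, dtype=int)
    fit = kabsch_superpose(study_coords[a_idx], reference_coords[a_idx])
    study = apply_transform(study_coords, fit)
    if mode == "combined":
        line_idx = np.concatenate([a_idx, b_idx])
    else:
        line_idx = b_idx
    ref_line = fit_axis(reference_coords[line_idx])
    study_line = fit_axis(study[line_idx])
    return _line_angle_deg(ref_line, study_line)


def bend_angle_series(
    traj: Trajectory,
    reference_coords: np.ndarray,
    alpha_h7_idx: np.ndarray,
    beta_h7_idx: np.ndarray,
    mode: str = "combined",
    window: tuple[float, float] | None = None,
) -> SampleDistribution:
    """Per-frame bend angle collected into a distribution (degrees)."""
    idx = traj.window_frames(window)
    samples = [
        bend_angle(traj.coords[i], reference_coords, alpha_h7_idx, beta_h7_idx, mode)
        for i in idx
    ]
    return SampleDistribution(np.array(samples), units="deg", label=f"bend_{mode}")


def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    return masses @ coords / total


def elongation(
    frame: np.ndarray,
    helix_idx_alpha: np.ndarray,
    helix_idx_beta: np.ndarray,
    masses: np.ndarray,
) -> float:
    """Distance (Å) between mass-weighted COMs of the two helix atom sets."""
    a_idx = np.asarray(helix_idx_alpha, dtype=int)
    b_idx = np.asarray(helix_idx_beta, dtype=int)
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("elongation requires non-empty helix selections")
    com_a = _com(frame[a_idx], masses[a_idx])
    com_b = _com(frame[b_idx], masses[b_idx])
    return float(np.linalg.norm(com_a - com_b))


def elongation_series(
    traj: Trajectory,
    helix_idx_alpha: np.ndarray,
    helix_idx_beta: np.ndarray,
    masses: np.ndarray,
    window: tuple[float, float] | None = None,
) -> SampleDistribution:
    idx = traj.window_frames(window)
    samples = [
        elongation(traj.coords[i], helix_idx_alpha, helix_idx_beta, masses)
        for i in idx
    ]
    return SampleDistribution(np.array(samples), units="A", label="elongation")


def _probe_point(
    frame: np.ndarray,
    structure: AnnotatedStructure,
    probe_idx: np.ndarray,
    probe_mode: str,
) -> np.ndarray:
    df = structure.atoms.iloc[probe_idx]
    if probe_mode == "residue_com":
        return _com(frame[probe_idx], structure.masses[probe_idx])
    if probe_mode == "ca":
        ca = probe_idx[(df["atom_name"] == "CA").to_numpy()]
        if ca.size != 1:
            raise ValueError("probe selection must contain exactly one CA atom")
        return frame[ca[0]]
    if probe_mode == "sidechain_tip":
        tips = probe_idx[df["atom_name"].isin(TIP_ATOM_NAMES).to_numpy()]
        if tips.size == 0:
            raise ValueError("probe selection has no recognised side-chain tip atom")
        return frame[tips[-1]]
    raise ValueError(f"unknown probe mode {probe_mode!r}")


def distance_series(
    traj: Trajectory,
    structure: AnnotatedStructure,
    probe_idx: np.ndarray,
    target_idx: np.ndarray,
    window: tuple[float, float] | None = None,
    probe_mode: str = "residue_com",
) -> SampleDistribution:
    """Distance per frame from a probe residue to the COM of a target region.

    The probe point is, per ``probe_mode``, the probe residue's COM, its
    side-chain tip atom, or its Cα.  Used for loop-opening observables such
    as the distance between a charged loop residue and a reference helix.
    """
    probe_idx = np.asarray(probe_idx, dtype=int)
    target_idx = np.asarray(target_idx, dtype=int)
    if probe_idx.size == 0 or target_idx.size == 0:
        raise ValueError("distance_series requires non-empty selections")
    idx = traj.window_frames(window)
    masses = structure.masses
    samples = np.empty(idx.size)
    for k, i in enumerate(idx):
        frame = traj.coords[i]
        p = _probe_point(frame, structure, probe_idx, probe_mode)
        t = _com(frame[target_idx], masses[target_idx])
        samples[k] = np.linalg.norm(p - t)
    return SampleDistribution(samples, units="A", label="distance")


def mean_structure(
    traj: Trajectory,
    fit_idx: np.ndarray,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Atom-wise average coordinates over a window.

    Every window frame is superimposed on the first window frame via the fit
    atoms before averaging, so the mean is not blurred by rigid-body motion.
    """
    idx = traj.window_frames(window)
    fit_idx = np.asarray(fit_idx, dtype=int)
    ref = traj.coords[idx[0]]
    acc = np.zeros_like(ref)
    for i in idx:
        res = kabsch_superpose(traj.coords[i][fit_idx], ref[fit_idx])
        acc += apply_transform(traj.coords[i], res)
    return acc / idx.size


def msd(
    traj: Trajectory,
    selection_idx: np.ndarray,
    masses: np.ndarray,
    window: tuple[float, float] | None = None,
    sliding: bool = True,
    max_lag_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared displacement of the selection COM vs lag time.

    Returns ``(lag_ps, msd_A2)``.  With ``sliding=True`` (default) every
    valid time origin contributes, which sharply reduces estimator variance;
    ``sliding=False`` uses only the first frame as origin.  For free
    diffusion with coefficient D the slope is 6·D.
    """
    sel = np.asarray(selection_idx, dtype=int)
    idx = traj.window_frames(window)
    if idx.size < 2:
        raise ValueError("MSD needs at least 2 frames")
    com = np.array([_com(traj.coords[i][sel], masses[sel]) for i in idx])
    times = traj.times[idx]
    n = len(com)
    if max_lag_frames is None:
        max_lag_frames = n - 1 if not sliding else max(1, n // 4)
    max_lag_frames = min(max_lag_frames, n - 1)
    lags = np.arange(1, max_lag_frames + 1)
    out = np.empty(lags.size)
    for k, lag in enumerate(lags):
        if sliding:
            disp = com[lag:] - com[:-lag]
        else:
            disp = (com[lag] - com[0])[None, :]
        out[k] = np.mean(np.sum(disp**2, axis=1))
    lag_ps = times[lags] - times[0] if not sliding else lags * np.mean(np.diff(times))
    return lag_ps, out
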