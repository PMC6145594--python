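"""Structures, trajectories, annotations, and named atom selections.

Conventions used throughout the package:

* coordinates are in Å, times in ps — no unit auto-detection;
* residue indices are 1-based and ungapped (contiguous) within each monomer;
* the two monomers of the heterodimer are labelled ``"alpha"`` and
  ``"beta"`` and map to PDB chains ``A`` and ``B``;
* per-atom annotations that the PDB format cannot carry (partial charge,
  named region, secondary-structure class) live in a tab-separated sidecar
  table keyed by ``(monomer, residue_index, atom_name)``.

The required trajectory dialect is multi-model PDB; DCD is accepted as an
optional, read-only alternative behind the same contract.  All parsing and
writing of both formats is delegated to MDAnalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedStructure",
    "Trajectory",
    "SelectionSpec",
    "StructureError",
    "TrajectoryError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_annotations",
    "write_annotations",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
]

MONOMERS = ("alpha", "beta")
SS_CLASSES = ("helix", "sheet", "coil", "turn", "3-10", "unknown")

_MONOMER_TO_CHAIN = {"alpha": "A", "beta": "B"}
_CHAIN_TO_MONOMER = {v: k for k, v in _MONOMER_TO_CHAIN.items()}

#: column order of the annotation sidecar table
ANNOTATION_COLUMNS = [
    "monomer",
    "residue_index",
    "atom_name",
    "element",
    "charge",
    "mass",
    "region",
    "ss_class",
]

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: columns of :attr:`AnnotatedStructure.atoms`
ATOM_COLUMNS = [
    "atom_id",
    "atom_name",
    "element",
    "residue_index",
    "monomer",
    "region",
    "ss_class",
    "charge",
    "mass",
    "resname",
]


class StructureError(ValueError):
    """Raised for inconsistent structures or annotation tables."""


class TrajectoryError(ValueError):
    """Raised for malformed or topology-incompatible trajectories."""


class SelectionError(ValueError):
    """Raised when a selection cannot be resolved (e.g. it is empty)."""


@dataclass
class AnnotatedStructure:
    """Atoms with coordinates plus the annotations every stage consumes.

    ``atoms`` is a DataFrame with one row per atom, ordered by ascending
    ``atom_id``; ``coords`` is the matching ``(n_atoms, 3)`` array in Å.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.atoms = self.atoms.reset_index(drop=True)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    # -- integrity ---------------------------------------------------------

    def validate(self) -> None:
        df = self.atoms
        missing = [c for c in ATOM_COLUMNS if c not in df.columns]
        if missing:
            raise StructureError(f"atom table lacks columns {missing}")
        if self.coords.shape != (len(df), 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(df)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if df["atom_id"].duplicated().any():
            dupes = df.loc[df["atom_id"].duplicated(), "atom_id"].tolist()
            raise StructureError(f"duplicate atom ids {dupes[:5]}")
        if not df["atom_id"].is_monotonic_increasing:
            raise StructureError("atoms must be ordered by ascending atom_id")
        if (df["mass"] <= 0).any():
            raise StructureError("all atom masses must be positive")
        bad_mono = set(df["monomer"]) - set(MONOMERS)
        if bad_mono:
            raise StructureError(f"unknown monomer labels {bad_mono}")
        bad_ss = set(df["ss_class"]) - set(SS_CLASSES)
        if bad_ss:
            raise StructureError(f"unknown ss_class labels {bad_ss}")
        for monomer in sorted(set(df["monomer"])):
            resids = np.unique(df.loc[df["monomer"] == monomer, "residue_index"])
            expected = np.arange(1, len(resids) + 1)
            if not np.array_equal(resids, expected):
                raise StructureError(
                    f"residue indices of monomer {monomer!r} are not "
                    f"contiguous from 1 (got range {resids.min()}..{resids.max()}"
                    f" with {len(resids)} residues)"
                )

    # -- convenience -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return self.atoms["mass"].to_numpy(dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return self.atoms["charge"].to_numpy(dtype=float)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique ``(monomer, residue_index)`` pairs."""
        seen = self.atoms[["monomer", "residue_index"]].drop_duplicates()
        return [(m, int(r)) for m, r in seen.itertuples(index=False)]

    def residue_charges(self) -> pd.Series:
        """Net charge per residue, indexed by (monomer, residue_index)."""
        return self.atoms.groupby(["monomer", "residue_index"], sort=False)[
            "charge"
        ].sum()

    def with_coords(self, coords: np.ndarray) -> "AnnotatedStructure":
        return AnnotatedStructure(self.atoms.copy(), np.array(coords, dtype=float))

    def copy(self) -> "AnnotatedStructure":
        return self.with_coords(self.coords.copy())


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Å; ``times`` is in ps
    and strictly increasing; ``frame_interval`` is the nominal spacing used
    when times must be inferred.
    """

    coords: np.ndarray
    times: np.ndarray
    frame_interval: float = 25.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(f"bad coords shape {self.coords.shape}")
        if self.coords.shape[0] == 0:
            raise TrajectoryError("trajectory has zero frames")
        if self.times.shape != (self.coords.shape[0],):
            raise TrajectoryError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frames(self) -> np.ndarray:
        return self.coords

    def window_frames(self, window: tuple[float, float] | None) -> np.ndarray:
        """Frame indices of the half-open time window ``[t_start, t_end)``.

        ``None`` selects all frames.
        """
        if window is None:
            return np.arange(self.n_frames)
        t_start, t_end = window
        if t_end <= t_start:
            raise TrajectoryError(f"empty window [{t_start}, {t_end})")
        idx = np.nonzero((self.times >= t_start) & (self.times < t_end))[0]
        if idx.size == 0:
            raise TrajectoryError(
                f"window [{t_start}, {t_end}) ps selects no frames "
                f"(trajectory spans {self.times[0]}..{self.times[-1]} ps)"
            )
        return idx


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection; filters compose with AND.

    ``residue_range`` is inclusive on both ends.  Resolution against a given
    structure is deterministic: atoms are returned in ascending ``atom_id``
    order, and an empty result is an error naming the spec.
    """

    name: str
    monomer: str | None = None
    region: str | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    ss_class: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if self.ss_class is not None:
            if isinstance(self.ss_class, str):
                object.__setattr__(self, "ss_class", frozenset([self.ss_class]))
            else:
                object.__setattr__(self, "ss_class", frozenset(self.ss_class))


def resolve_selection(
    spec: SelectionSpec, structure: AnnotatedStructure
) -> np.ndarray:
    """Resolve ``spec`` to an ordered array of atom row indices.

    The order is ascending ``atom_id`` (the storage order of the structure),
    so resolving the same spec twice yields identical arrays.
    """
    df = structure.atoms
    mask = np.ones(len(df), dtype=bool)
    if spec.monomer is not None:
        if spec.monomer not in MONOMERS:
            raise SelectionError(f"{spec.name}: unknown monomer {spec.monomer!r}")
        mask &= (df["monomer"] == spec.monomer).to_numpy()
    if spec.region is not None:
        mask &= (df["region"] == spec.region).to_numpy()
    if spec.residue_range is not None:
        lo, hi = spec.residue_range
        ri = df["residue_index"].to_numpy()
        mask &= (ri >= lo) & (ri <= hi)
    if spec.atom_names is not None:
        mask &= df["atom_name"].isin(spec.atom_names).to_numpy()
    if spec.ss_class is not None:
        mask &= df["ss_class"].isin(spec.ss_class).to_numpy()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(f"selection {spec.name!r} resolves to no atoms")
    return idx


# ---------------------------------------------------------------------------
# annotation sidecar
# ---------------------------------------------------------------------------


def write_annotations(structure: AnnotatedStructure, path: str | Path) -> None:
    """Write the TSV sidecar carrying charge/mass/region/ss_class."""
    df = structure.atoms[ANNOTATION_COLUMNS].copy()
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise StructureError(f"annotation table lacks columns {missing}")
    df["residue_index"] = df["residue_index"].astype(int)
    df["charge"] = df["charge"].astype(float)
    df["mass"] = df["mass"].astype(float)
    df["region"] = df["region"].astype(str)
    ss = df["ss_class"].astype(str)
    df["ss_class"] = ss.where(ss != "", "unknown")
    return df


# ---------------------------------------------------------------------------
# PDB / DCD via MDAnalysis
# ---------------------------------------------------------------------------


def _load_universe(path: Path, n_atoms: int | None = None):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".dcd":
            if n_atoms is None:
                raise TrajectoryError("DCD input requires a topology")
            u = mda.Universe.empty(n_atoms, trajectory=True)
            u.load_new(str(path))
        else:
            u = mda.Universe(str(path))
    return u


def _universe_from_structure(structure: AnnotatedStructure, coords=None):
    import MDAnalysis as mda

    df = structure.atoms
    res_keys = structure.residue_keys()
    key_to_resindex = {k: i for i, k in enumerate(res_keys)}
    atom_resindex = np.array(
        [
            key_to_resindex[(m, int(r))]
            for m, r in df[["monomer", "residue_index"]].itertuples(index=False)
        ]
    )
    seg_of_res = np.array([0 if m == "alpha" else 1 for m, _ in res_keys])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            len(df),
            n_residues=len(res_keys),
            atom_resindex=atom_resindex,
            residue_segindex=seg_of_res,
            n_segments=2,
            trajectory=True,
        )
        u.add_TopologyAttr("names", df["atom_name"].tolist())
        u.add_TopologyAttr("elements", df["element"].tolist())
        u.add_TopologyAttr("ids", df["atom_id"].tolist())
        u.add_TopologyAttr("resids", [r for _, r in res_keys])
        first_atom = df.drop_duplicates(["monomer", "residue_index"])
        u.add_TopologyAttr("resnames", first_atom["resname"].tolist())
        u.add_TopologyAttr("segids", ["A", "B"])
        u.add_TopologyAttr(
            "chainIDs", [_MONOMER_TO_CHAIN[m] for m in df["monomer"]]
        )
        u.atoms.positions = structure.coords if coords is None else coords
    return u


def write_structure(
    structure: AnnotatedStructure,
    pdb_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write a single-model PDB plus the TSV annotation sidecar."""
    u = _universe_from_structure(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(pdb_path))
    write_annotations(structure, annotation_path)


def read_structure(
    pdb_path: str | Path, annotation_path: str | Path
) -> AnnotatedStructure:
    """Merge PDB coordinates with the annotation sidecar.

    The sidecar must describe exactly the atoms present in the PDB (one row
    per atom, keyed by monomer/residue_index/atom_name); a count mismatch or
    an unmatched atom is an error.  Empty ``region`` cells mean "no region";
    empty ``ss_class`` cells fall back to ``unknown``.
    """
    pdb_path = Path(pdb_path)
    if not pdb_path.exists():
        raise FileNotFoundError(pdb_path)
    u = _load_universe(pdb_path)
    ann = read_annotations(annotation_path)
    if len(u.atoms) != len(ann):
        raise StructureError(
            f"atom-count mismatch: PDB has {len(u.atoms)} atoms, annotation "
            f"table describes {len(ann)}"
        )
    try:
        chains = u.atoms.chainIDs
    except AttributeError:  # pragma: no cover - PDB always carries chainIDs
        chains = [
            "A" if seg in ("A", "SYSTEM") else "B" for seg in u.atoms.segids
        ]
    monomers = []
    for c in chains:
        if c not in _CHAIN_TO_MONOMER:
            raise StructureError(
                f"chain {c!r} does not map to a monomer (expected A or B)"
            )
        monomers.append(_CHAIN_TO_MONOMER[c])
    df = pd.DataFrame(
        {
            "atom_id": np.arange(1, len(u.atoms) + 1),
            "atom_name": u.atoms.names,
            "residue_index": u.atoms.resids,
            "monomer": monomers,
            "resname": u.atoms.resnames,
        }
    )
    ann_indexed = ann.set_index(["monomer", "residue_index", "atom_name"])
    if ann_indexed.index.duplicated().any():
        raise StructureError("annotation table has duplicate atom keys")
    try:
        merged = ann_indexed.loc[
            list(
                zip(df["monomer"], df["residue_index"], df["atom_name"]),
            )
        ].reset_index()
    except KeyError as exc:
        raise StructureError(f"annotation table does not cover atom {exc}") from None
    df["element"] = merged["element"].to_numpy()
    df["charge"] = merged["charge"].to_numpy()
    df["mass"] = merged["mass"].to_numpy()
    df["region"] = merged["region"].to_numpy()
    df["ss_class"] = merged["ss_class"].to_numpy()
    coords = u.atoms.positions.astype(float)
    return AnnotatedStructure(df[ATOM_COLUMNS], coords)


def write_trajectory(
    traj: Trajectory, structure: AnnotatedStructure, path: str | Path
) -> None:
    """Write a multi-model PDB, one MODEL per frame."""
    import MDAnalysis as mda

    if traj.n_atoms != structure.n_atoms:
        raise TrajectoryError(
            f"trajectory has {traj.n_atoms} atoms, topology {structure.n_atoms}"
        )
    u = _universe_from_structure(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=u.atoms.n_atoms, multiframe=True) as w:
            for frame in traj.coords:
                u.atoms.positions = frame
                w.write(u.atoms)


def read_trajectory(
    path: str | Path,
    topology: AnnotatedStructure,
    frame_interval: float = 25.0,
    t0: float = 0.0,
) -> Trajectory:
    """Read a multi-model PDB (or DCD) against ``topology``.

    Times are inferred as ``t0 + i * frame_interval`` since neither dialect
    stores reliable timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = _load_universe(path, n_atoms=topology.n_atoms)
    if len(u.atoms) != topology.n_atoms:
        raise TrajectoryError(
            f"frame atom count {len(u.atoms)} does not match topology "
            f"({topology.n_atoms})"
        )
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
    if not frames:
        raise TrajectoryError(f"{path} contains zero frames")
    coords = np.stack(frames)
    times = t0 + frame_interval * np.arange(len(frames))
    return Trajectory(coords, times, frame_interval)
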