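"""Endpoint displacement between two conditions.

"Final displacement" compares the endpoint structures of two runs (typically
fields of opposite sign): after optimal rigid superposition of one endpoint
onto the other, the per-residue Cα distance is reported.  Residues that move
more than a threshold can be exported as start→end vectors for rendering as
arrows in a molecular viewer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fluctuations import ResidueSeries
from .io_model import AnnotatedStructure
from .superposition import apply_transform, kabsch_superpose

__all__ = ["final_displacement", "displacement_vectors"]


def _ca_map(structure: AnnotatedStructure) -> dict[tuple[str, int], int]:
    df = structure.atoms
    mask = (df["atom_name"] == "CA").to_numpy()
    out: dict[tuple[str, int], int] = {}
    for pos in np.nonzero(mask)[0]:
        key = (df.iloc[pos]["monomer"], int(df.iloc[pos]["residue_index"]))
        out[key] = int(pos)
    return out


def final_displacement(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    structure: AnnotatedStructure,
    fit_idx: np.ndarray,
    label: str = "final_displacement",
) -> ResidueSeries:
    """Per-residue Cα distance between two frames after superposition.

    Frame ``b`` is fitted onto frame ``a`` using the ``fit_idx`` atoms.
    Residues lacking a Cα are absent from the result (not reported as zero).
    The measure is symmetric in its arguments.
    """
    fit_idx = np.asarray(fit_idx, dtype=int)
    res = kabsch_superpose(frame_b[fit_idx], frame_a[fit_idx])
    b_fit = apply_transform(frame_b, res)
    ca = _ca_map(structure)
    keys = [k for k in structure.residue_keys() if k in ca]
    vals = [
        float(np.linalg.norm(frame_a[ca[k]] - b_fit[ca[k]])) for k in keys
    ]
    series = pd.Series(
        vals,
        index=pd.MultiIndex.from_tuples(keys, names=["monomer", "residue_index"]),
    )
    return ResidueSeries(series, label=label, units="A")


def displacement_vectors(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    structure: AnnotatedStructure,
    fit_idx: np.ndarray,
    threshold: float = 2.0,
    stride: int = 1,
) -> list[tuple[tuple[str, int], np.ndarray, np.ndarray]]:
    """Start→end Cα vectors for residues displaced strictly beyond threshold.

    Vectors run from frame ``a``'s Cα to frame ``b``'s fitted Cα.  ``stride``
    is a plotting decimation (keep every ``stride``-th qualifying vector).
    The threshold comparison is strict; displacements below 1e-9 Å (numerical
    superposition residue) count as zero.
    """
    fit_idx = np.asarray(fit_idx, dtype=int)
    res = kabsch_superpose(frame_b[fit_idx], frame_a[fit_idx])
    b_fit = apply_transform(frame_b, res)
    ca = _ca_map(structure)
    out = []
    for key in structure.residue_keys():
        if key not in ca:
            continue
        pos = ca[key]
        start, end = frame_a[pos], b_fit[pos]
        d = np.linalg.norm(end - start)
        if d > threshold and d > 1e-9:
            out.append((key, start.copy(), end.copy()))
    return out[::stride] if stride > 1 else out
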