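"""Condition-matrix orchestration: run every stage from one config.

A run config names one topology (PDB + annotation sidecar), one trajectory
per condition with its field specification, and the analysis options; the
pipeline validates everything up front (fail fast, before any output is
written), runs each stage per condition, the pairwise stages per declared
condition pair, and writes CSV outputs plus a JSON manifest holding the
config hash and all summary statistics.  Summary numbers in the manifest
are exactly the unit-level operation outputs — the pipeline adds no math of
its own.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .displacement import displacement_vectors, final_displacement
from .electrostatics import FieldSpec, dipole_series, salt_bridges
from .fluctuations import ResidueSeries, delta_rmsf, rmsf, ss_counts
from .geometry import (
    SampleDistribution,
    bend_angle_series,
    distance_series,
    elongation_series,
    msd,
)
from .io_model import (
    AnnotatedStructure,
    SelectionSpec,
    Trajectory,
    read_structure,
    read_trajectory,
    resolve_selection,
    write_structure,
    write_trajectory,
)
from .superposition import rmsd_series, rmsd_series_by_ss
from .synthetic import GeneratorParams, build_synthetic_dimer, generate_trajectory, preset

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "config_hash", "load_config"]

_FLOAT_FMT = "%.6f"

FIXTURE_STRENGTHS = (50.0, 100.0, 200.0, 750.0)
FIELD_PRESETS = (
    "pos_transverse",
    "neg_transverse",
    "pos_longitudinal",
    "neg_longitudinal",
)


@dataclass
class Condition:
    name: str
    trajectory: str
    field: FieldSpec


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``load_config`` for the YAML)."""

    topology: str
    annotations: str
    output: str
    conditions: list[Condition]
    displacement_pairs: list[tuple[str, str]] = field(default_factory=list)
    delta_rmsf_pairs: list[tuple[str, str]] = field(default_factory=list)
    frame_interval: float = 25.0
    salt_bridge_cutoff: float = 3.2
    displacement_threshold: float = 2.0
    bend_mode: str = "combined"
    probe_mode: str = "residue_com"
    dipole_reference: str = "com"
    distributions_window: str | tuple[float, float] = "last_half"
    selections: dict = field(default_factory=dict)
    seed: int = 0

    def raw(self) -> dict:
        d = {
            "topology": self.topology,
            "annotations": self.annotations,
            "output": self.output,
            "frame_interval": self.frame_interval,
            "conditions": {
                c.name: {
                    "trajectory": c.trajectory,
                    "field": {
                        "rule": c.field.direction_rule,
                        "magnitude": c.field.magnitude,
                        "window": list(c.field.window),
                    },
                }
                for c in self.conditions
            },
            "pairs": {
                "displacement": [list(p) for p in self.displacement_pairs],
                "delta_rmsf": [list(p) for p in self.delta_rmsf_pairs],
            },
            "thresholds": {
                "salt_bridge_cutoff": self.salt_bridge_cutoff,
                "displacement": self.displacement_threshold,
            },
            "modes": {
                "bend": self.bend_mode,
                "probe": self.probe_mode,
                "dipole_reference": self.dipole_reference,
            },
            "windows": {
                "distributions": self.distributions_window
                if isinstance(self.distributions_window, str)
                else list(self.distributions_window)
            },
            "selections": self.selections,
            "seed": self.seed,
        }
        return d


def config_hash(config: RunConfig) -> str:
    """Stable hash over the semantically meaningful config fields."""
    blob = json.dumps(config.raw(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; paths are resolved relative to the file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    conditions = []
    for name, spec in raw["conditions"].items():
        f = spec.get("field", {})
        window = tuple(f.get("window", (0.0, 1e12)))
        conditions.append(
            Condition(
                name=name,
                trajectory=_resolve(spec["trajectory"]),
                field=FieldSpec(
                    f.get("rule", "transverse_pos"),
                    float(f.get("magnitude", 0.0)),
                    (float(window[0]), float(window[1])),
                ),
            )
        )
    pairs = raw.get("pairs", {})
    thresholds = raw.get("thresholds", {})
    modes = raw.get("modes", {})
    windows = raw.get("windows", {})
    dist_window = windows.get("distributions", "last_half")
    if isinstance(dist_window, (list, tuple)):
        dist_window = (float(dist_window[0]), float(dist_window[1]))
    return RunConfig(
        topology=_resolve(raw["topology"]),
        annotations=_resolve(raw["annotations"]),
        output=_resolve(raw.get("output", "results")),
        conditions=conditions,
        displacement_pairs=[tuple(p) for p in pairs.get("displacement", [])],
        delta_rmsf_pairs=[tuple(p) for p in pairs.get("delta_rmsf", [])],
        frame_interval=float(raw.get("frame_interval", 25.0)),
        salt_bridge_cutoff=float(thresholds.get("salt_bridge_cutoff", 3.2)),
        displacement_threshold=float(thresholds.get("displacement", 2.0)),
        bend_mode=modes.get("bend", "combined"),
        probe_mode=modes.get("probe", "residue_com"),
        dipole_reference=modes.get("dipole_reference", "com"),
        distributions_window=dist_window,
        selections=raw.get("selections", {}),
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------


def _builtin_selections(structure: AnnotatedStructure) -> dict[str, SelectionSpec]:
    sels = {
        "ca_all": SelectionSpec("ca_all", atom_names=frozenset(["CA"])),
        "alpha_h7": SelectionSpec("alpha_h7", monomer="alpha", region="H7"),
        "beta_h7": SelectionSpec("beta_h7", monomer="beta", region="H7"),
        "helix_alpha": SelectionSpec("helix_alpha", monomer="alpha", ss_class="helix"),
        "helix_beta": SelectionSpec("helix_beta", monomer="beta", ss_class="helix"),
    }
    return sels


def _config_selections(config: RunConfig) -> dict[str, SelectionSpec]:
    out = {}
    for name, spec in config.selections.items():
        rr = spec.get("residue_range")
        out[name] = SelectionSpec(
            name,
            monomer=spec.get("monomer"),
            region=spec.get("region"),
            residue_range=tuple(rr) if rr else None,
            atom_names=frozenset(spec["atom_names"]) if spec.get("atom_names") else None,
            ss_class=frozenset([spec["ss_class"]]) if spec.get("ss_class") else None,
        )
    return out


def default_distance_probes(structure: AnnotatedStructure) -> list[dict]:
    """Charged α-loop residues probed against the α:H3 anchor helix.

    Mirrors the loop-opening observable: one positively and one negatively
    charged residue of the α:H1-B2 loop, each measured against α:H3.
    """
    df = structure.atoms
    probes = []
    loop = df[(df["monomer"] == "alpha") & (df["region"] == "H1-B2")]
    if loop.empty or "H3" not in set(df["region"]):
        return []
    res_q = loop.groupby("residue_index")["charge"].sum()
    for sign, tag in ((1, "plus"), (-1, "minus")):
        hits = res_q[np.sign(res_q) == sign]
        if hits.empty:
            continue
        ridx = int(hits.index[0])
        probes.append(
            {
                "name": f"H1-B2_{tag}_{ridx}",
                "probe": SelectionSpec(
                    f"probe_{tag}", monomer="alpha", residue_range=(ridx, ridx)
                ),
                "target": SelectionSpec("alpha_h3", monomer="alpha", region="H3"),
            }
        )
    return probes


def _dist_window(traj: Trajectory, spec) -> tuple[float, float]:
    if spec == "last_half":
        mid = traj.times[traj.n_frames // 2]
        return (float(mid), float(traj.times[-1] + traj.frame_interval))
    return spec


def _field_window_of(traj: Trajectory, fs: FieldSpec) -> tuple[float, float]:
    """The field-on window clipped to the trajectory extent (RMSF window)."""
    lo = max(fs.window[0], float(traj.times[0]))
    hi = min(fs.window[1], float(traj.times[-1] + traj.frame_interval))
    if fs.magnitude == 0 or lo >= hi:
        return (float(traj.times[0]), float(traj.times[-1] + traj.frame_interval))
    return (lo, hi)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _residue_csv(series: ResidueSeries, column: str, path: Path) -> None:
    _write_csv(series.to_frame(column), path)


def run_pipeline(config: RunConfig, quiet: bool = True) -> Path:
    """Run every stage for every condition; returns the report directory."""
    structure = read_structure(config.topology, config.annotations)
    sels = _builtin_selections(structure)
    sels.update(_config_selections(config))
    # fail-fast: every selection must resolve before any stage runs
    resolved = {name: resolve_selection(s, structure) for name, s in sels.items()}
    probes = default_distance_probes(structure)
    for p in probes:
        p["probe_idx"] = resolve_selection(p["probe"], structure)
        p["target_idx"] = resolve_selection(p["target"], structure)
    names = {c.name for c in config.conditions}
    for a, b in config.displacement_pairs + config.delta_rmsf_pairs:
        unknown = {a, b} - names
        if unknown:
            raise ValueError(f"pair references unknown condition(s) {unknown}")

    out_root = Path(config.output)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config_hash(config),
        "config": config.raw(),
        "complete": False,
        "conditions": {},
        "pairs": {},
    }
    masses = structure.masses
    charges = structure.charges
    ca_idx = resolved["ca_all"]
    trajs: dict[str, Trajectory] = {}
    rmsf_by_condition: dict[str, ResidueSeries] = {}
    endpoints: dict[str, np.ndarray] = {}

    try:
        for cond in config.conditions:
            t0 = time.perf_counter()
            cdir = out_root / cond.name
            traj = read_trajectory(
                cond.trajectory, structure, frame_interval=config.frame_interval
            )
            trajs[cond.name] = traj
            endpoints[cond.name] = traj.coords[-1]
            summary: dict = {"n_frames": traj.n_frames}

            series_all = rmsd_series(traj, 0, ca_idx, ca_idx)
            by_ss = rmsd_series_by_ss(traj, structure, 0, ca_idx)
            df = pd.DataFrame({"time_ps": traj.times, "rmsd_all": series_all})
            for key, col in (("helix_sheet", "rmsd_helix_sheet"), ("other", "rmsd_other")):
                if by_ss[key] is not None:
                    df[col] = by_ss[key]
            _write_csv(df, cdir / "rmsd.csv")

            window = _field_window_of(traj, cond.field)
            r = rmsf(traj, structure, ca_idx, ca_idx, window, label=cond.name)
            rmsf_by_condition[cond.name] = r
            _residue_csv(r, "rmsf_A", cdir / "rmsf.csv")

            counts = ss_counts(traj, structure, "labels")
            _write_csv(counts, cdir / "ss_counts.csv")

            dip = dipole_series(traj, charges, masses, config.dipole_reference)
            _write_csv(
                pd.DataFrame(
                    {
                        "time_ps": [d.time for d in dip],
                        "dipole_x_eA": [d.vector[0] for d in dip],
                        "dipole_y_eA": [d.vector[1] for d in dip],
                        "dipole_z_eA": [d.vector[2] for d in dip],
                        "magnitude_debye": [d.magnitude_debye for d in dip],
                    }
                ),
                cdir / "dipole.csv",
            )
            summary["dipole_mean_debye"] = float(
                np.mean([d.magnitude_debye for d in dip])
            )

            dwin = _dist_window(traj, config.distributions_window)
            widx = traj.window_frames(dwin)
            bend = bend_angle_series(
                traj,
                structure.coords,
                resolved["alpha_h7"],
                resolved["beta_h7"],
                config.bend_mode,
                dwin,
            )
            _write_csv(
                pd.DataFrame(
                    {"time_ps": traj.times[widx], "bend_deg": bend.samples}
                ),
                cdir / "bend.csv",
            )
            summary["bend"] = bend.summary()

            elo = elongation_series(
                traj, resolved["helix_alpha"], resolved["helix_beta"], masses, dwin
            )
            _write_csv(
                pd.DataFrame(
                    {"time_ps": traj.times[widx], "elongation_A": elo.samples}
                ),
                cdir / "elongation.csv",
            )
            summary["elongation"] = elo.summary()

            summary["distances"] = {}
            for p in probes:
                d = distance_series(
                    traj,
                    structure,
                    p["probe_idx"],
                    p["target_idx"],
                    dwin,
                    config.probe_mode,
                )
                _write_csv(
                    pd.DataFrame(
                        {"time_ps": traj.times[widx], "distance_A": d.samples}
                    ),
                    cdir / f"distance_{p['name']}.csv",
                )
                summary["distances"][p["name"]] = d.summary()

            lag, msd_vals = msd(traj, ca_idx, masses)
            _write_csv(
                pd.DataFrame({"lag_ps": lag, "msd_A2": msd_vals}), cdir / "msd.csv"
            )

            bridges = salt_bridges(
                traj.coords[0], structure, config.salt_bridge_cutoff, strict=False
            )
            _write_csv(
                pd.DataFrame(
                    [
                        (f"{a[0]}:{a[1]}", f"{b[0]}:{b[1]}", d)
                        for a, b, d in bridges
                    ],
                    columns=["res_a", "res_b", "min_distance_A"],
                ),
                cdir / "salt_bridges.csv",
            )
            summary["n_salt_bridges"] = len(bridges)
            summary["wall_s"] = round(time.perf_counter() - t0, 3)
            manifest["conditions"][cond.name] = summary
            if not quiet:
                print(
                    f"[{cond.name}] {traj.n_frames} frames analysed in "
                    f"{summary['wall_s']} s"
                )

        for a, b in config.delta_rmsf_pairs:
            key = f"{a}__vs__{b}"
            d = delta_rmsf(rmsf_by_condition[a], rmsf_by_condition[b])
            _residue_csv(d, "delta_rmsf_A", out_root / "pairs" / key / "delta_rmsf.csv")
            manifest["pairs"].setdefault(key, {})["delta_rmsf_max"] = float(
                d.values.max()
            )

        for a, b in config.displacement_pairs:
            key = f"{a}__vs__{b}"
            pdir = out_root / "pairs" / key
            disp = final_displacement(endpoints[a], endpoints[b], structure, ca_idx)
            _residue_csv(disp, "displacement_A", pdir / "displacement.csv")
            vecs = displacement_vectors(
                endpoints[a],
                endpoints[b],
                structure,
                ca_idx,
                config.displacement_threshold,
            )
            _write_csv(
                pd.DataFrame(
                    [
                        (k[0], k[1], *s, *e)
                        for k, s, e in vecs
                    ],
                    columns=[
                        "monomer",
                        "residue_index",
                        "start_x",
                        "start_y",
                        "start_z",
                        "end_x",
                        "end_y",
                        "end_z",
                    ],
                ),
                pdir / "vectors.csv",
            )
            manifest["pairs"].setdefault(key, {}).update(
                {
                    "displacement_max_A": float(disp.values.max()),
                    "n_vectors": len(vecs),
                }
            )
        manifest["complete"] = True
    finally:
        (out_root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_root


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(
    out_dir: str | Path, scale: str = "tiny", seed: int = 1234
) -> list[str]:
    """Write the canonical synthetic dataset: ambient + 4 directions × 4 strengths.

    ``tiny`` uses 50 frames per condition, ``standard`` 2000.  One shared
    topology (the straight ambient reference) is written at the root; each
    condition directory holds a multi-model PDB trajectory and the
    generator's ground-truth JSON.  All conditions share one seed, so
    paired comparisons across conditions see the same noise realisation
    (common random numbers) and differ only through the field terms.
    """
    if scale not in ("tiny", "standard"):
        raise ValueError(f"unknown scale {scale!r}")
    n_frames = 50 if scale == "tiny" else 2000
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    amb = preset("ambient", 0.0, n_frames=n_frames, seed=seed)
    structure = build_synthetic_dimer(amb)
    write_structure(structure, out / "topology.pdb", out / "annotations.tsv")
    conditions: list[tuple[str, GeneratorParams]] = [("ambient", amb)]
    for name in FIELD_PRESETS:
        for strength in FIXTURE_STRENGTHS:
            conditions.append(
                (
                    f"{name}_{int(strength)}",
                    preset(name, strength, n_frames=n_frames, seed=seed),
                )
            )
    config = {
        "topology": "topology.pdb",
        "annotations": "annotations.tsv",
        "output": "analysis",
        "frame_interval": amb.frame_interval,
        "conditions": {},
        "pairs": {
            "displacement": [["pos_transverse_750", "neg_transverse_750"]],
            "delta_rmsf": [["pos_transverse_750", "ambient"]],
        },
    }
    names = []
    for name, params in conditions:
        cdir = out / name
        cdir.mkdir(exist_ok=True)
        traj, truth = generate_trajectory(structure, params)
        write_trajectory(traj, structure, cdir / "trajectory.pdb")
        truth.to_json(cdir / "ground_truth.json")
        config["conditions"][name] = {
            "trajectory": f"{name}/trajectory.pdb",
            "field": {
                "rule": params.field.direction_rule,
                "magnitude": params.field.magnitude,
                "window": [float(params.field.window[0]), float(params.field.window[1])],
            },
        }
        names.append(name)
    (out / "run.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return names
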