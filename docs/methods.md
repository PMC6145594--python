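# Methods

This note documents the models, conventions and numerical choices behind
`eeftraj`, in the order a reader meets them: measurement stages first, then
the synthetic generator whose ground truth the tests recover.

## Coordinate and unit conventions

Coordinates are Å, times ps, charges e, masses amu, fields kV/cm
(conversions to V/Å and V/m are exact: 1 kV/cm = 1e-5 V/Å = 1e5 V/m),
dipoles e·Å with 1 e·Å = 4.80321 D. Residue indices are 1-based and
contiguous within each monomer ("ungapped"); the monomers are `alpha`
(PDB chain A) and `beta` (chain B). Time windows are half-open
`[t_start, t_end)`; a trajectory frame at time t belongs to the window iff
`t_start ≤ t < t_end`. All analyses consume a single annotated topology
(PDB plus a TSV sidecar carrying charge, mass, named region and
secondary-structure class per atom) and multi-model PDB trajectories
(DCD readable as an option); parsing is delegated to MDAnalysis.

## Superposition and RMSD

Rigid-body fits use the SVD (Kabsch) solution with reflections excluded:
if the determinant of the candidate rotation is −1 the smallest singular
vector is sign-flipped, so the result is always a proper rotation. Fewer
than three points, or a collinear point set, is an error — the rotation is
under-determined and silently returning one would poison every downstream
stage. Weights default to uniform for Cα work (the common convention);
mass weighting is available by passing masses.

`rmsd_series` fits each frame to a reference (the first frame by default —
the series then measures change since field onset when the trajectory
starts there) over a *fit* selection and reports RMSD over a *measure*
selection. The by-secondary-structure variant partitions Cα atoms into
helix+sheet vs everything else with one shared fit, so the two series are
directly comparable; an empty partition yields `None` rather than an
error.

## RMSF and ΔRMSF

RMSF is computed about the iterated mean: frames are fitted to the plain
frame average, the average is recomputed from fitted frames, and frames
are fitted once more. One refinement pass removes essentially all
rigid-body inflation; further iterations change the answer by less than
numerical noise on every fixture we generate. For a free atom with
isotropic per-coordinate noise σ the estimator converges to σ√3, which the
tests check in closed form. ΔRMSF is a plain per-residue subtraction
(field minus ambient, so positive means the field increased fluctuation);
it is exactly antisymmetric and requires identical residue key sets.

The default RMSF window is the field-on window of the condition being
analysed (and the matching time window of the ambient run), since that is
the interval over which exposure effects are stationary in the generator.

## Secondary-structure counts

`labels` mode trusts the static annotations and returns constant per-frame
counts. `ca_geometry` mode classifies each frame from the Cα trace alone
with P-SEA-style distance criteria: helix when Cα(i)–Cα(i+3) ∈ [4.8, 6.2] Å
and Cα(i)–Cα(i+4) ∈ [5.8, 7.2] Å (marking residues i..i+4), sheet when
Cα(i)–Cα(i+2) ∈ [6.4, 7.4] Å along a run whose pseudo-dihedral is within
45° of trans. The thresholds are locked by tests on ideal helix geometry
(≥16 of 20 residues called helical) and on a fully extended chain (zero
calls). This is deliberately not a DSSP/STRIDE reimplementation — no
hydrogen-bond geometry is available from a Cα trace.

## Curvature (bend angle) and elongation

The bend angle superposes the study frame on a straight reference using
the α:H7 atoms only (anchoring the α monomer), fits a total-least-squares
line — centroid plus first principal axis — through designated H7 atoms of
each structure, and reports the angle between the two lines folded to
[0°, 90°] (lines have no sense). Two line conventions are first-class:

* `combined` (default): one line through α:H7 ∪ β:H7 per structure;
* `beta_only`: one line through each structure's β:H7.

Both are reported because the literature's phrasing of the measurement is
ambiguous between them; `beta_only` reads a constructed rigid rotation of
the β monomer back exactly, while `combined` mixes in the fixed α anchor.
Axis fits refuse isotropic clouds (relative eigengap below 1e-6) and
coincident points. The fitted direction's sign follows the input ordering
(first → last atom), giving a stable α→β sense.

Elongation is the distance between mass-weighted centres of the two
monomers' helix-class atoms, using the annotations of the reference
structure (helix membership is static).

## Distances, mean structures, MSD

Loop-opening observables are per-frame distances from a probe residue to
the centre of mass of a target region. The probe point is the residue COM
by default (`sidechain_tip` and `ca` modes available) — the residue-level
definition is robust to which side-chain atoms a reduced representation
carries. Distributions report mean, linear-interpolation quartiles, and a
normalised histogram.

Windowed mean structures fit every window frame to the first window frame
before atom-wise averaging. MSD uses the selection's COM with sliding time
origins by default (single-origin variant by flag) and lags up to a
quarter of the window; for free diffusion the slope is 6D.

## Electrostatics and salt bridges

Dipoles are computed purely from fixed partial charges. The heterodimer
carries a net charge, so the dipole depends on the reference point; the
default is the system COM and the reference is recorded in every output
record. Hydrogens are simply whatever atoms the annotation table lists —
the reduced synthetic topology carries none. The transverse axis is the
unit dipole of the reference structure; the longitudinal axis is the unit
β→α COM vector; negative field directions are exact negations.

Salt bridges pair acidic side-chain oxygens (OD1/OD2, OE1/OE2, OXT) with
basic side-chain nitrogens (NZ, NE/NH1/NH2) at an inclusive distance
cutoff, 3.2 Å by default, one report per residue pair with the minimum
O–N distance. Histidine nitrogens are excluded by default (the
δ-protonated tautomer is neutral); a flag includes them. Detection is
checked against an all-pairs brute-force scan.

## The synthetic generator

### What it emulates

The generator reproduces, with known parameters, the statistical features
the analyses are sensitive to: a rigid two-monomer core ("close to 1 Å"
Cα RMSD for helix/sheet residues), flexible charged loops and tails whose
RMSD runs 2–3 Å ambient and 5–6 Å under a 750 kV/cm field, field-coupled
mean shifts of charged residues along the field direction, a stationary
per-residue fluctuation spectrum, frame-wise bend and elongation
distributions, and whole-dimer diffusion.

Geometry: each monomer is two ideal α-helix segments (rise 1.5 Å, 100°
per residue, radius 2.3 Å) joined by an interior loop (α:H1-B2 / β:M-loop,
bulging +y with one +1e and one −1e residue) and finished by a charged
C-terminal tail (−1e per residue, dangling −y). The central stretch of the
long segment is labelled H7; the end of the first segment is labelled H3.
The β monomer sits below the α monomer with helix-atom COMs exactly
`elong_mean` apart along +z, so the longitudinal axis is +z by
construction and the net dipole (dominated by the tails) points roughly
+y. Charged residues carry a single side-chain tip atom (NZ/OD1/OE1) 1.6 Å
outward from the Cα.

### Frame model

Per frame t:

1. start from the straight reference; while the field window is on, shift
   every atom of a flexible residue by `coupling · q · E` along the field
   unit vector (applied instantaneously at window start — relaxation is an
   observation for downstream stages, not a generator feature);
2. rigidly place the β monomer: rotate about the +y axis through the
   pivot (midpoint of the two helix-COMs) and translate along the current
   COM-separation direction so the helix-COM distance equals the frame's
   elongation draw e_t ~ N(elong_mean, elong_sd);
3. add per-atom OU noise with the exact discrete update
   x ← μ + (x−μ)e^(−Δ/τ) + N(0, σ²(1−e^(−2Δ/τ))), stationary SD σ_core
   for core atoms and σ_loop for flexible atoms, correlation time τ;
4. add the dimer-wide Brownian offset (cumulative N(0, 2DΔ) per
   coordinate).

One seeded NumPy generator drives everything, consumed in a fixed block
order (bend draws, elongation draws, Brownian steps, then OU innovations
frame-major), so trajectories are bit-reproducible for a given seed.

### The bend parameter is the observable

`bend_mean`/`bend_sd` parameterise the *measured* combined-mode bend
angle, not the raw rotation applied to β. For each frame the generator
draws θ_t ~ N(bend_mean, bend_sd) and numerically inverts the noiseless
measurement (Brent root-finding on the rotation angle, using that frame's
elongation draw) so that the curvature stage applied to the noiseless
geometry returns exactly θ_t; the draws and the applied rotations are both
recorded in the ground truth. With a midpoint pivot the applied rotation
is roughly twice the measured combined-mode angle, which is why defining
the parameter on the observable side is the only convention under which
"generate with mean m, measure, recover m" is an identity rather than a
pivot-dependent coincidence. Negative draws (rare at the default means)
rotate the other way and fold to |θ| under measurement, a sub-0.01°
effect on the mean at the preset parameters.

### Presets and calibration

| parameter | ambient | field presets (E in kV/cm) | why |
|---|---|---|---|
| bend_mean (deg) | 5.9 | linear from 5.9 to the 750-value: neg_transverse 8.2, pos_transverse 6.4, longitudinals 6.9 | 5.9/8.2 are the study's unexposed and negative-transverse means; the other 750-values are synthetic choices ordered so the negative transverse shows the greatest change |
| bend_sd (deg) | 2.0 | 2.0 | plausible frame-to-frame spread; no reported value |
| elong_mean (Å) | 45.0 | +0.5 (transverse) / +1.5 (longitudinal) at 750, linear in E | all directions elongate, longitudinal most; magnitudes synthetic |
| elong_sd (Å) | 0.5 | 0.5 | small stationary breathing |
| σ_core (Å) | 0.30 | 0.30 | √6·σ ≈ 0.75 Å core RMSD contribution, keeping the rigid partition near 1 Å |
| σ_loop (Å) | 1.0 | 1.0·(1+E/750) | ambient flexible RMSD √6·σ ≈ 2.4 Å (target range 2–3); widening under field feeds positive ΔRMSF on flexible residues |
| coupling (Å per e·kV/cm) | — | 0.006 | with σ_loop(750)=2.0 puts flexible RMSD at ≈5.9 Å in the 5–6 target range (error budget: 6σ² OU + charged-fraction·shift² + rigid-placement variance) |
| τ (ps) | 100 | 100 | slow loop relaxation; ≈0.78 frame-to-frame correlation at 25 ps |
| D (Å²/ps) | 0.005 | 0.005 | protein-scale translational diffusion (~5×10⁻⁷ cm²/s) |
| frames / interval | 2000 × 25 ps (standard), 50 (tiny) | same | 25 ps matches the archival save interval; 2000 frames keep standard-scale runs in seconds |

The field window opens after the first 20% of frames and stays on, so the
first frame is a pre-exposure reference for RMSD and any "last half"
window is fully exposed. RMSD-range calibration targets (2–3 Å / 5–6 Å /
~1 Å) are ranges the generator is tuned into, documented here — they are
not claims about any particular real trajectory.

The canonical fixture set (`eef fixtures`) is ambient plus four directions
× {50, 100, 200, 750} kV/cm — 17 conditions sharing one seed. Sharing the
seed is deliberate (common random numbers): paired comparisons across
conditions — ΔRMSF signs, probe-distance monotonicity in field strength,
opposite-direction displacement — then isolate the field terms instead of
resampling noise.

### What the generator does not emulate

No solvent, no forces, no electrostatic self-consistency: the field acts
only through the prescribed mean shifts. Secondary structure is static
(no field-induced unfolding), the bend/elongation draws are i.i.d. across
frames rather than autocorrelated, there is no post-exposure relaxation
transient, and the reduced topology has no backbone beyond Cα and no
hydrogens. Passing recovery tests therefore demonstrates the correctness
of the estimators and their conventions, not the physics of any real
dimer.

## Pipeline

`run_pipeline` validates the whole config before writing anything (every
named selection must resolve; every pair must reference a declared
condition), runs each stage per condition and the pairwise stages, and
writes a manifest whose summary numbers are exactly the unit-level
outputs. CSV floats are written at fixed precision so reruns are
byte-identical; the manifest carries a SHA-256 config hash over the
semantically meaningful fields. Distribution-type observables (bend,
elongation, distances) default to the last half of each trajectory — the
fully-exposed stationary stretch under the preset windows — and the window
is overridable. Conditions are independent and may be executed in any
order with identical results.

## Known limitations

* The curvature measurement's combined mode has a small noise-induced
  positive bias (second order in the H7 anchor jitter, ≈0.05–0.08° at the
  default σ_core); it is visible only because the recovery tolerances are
  tight, and it is part of what the 2-standard-error recovery check
  absorbs.
* `beta_only` bend mode reads back the applied β rotation, which under the
  observable-defined bend parameter is larger than the combined-mode
  value; the two modes are different observables and are reported side by
  side, never mixed.
* DCD reading requires the atom count from the annotated topology; DCD
  writing is not provided (multi-model PDB is the interchange dialect).
* The Cα-geometry secondary-structure classifier is distance-based only
  and is not a substitute for hydrogen-bond-aware assignment on real
  all-atom structures.
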