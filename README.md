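# cxcaxis

Post-simulation analysis toolbox for studies of chemokine-receptor
activation and small-molecule antagonism, built around the CXCR6–CXCL16
axis. It covers the three analysis layers such studies chain together:

1. **Trajectory geometry** — per-segment RMSD/RMSF, receptor–chemokine
   center-of-mass distance, neighbor-count ("gromos"/Daura) conformational
   clustering, representative-frame selection against the average
   structure, and per-helix rotation axis/angle series for the seven
   transmembrane (TM) segments of a GPCR.
2. **Interaction analysis** — heavy-atom polar-contact detection between TM
   segments and across the receptor–chemokine interface (H-bond ≤ 3.35 Å,
   ionic ≤ 4.0 Å, hydrophobic ≤ 3.9 Å), the Asp–Arg "arginine cage" state
   of the DRF motif (Asp126-Arg127-Phe128), and contact persistence across
   frames.
3. **Ligand modelling** — docked-pose clustering at a 2 Å RMSD cutoff,
   rule-based pharmacophore features (HAc, HDn, Arm, Hph, PIn, NIn),
   a PAM (k-medoids) consensus "general protein–ligand interaction model"
   ranked by summed pIC50, and CoMFA-style 3D-QSAR: steric (Lennard-Jones
   6-12, sp³-carbon probe) and electrostatic (Coulomb, ε = r) fields on a
   lattice, regressed against pIC50 by PLS with leave-one-out
   q² = 1 − PRESS/TSS, training R², F = (R²/k)/((1−R²)/(n−k−1)), and
   repeated random 28% test splits with the q² > 0.5, R² ≥ 0.85 selection
   rule.

A seeded synthetic-data module generates every input the pipeline needs —
an idealized 7-helix bundle with CXCR6's UniProt segment numbering,
trajectories with planted helix rotations or approach schedules, pose sets
with planted clusters, and an aligned 82-member pseudo-ligand series with
planted pharmacophore hotspots and a planted linear field→pIC50 relation —
each with a ground-truth record, so every stage is testable end to end
without any external structures.

## Worked example

Recovering planted helix rotations (`examples/01_helix_rotations.py`):

```text
helix  planted  recovered  error (deg)
TM1        5.0      4.945  0.055
TM2       10.0     10.236  0.236
...
TM7       35.0     35.372  0.372
```

Each helix of the bundle was rigidly rotated by a known angle about its own
axis and 0.1 Å of coordinate noise added; the analysis recovers every angle
to a fraction of a degree, the regime where TM rotations in a microsecond
trajectory can be read off reliably.

Building the consensus interaction model
(`examples/03_consensus_pharmacophore.py`):

```text
type  ligands  sum pIC50   medoid (Å)            error vs truth
HDn        40      275.9   [  0.04,   6.96,   0.02]   0.06
Hph        32      229.8   [ -4.97,  -3.99,   1.85]   0.15
HAc        32      227.2   [  6.88,  -0.07,   0.12]   0.18
```

Exactly the three planted hotspot types are selected, each medoid within
0.2 Å of the planted position, ranked by summed activity.

The QSAR suite (`examples/04_field_qsar.py`) fits ten random-split PLS
models on the planted-signal series; with the true-indicator model at
R² ≈ 0.9, every split passes the q² > 0.5 / R² ≥ 0.85 rule (best model:
q² 0.89, R² 0.92, 23 of 82 compounds held out), while a pure-noise response
selects zero models.

The library is used from Python (see `examples/`); a thin `cxcaxis` command
wraps the same stages for shell use (`cxcaxis run config.yaml`,
`cxcaxis simulate|trajmetrics|contacts|pharmacophore|qsar ...`).

## Layout

```
src/cxcaxis/      io, metrics, contacts, pharmacophore, qsar,
                  synthetic, pipeline, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   model assumptions, parameter defaults, limitations
```
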