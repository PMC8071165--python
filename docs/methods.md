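# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators emulate,
and the design decisions taken where the methodology was genuinely open.

## Coordinate and unit conventions

Coordinates are Å, times ns, energies kcal/mol, charges elementary units.
Residue numbering is author/UniProt numbering, 1-based, with inclusive
ranges. The default segment map carries CXCR6's (UniProt O00574) seven TM
ranges — TM1 33–59, TM2 69–89, TM3 104–128, TM4 144–164, TM5 188–215,
TM6 232–259, TM7 276–293 — with the DRF motif 126–128 inside TM3. Loop
ranges are the gaps between consecutive TMs (ICL1, ECL1, ICL2, ECL2, ICL3,
ECL3 alternating), the N-terminus is 1–32 and the C-terminus 294–342
(342 = the UniProt sequence length; the termini are conventions, not
database annotations, and are overridable in any config).

## Trajectory geometry

**Superposition.** All fitted quantities go through weighted least-squares
rigid superposition (Kabsch, via quaternion-based `align_vectors`). The
rotation angle is reported in [0, 180]°, the axis as a unit vector;
degenerate inputs (fewer than three points, collinear points) raise rather
than returning an arbitrary frame. Angle extraction uses the quaternion
magnitude, which is stable at 180°.

**RMSD series** superpose each frame on a fit selection (CA atoms by
default — the alignment level used for coarse-grained receptor models
back-converted to all-atom, where side-chain placement is not trustworthy)
and report the unfitted RMSD of the analysis selection; the reference frame
therefore reads exactly zero. **RMSF profiles** superpose frames on the fit
selection's average structure and average atomic fluctuations per residue.
**Center-of-mass distances** are geometric by default, mass-weighted on
request.

**Conformational clustering** is the neighbor-count scheme: on the pairwise
fitted-RMSD matrix, the frame with the most neighbors within the cutoff
becomes a cluster center, the cluster is removed, and the process repeats.
Ties break to the lowest frame index everywhere, so results are
deterministic; cluster ids are ordered by decreasing size.

**Representative frames** are chosen as the frame with the smallest fitted
RMSD to the uniform-weight average structure — the "average structure"
procedure used to pick per-window representatives across replicas.

**Helix rotations.** Per frame, the receptor may first be superposed on a
global fit selection (all receptor CA atoms) to remove rigid-body tumbling;
the per-helix transform is then the Kabsch rotation between the reference
and current helix CA coordinates. Angles are reported relative to the first
frame (the minimized start used as the control) by default;
`relative_to="previous"` reports frame-to-frame increments instead, since
published rotation plots do not always state which of the two they show.
De-tumbling is a knob rather than always-on: on a bundle whose helices
rotate internally, the global fit is itself slightly biased, so recovery
tests against planted rotations run with it disabled and no planted
tumbling.

Accuracy: with CA-only fitting, the angle estimator's standard error on an
18-residue helix (CA radius 2.3 Å) is ≈ 0.6° per 0.1 Å of RMS coordinate
noise — sub-degree recovery is achievable at that noise level and is what
the acceptance checks verify.

## Contact criteria

Criteria are heavy-atom only with no angle term: the frames this stage
consumes are back-converted from coarse-grained beads, where hydrogen
positions would be fabricated. Cutoffs follow LigPlot+/HBPLUS practice and
are configurable: hydrogen bond 3.35 Å between a donor-capable and an
acceptor-capable N/O; ionic 4.0 Å between Asp/Glu carboxylate oxygens and
Lys NZ / Arg guanidinium nitrogens (His ring nitrogens only with
`his_charged=True`); hydrophobic 3.9 Å between side-chain carbons of
apolar residues. Donor/acceptor capability comes from a fixed
residue→atom table (backbone N donor except proline, backbone O acceptor,
plus the usual side-chain sets). A residue pair may carry several kinds at
once; per pair and kind the closest qualifying atom pair is recorded.
Unknown residue names are skipped with a logged warning.

The arginine-cage state is the minimum over (OD1, OD2) × (NE, NH1, NH2)
distances against the ionic cutoff — intact at or below 4.0 Å, broken
above. Persistence is the fraction of analyzed frames in which a canonical
(pair, kind) key appears.

## Pharmacophore features and the consensus model

Feature rules (version 1), applied to the molecular graph with hydrogens
implicit:

| type | rule |
|------|------|
| HDn | N or O carrying ≥ 1 H, not positively charged |
| HAc | O not positively charged; N with no H, not amide N, not 3-coordinate aromatic N, not positively charged |
| Arm | 5/6-membered fully aromatic ring, centroid at ring center |
| Hph | connected group of ≥ 2 apolar atoms (C with only C/halogen heavy neighbors; halogens on such C) |
| PIn | formally positive atoms |
| NIn | formally negative groups; oxyanion features sit at the centroid of the equivalent terminal oxygens |

Two choices deserve justification. First, N–H nitrogens are donors only,
not acceptors: amide and pyrrole N are standard acceptor exclusions, amines
at physiological pH are borderline, and a donor feature that always drags a
co-located acceptor feature would make a donor-only consensus site
inexpressible. O–H oxygens remain both (a hydroxyl is genuinely
ambivalent). Second, the feature radius is the RMS spread of the matched
atoms floored at 1.0 Å, so single-atom features still occupy a sphere.

**Pose clustering** uses the same neighbor-count scheme on pose RMSD
*without* re-superposition — docked poses share the receptor frame, and
re-fitting them would erase exactly the binding-mode differences being
clustered. Representatives are the members with the most in-cluster
neighbors, ties to the best docking score then the lowest index.

**PAM.** Feature clustering per type uses k-medoids on
d = ‖Δcentroid‖ + λ·|Δradius| with λ = 0.5 (the radius term keeps features
of very different sizes apart; λ is a config knob). Small instances
(≤ 3000 candidate medoid sets) are solved exactly by enumeration — the
classic build+swap search is only locally optimal, and at these sizes the
global optimum is cheaper to find than to approximate; larger instances
use greedy BUILD plus steepest-descent SWAP, which is swap-optimal by
construction. Ties break to the lowest index throughout.

**k selection** maximizes the mean silhouette over k = 2…min(8, n−1)
(k = 1 when n < 4). The silhouette is undefined at k = 1, so a fallback is
required for the common case of a single compact feature cloud: when the
best achievable silhouette stays below 0.5 — the usual "reasonable
structure" threshold, below which a split is judged artificial — the type
is kept as one cluster. Without this, PAM fragments a tight cloud into
arbitrary shards whose per-shard ligand coverage falls below the selection
threshold.

**Selection and ranking.** Clusters are scored by summed member pIC50
(more active ligands pull their interaction points up the ranking) and
selected when their distinct-ligand coverage reaches 30% of the series;
both the weighting and the threshold are knobs, since no standard formula
exists for activity-weighted consensus selection. Receptor residues within
5 Å of a selected medoid annotate the model; residues shared between
features are flagged.

## 3D-QSAR

Fields use classical CoMFA defaults: 1.0 Å lattice spacing with a 4.0 Å
margin around the union bounding box of the aligned series; an sp³-carbon
probe (r_min 1.70 Å, ε 0.107 kcal/mol, charge +1); steric energy
E = Σ ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶] with Lorentz–Berthelot-style
combination from a small element-typed parameter table; electrostatic
energy E = 332.06·q/(ε(r)·r) with the distance-dependent dielectric
ε(r) = r; both truncated at ±30 kcal/mol, with the electrostatic value at
sterically forbidden points (steric at the cap) set to the cap and masked.

Pretreatment drops columns with SD < 0.1 kcal/mol and mean-centers the
rest, recomputed on every training set and every cross-validation fold —
anything else leaks held-out information into q². No block scaling by
default (a flag exists). The latent-variable fit is single-response PLS
(NIPALS; scikit-learn's `PLSRegression` with `scale=False`), validated in
the tests against an independently written NIPALS implementation to
machine precision. A response with exactly zero covariance against every
column reduces to the mean model rather than failing.

LOO q² = 1 − PRESS/TSS with each held-out sample predicted by a full refit
and TSS about the full-sample mean. The model suite draws
round(0.28·n) test compounds per seed (23 of 82), picks the number of
components (1…5) by training-set LOO q², and flags models passing
q² > 0.5 and R² ≥ 0.85; F = (R²/k)/((1−R²)/(n−k−1)) is reported alongside.
Predictive r² on the held-out set is recorded but not used for selection.
Contour extraction returns the grid points whose coefficient·SD products
fall in the top/bottom 20% per field, the analogue of the four colored
contour families of a field plot.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their arguments and seed
(bit-identical regeneration) and attach a ground-truth record to every
dataset.

* `make_helical_bundle` — ideal α-helices (1.5 Å rise, 100°/residue,
  CA radius 2.3 Å) on a 12 Å circle with alternating direction, straight
  loop/termini connectors, backbone dummies (N, CA, C, O), poly-Ala with
  ASP/ARG/PHE at 126–128. It reproduces the *geometry* a rotation analysis
  sees, not packing, side chains, or membrane context.
* `make_rotation_trajectory` — rigid per-helix rotations about each helix's
  own principal axis per a degree schedule; optional global tumbling and
  Gaussian jitter apply to frames after the first, the first frame being
  the clean minimized reference the analyses use as control. "Jitter" is
  RMS displacement in Å (per-coordinate σ = jitter/√3) — the convention
  used by every generator here.
* `make_approach_trajectory` — a particle blob whose geometric center sits
  exactly at d(t) from the receptor center along a fixed vector; it tests
  distance recovery, not binding physics.
* `make_pose_set` — translated/jittered copies of a base conformer around
  planted cluster centers with synthetic docking scores.
* `make_ligand_series` — pseudo-ligands: a rigid scaffold of isolated
  carbons (deliberately feature-free) plus real mini-fragments (ketone for
  HAc, methylamine for HDn, propane for Hph, benzene for Arm) at planted
  hotspot anchors, present per ligand with probability 0.5 (0.7 in
  consensus experiments so each hotspot clears the 30% coverage rule), a
  10% decoy rate at uniform random positions, 0.5 Å RMS anchor jitter, and
  pIC50 = 5.0 + 1.0·I₁ + 0.8·I₂ + 0.6·I₃ + N(0, 0.22) — the noise level at
  which the true-indicator model explains ≈ 90% of the activity variance,
  a realistic ceiling for a well-behaved congeneric series. Partial
  charges are Gasteiger. These molecules exercise the feature rules and
  the field algebra; they are not chemically sensible drugs, so passing
  tests demonstrate the *analyses* recover planted structure, not that the
  pipeline would rank real antagonists correctly.

## Problem sizes

Tests and the reproduction script run deliberately scaled-down instances:
2–30 frame trajectories of the full 342-residue bundle, 50–82 ligand
series, 2.0 Å QSAR lattices (≈ 4000 field columns), ten random splits with
full LOO on 59-compound training sets. These sizes keep every oracle
comparison exact (brute-force clustering, full refit loops, complete
medoid enumeration) while exercising the same code paths as full-scale
data.

## Known limitations

* No periodic-boundary handling beyond whole-molecule coordinates; inputs
  are assumed whole and unwrapped.
* Contact chemistry is table-driven for the 20 standard residues; modified
  residues are skipped with a warning rather than parameterized.
* Pose RMSD is computed atom-by-index; symmetry-equivalent atom relabeling
  (ring flips) is not searched, which can overestimate RMSD for symmetric
  ligands.
* The pharmacophore rule table is one defensible reading of standard
  practice; tools differ on amine/aromatic-N acceptor status, and the
  table is versioned so alternatives can be added without breaking
  existing models.
* π-stacking, cation–π and water-mediated bridges are out of scope, as are
  CoMSIA-style similarity fields and variable selection.
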