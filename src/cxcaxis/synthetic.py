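"""Deterministic seeded generators for every pipeline input.

Each generator is a pure function of its arguments and seed and attaches a
GroundTruth record of the planted parameters, so every downstream stage has
a recovery test with known truth and no external downloads:

* an idealized 7-helix bundle with the receptor's segment numbering,
* trajectories with planted per-helix rigid rotations (and optional global
  tumbling and coordinate jitter),
* chemokine-approach trajectories with a prescribed center-of-mass distance
  schedule,
* docked-pose sets with planted cluster structure,
* an aligned pseudo-ligand series with planted pharmacophore hotspots and a
  planted linear relation between hotspot occupancy and pIC50.

Pseudo-ligands are typed, charged atom sets on a shared scaffold rather
than full drug-like molecules; the feature-bearing substituents use real
mini-topologies (ketone, amine, alkyl, phenyl) so rule-based feature
extraction fires on genuine chemistry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .io import (LigandRecord, Pose, SegmentMap, Structure, Trajectory,
                 default_segment_map, ligand_from_rdkit, select_atoms)

HELIX_RISE = 1.5       # Å per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_CA_RADIUS = 2.3  # Å


@dataclass
class GroundTruth:
    """Planted parameters of one generated dataset."""

    kind: str
    seed: int | None
    data: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(type(obj))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=default,
                      sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# Helical bundle and rotation trajectories
# ---------------------------------------------------------------------------

def _helix_point(j: float, direction: float) -> np.ndarray:
    """Point on an ideal α-helix at fractional residue index j (local frame)."""
    ang = np.radians(HELIX_TWIST * j)
    return np.array([
        HELIX_CA_RADIUS * np.cos(ang),
        HELIX_CA_RADIUS * np.sin(ang),
        direction * HELIX_RISE * j,
    ])


def make_helical_bundle(
    segment_map: SegmentMap | None = None,
    radius: float = 12.0,
    last_residue: int | None = None,
    chain_id: str = "R",
) -> Structure:
    """Idealized 7-helix bundle with backbone dummy atoms (N, CA, C, O).

    Helices are ideal α-helices (1.5 Å rise, 100°/residue twist) placed on a
    circle of the given radius with alternating up/down direction; loop and
    terminal residues are straight-line connectors. Residue numbering
    follows the segment map; the DRF positions carry ASP/ARG/PHE names.
    """
    smap = segment_map or default_segment_map()
    tms = smap.tm_names()
    if len(tms) != 7:
        raise ValidationError(f"segment map has {len(tms)} TM ranges, need 7")
    if last_residue is None:
        last_residue = max(end for _, end in smap.segments.values())

    ca_pos: dict[int, np.ndarray] = {}
    helix_of: dict[int, tuple[np.ndarray, float, int]] = {}
    for h, name in enumerate(tms):
        start, end = smap.segments[name]
        n_res = end - start + 1
        theta = 2.0 * np.pi * h / 7.0
        center = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
        direction = 1.0 if h % 2 == 0 else -1.0
        for k, resid in enumerate(range(start, end + 1)):
            local = _helix_point(k - (n_res - 1) / 2.0, direction)
            ca_pos[resid] = center + local
            helix_of[resid] = (center, direction, k)

    # linear connectors for loops/termini between the helix anchor points
    anchors = sorted(ca_pos)
    for resid in range(1, last_residue + 1):
        if resid in ca_pos:
            continue
        prev = max((r for r in anchors if r < resid), default=None)
        nxt = min((r for r in anchors if r > resid), default=None)
        if prev is not None and nxt is not None:
            frac = (resid - prev) / (nxt - prev)
            ca_pos[resid] = ca_pos[prev] + frac * (ca_pos[nxt] - ca_pos[prev])
        elif prev is None:  # N-terminal extension
            step = np.array([0.0, 0.0, HELIX_RISE])
            ca_pos[resid] = ca_pos[nxt] + (nxt - resid) * step + np.array(
                [0.5 * (nxt - resid), 0.0, 0.0])
        else:  # C-terminal extension
            step = np.array([0.0, 0.0, -HELIX_RISE])
            ca_pos[resid] = ca_pos[prev] + (resid - prev) * step + np.array(
                [0.5 * (resid - prev), 0.0, 0.0])

    special = {126: "ASP", 127: "ARG", 128: "PHE"}
    names, elements, res_names, res_ids, coords = [], [], [], [], []
    for resid in range(1, last_residue + 1):
        ca = ca_pos[resid]
        if resid in helix_of:
            center, direction, k = helix_of[resid]
            n_xyz = center + _helix_point(k - 0.35, direction) * np.array(
                [1.6 / HELIX_CA_RADIUS, 1.6 / HELIX_CA_RADIUS, 1.0])
            c_xyz = center + _helix_point(k + 0.35, direction) * np.array(
                [1.6 / HELIX_CA_RADIUS, 1.6 / HELIX_CA_RADIUS, 1.0])
            o_xyz = center + _helix_point(k + 0.45, direction) * np.array(
                [2.4 / HELIX_CA_RADIUS, 2.4 / HELIX_CA_RADIUS, 1.0])
        else:
            n_xyz = ca + np.array([-0.5, 0.3, 0.0])
            c_xyz = ca + np.array([0.5, 0.3, 0.0])
            o_xyz = ca + np.array([0.7, 1.0, 0.3])
        for atom, el, xyz in (("N", "N", n_xyz), ("CA", "C", ca),
                              ("C", "C", c_xyz), ("O", "O", o_xyz)):
            names.append(atom)
            elements.append(el)
            res_names.append(special.get(resid, "ALA"))
            res_ids.append(resid)
            coords.append(xyz)
    n = len(names)
    return Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_names=np.array(res_names, dtype=object),
        res_ids=np.array(res_ids),
        chain_ids=np.array([chain_id] * n, dtype=object),
        coords=np.array(coords),
        title="synthetic 7-helix bundle",
    )


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    pivot = int(np.argmax(np.abs(axis)))
    if axis[pivot] < 0:
        axis = -axis
    return axis


def make_rotation_trajectory(
    bundle: Structure,
    schedules: dict[str, np.ndarray],
    jitter: float = 0.0,
    tumble: bool = False,
    seed: int = 0,
    segment_map: SegmentMap | None = None,
    time_step_ns: float = 100.0,
) -> tuple[Trajectory, GroundTruth]:
    """Trajectory with each helix rotated about its own principal axis.

    `schedules` maps TM names to per-frame rotation angles in degrees (all
    schedules must share a length, which sets the frame count). Optional
    global tumbling (rotation + translation) and Gaussian coordinate jitter
    of the given RMS displacement (Å) apply to frames after the first: the
    first frame is the clean minimized reference structure that later
    frames are analyzed against.
    """
    smap = segment_map or default_segment_map()
    lengths = {len(v) for v in schedules.values()}
    if len(lengths) != 1:
        raise ValidationError("all angle schedules must have the same length")
    n_frames = lengths.pop()
    rng = np.random.default_rng(seed)

    seg_atoms, seg_axis, seg_center = {}, {}, {}
    for name in schedules:
        all_idx = select_atoms(bundle, name, "all", smap)
        ca_idx = select_atoms(bundle, name, "CA", smap)
        seg_atoms[name] = all_idx
        ca = bundle.coords[ca_idx]
        seg_axis[name] = _principal_axis(ca)
        seg_center[name] = ca.mean(axis=0)

    frames = np.empty((n_frames, bundle.n_atoms, 3))
    tumbles = []
    for f in range(n_frames):
        coords = bundle.coords.copy()
        for name, angles in schedules.items():
            angle = float(angles[f])
            if angle != 0.0:
                rot = Rotation.from_rotvec(np.radians(angle) * seg_axis[name])
                idx = seg_atoms[name]
                coords[idx] = (coords[idx] - seg_center[name]) @ \
                    rot.as_matrix().T + seg_center[name]
        if tumble and f > 0:
            rotvec = rng.normal(size=3)
            rotvec *= rng.uniform(0, np.pi) / np.linalg.norm(rotvec)
            shift = rng.uniform(-10, 10, size=3)
            rot = Rotation.from_rotvec(rotvec)
            centroid = coords.mean(axis=0)
            coords = (coords - centroid) @ rot.as_matrix().T + centroid + shift
            tumbles.append({"frame": f, "rotvec": rotvec.tolist(),
                            "shift": shift.tolist()})
        if jitter > 0 and f > 0:
            coords = coords + rng.normal(0.0, jitter / np.sqrt(3.0),
                                         coords.shape)
        frames[f] = coords

    traj = Trajectory(topology=bundle, frames=frames,
                      times=np.arange(n_frames) * time_step_ns)
    truth = GroundTruth(
        kind="rotation_trajectory",
        seed=seed,
        data={
            "schedules_deg": {k: np.asarray(v).tolist()
                              for k, v in schedules.items()},
            "jitter": jitter,
            "tumble": tumble,
            "tumbles": tumbles,
            "time_step_ns": time_step_ns,
        },
    )
    return traj, truth


def make_approach_trajectory(
    receptor: Structure,
    d_schedule,
    n_particles: int = 20,
    direction=(1.0, 0.0, 0.0),
    seed: int = 0,
    time_step_ns: float = 100.0,
    chain_id: str = "Q",
) -> tuple[Trajectory, GroundTruth]:
    """Receptor plus an approaching particle blob at prescribed COM distances.

    The blob's geometric center sits exactly at d(t) from the receptor's
    geometric center along a fixed approach vector, so a center-of-mass
    distance analysis must recover the schedule."""
    d_schedule = np.asarray(d_schedule, dtype=float)
    if np.any(d_schedule <= 0):
        raise ValidationError("distance schedule must be positive")
    rng = np.random.default_rng(seed)
    unit = np.asarray(direction, dtype=float)
    unit = unit / np.linalg.norm(unit)
    blob_local = rng.normal(0.0, 2.0, size=(n_particles, 3))
    blob_local -= blob_local.mean(axis=0)
    receptor_com = receptor.coords.mean(axis=0)

    n = n_particles
    topo = Structure(
        atom_names=np.concatenate([receptor.atom_names,
                                   np.array(["CA"] * n, dtype=object)]),
        elements=np.concatenate([receptor.elements,
                                 np.array(["C"] * n, dtype=object)]),
        res_names=np.concatenate([receptor.res_names,
                                  np.array(["ALA"] * n, dtype=object)]),
        res_ids=np.concatenate([receptor.res_ids, np.arange(1, n + 1)]),
        chain_ids=np.concatenate([receptor.chain_ids,
                                  np.array([chain_id] * n, dtype=object)]),
        coords=np.vstack([receptor.coords,
                          receptor_com + d_schedule[0] * unit + blob_local]),
        title="synthetic approach system",
    )
    frames = np.empty((len(d_schedule), topo.n_atoms, 3))
    for f, d in enumerate(d_schedule):
        frames[f, :receptor.n_atoms] = receptor.coords
        frames[f, receptor.n_atoms:] = receptor_com + d * unit + blob_local
    traj = Trajectory(topology=topo, frames=frames,
                      times=np.arange(len(d_schedule)) * time_step_ns)
    truth = GroundTruth(kind="approach_trajectory", seed=seed,
                        data={"d_schedule": d_schedule.tolist(),
                              "direction": unit.tolist(),
                              "n_particles": n_particles})
    return traj, truth


def make_pose_set(
    base_coords: np.ndarray,
    centers,
    populations,
    jitter: float = 0.3,
    seed: int = 0,
    ligand_id: str = "LIG1",
) -> tuple[list[Pose], GroundTruth]:
    """Docked-pose set with planted cluster structure.

    Each pose is the base conformer translated to one of the cluster centers
    plus Gaussian jitter; cluster labels and synthetic docking scores are
    recorded in the truth."""
    base = np.asarray(base_coords, dtype=float)
    centers = [np.asarray(c, dtype=float) for c in centers]
    if len(centers) != len(populations):
        raise ValidationError("need one population per center")
    if len(centers) > 1:
        dmin = min(np.linalg.norm(a - b)
                   for i, a in enumerate(centers) for b in centers[i + 1:])
        if jitter >= dmin / 2:
            raise ValidationError("jitter must be < half the min center spacing")
    rng = np.random.default_rng(seed)
    poses, labels = [], []
    run = 0
    for label, (center, pop) in enumerate(zip(centers, populations)):
        for _ in range(int(pop)):
            coords = base + center + rng.normal(0.0, jitter / np.sqrt(3),
                                                size=(1, 3))
            score = float(rng.uniform(-11.0, -6.0))
            poses.append(Pose(ligand_id=ligand_id, coords=coords + 0.0,
                              docking_score=score, run_index=run))
            labels.append(label)
            run += 1
    truth = GroundTruth(kind="pose_set", seed=seed,
                        data={"labels": labels,
                              "centers": [c.tolist() for c in centers],
                              "populations": list(populations),
                              "jitter": jitter})
    return poses, truth


# ---------------------------------------------------------------------------
# Pseudo-ligand series
# ---------------------------------------------------------------------------

_SCAFFOLD_CARBONS = np.array([
    [0.0, 0.0, 0.0], [1.6, 0.0, 0.0], [3.2, 0.0, 0.0],
    [0.0, 1.6, 0.0], [1.6, 1.6, 0.0], [3.2, 1.6, 0.0],
])

DEFAULT_HOTSPOTS = (
    ("HAc", (7.0, 0.0, 0.0)),
    ("HDn", (0.0, 7.0, 0.0)),
    ("Hph", (-5.0, -4.0, 2.0)),
)


def _fragment_spec(kind: str):
    """(atoms, bonds) of the mini-fragment whose key feature sits at origin."""
    if kind == "HAc":  # ketone: acceptor O at origin
        atoms = [("O", (0.0, 0.0, 0.0)), ("C", (1.22, 0.0, 0.0)),
                 ("C", (2.0, 1.25, 0.0)), ("C", (2.0, -1.25, 0.0))]
        bonds = [(0, 1, 2.0), (1, 2, 1.0), (1, 3, 1.0)]
    elif kind == "HDn":  # methylamine: donor N at origin
        atoms = [("N", (0.0, 0.0, 0.0)), ("C", (1.47, 0.0, 0.0))]
        bonds = [(0, 1, 1.0)]
    elif kind == "Hph":  # propane: apolar centroid at origin
        atoms = [("C", (-1.26, 0.42, 0.0)), ("C", (0.0, -0.84, 0.0)),
                 ("C", (1.26, 0.42, 0.0))]
        bonds = [(0, 1, 1.0), (1, 2, 1.0)]
    elif kind == "Arm":  # benzene: ring centroid at origin
        ring = 1.39
        atoms = [("C", (ring * np.cos(a), ring * np.sin(a), 0.0))
                 for a in np.radians(np.arange(0, 360, 60))]
        bonds = [(i, (i + 1) % 6, 1.5) for i in range(6)]
    else:
        raise ValidationError(f"no fragment for feature kind {kind!r}")
    return atoms, bonds


def _build_pseudo_ligand(ligand_id: str, fragments):
    """RDKit molecule from scaffold carbons plus placed fragments."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    positions = []
    for xyz in _SCAFFOLD_CARBONS:
        mol.AddAtom(Chem.Atom("C"))
        positions.append(np.asarray(xyz, dtype=float))
    for kind, anchor in fragments:
        atoms, bonds = _fragment_spec(kind)
        offset = mol.GetNumAtoms()
        for el, xyz in atoms:
            mol.AddAtom(Chem.Atom(el))
            positions.append(np.asarray(xyz) + np.asarray(anchor))
        order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                     1.5: Chem.BondType.AROMATIC}
        for i, j, order in bonds:
            mol.AddBond(offset + i, offset + j, order_map[order])
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(positions):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    mol.SetProp("_Name", ligand_id)
    return mol.GetMol()


def make_ligand_series(
    n: int = 82,
    hotspots=DEFAULT_HOTSPOTS,
    presence_prob: float = 0.5,
    decoy_rate: float = 0.1,
    coefficients=(1.0, 0.8, 0.6),
    intercept: float = 5.0,
    noise_sigma: float = 0.22,
    jitter: float = 0.5,
    seed: int = 0,
) -> tuple[list[LigandRecord], pd.DataFrame, GroundTruth]:
    """Aligned pseudo-ligand series with planted hotspots and activities.

    Every ligand shares a rigid all-carbon scaffold; each hotspot fragment
    is present with `presence_prob` and, when present, placed at the
    hotspot anchor displaced by a Gaussian of RMS length `jitter`. With
    probability `decoy_rate` a ligand additionally carries one decoy
    fragment at a uniform random position. Activities follow
    pIC50 = intercept + sum(coef * indicator) + N(0, noise_sigma).
    """
    if n < 10:
        raise ValidationError("ligand series needs n >= 10")
    hotspots = list(hotspots)
    coefficients = list(coefficients)
    if len(coefficients) != len(hotspots):
        raise ValidationError("need one coefficient per hotspot")
    rng = np.random.default_rng(seed)
    decoy_kinds = ("HAc", "HDn", "Hph", "Arm")

    ligands, rows = [], []
    indicators = np.zeros((n, len(hotspots)), dtype=int)
    decoys = []
    for i in range(n):
        lid = f"L{i + 1:03d}"
        present = rng.random(len(hotspots)) < presence_prob
        indicators[i] = present.astype(int)
        fragments = []
        for h, (kind, anchor) in enumerate(hotspots):
            if present[h]:
                disp = rng.normal(0.0, jitter / np.sqrt(3.0), size=3)
                fragments.append((kind, np.asarray(anchor, dtype=float) + disp))
        lig_decoys = []
        if rng.random() < decoy_rate:
            kind = decoy_kinds[int(rng.integers(len(decoy_kinds)))]
            pos = rng.uniform(-9.0, 9.0, size=3)
            fragments.append((kind, pos))
            lig_decoys.append({"kind": kind, "position": pos.tolist()})
        decoys.append(lig_decoys)
        noise = float(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 0.0
        pic50 = float(intercept + np.dot(coefficients, indicators[i]) + noise)
        mol = _build_pseudo_ligand(lid, fragments)
        ligands.append(ligand_from_rdkit(
            mol, ligand_id=lid, ic50_um=10.0 ** (6.0 - pic50), pic50=pic50))
        rows.append({"ligand_id": lid, "ic50_um": 10.0 ** (6.0 - pic50),
                     "pic50": pic50})
    activities = pd.DataFrame(rows)
    truth = GroundTruth(
        kind="ligand_series",
        seed=seed,
        data={
            "hotspots": [{"type": k, "anchor": list(map(float, a))}
                         for k, a in hotspots],
            "indicators": indicators.tolist(),
            "coefficients": coefficients,
            "intercept": intercept,
            "noise_sigma": noise_sigma,
            "presence_prob": presence_prob,
            "decoy_rate": decoy_rate,
            "jitter": jitter,
            "decoys": decoys,
        },
    )
    return ligands, activities, truth


def write_ligands_sdf(ligands: list[LigandRecord], path) -> None:
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    try:
        for lig in ligands:
            if lig.mol is None:
                raise ValidationError(f"{lig.ligand_id}: no RDKit molecule")
            lig.mol.SetProp("_Name", lig.ligand_id)
            writer.write(lig.mol)
    finally:
        writer.close()
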