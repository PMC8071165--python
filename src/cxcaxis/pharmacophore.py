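"""Consensus protein-ligand interaction ("general") model construction.

From docked poses and activities: pose clustering at a fixed RMSD cutoff,
pharmacophore feature extraction (HAc/HDn/Arm/Hph/PIn/NIn) by a documented
rule table, partitioning-around-medoids (PAM) clustering of features by
nature/position/size, activity-weighted consensus selection, and annotation
of receptor residues within 5 Å of each consensus feature.

Feature rule table (version 1):
  HDn  N or O bearing >= 1 hydrogen, not positively charged
  HAc  O not positively charged; N with no hydrogens, not positively
       charged, not amide N, not 3-coordinate aromatic N
  Arm  5- or 6-membered fully aromatic ring (centroid = ring center)
  Hph  connected group of >= 2 apolar atoms (carbons whose heavy neighbors
       are all carbon or halogen; halogens attached to such carbons)
  PIn  formally positive atoms
  NIn  formally negative groups; for oxyanions the feature sits at the
       centroid of the equivalent terminal oxygens (e.g. carboxylate midpoint)

Nitrogens with hydrogens are donors only: at the consensus-model level a
planted donor hotspot must not drag an acceptor cluster with it, and amide
and pyrrole N are standard acceptor exclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, TopologyError, ValidationError
from .io import LigandRecord, Pose, Structure
from .metrics import neighbor_cluster

FEATURE_TYPES = ("HAc", "HDn", "Arm", "Hph", "PIn", "NIn")
_HALOGENS = {"F", "Cl", "Br", "I"}


def pic50_from_ic50(ic50_um: float) -> float:
    """pIC50 = -log10(IC50 in molar), with IC50 given in µM."""
    if ic50_um <= 0:
        raise ValidationError(f"IC50 must be positive, got {ic50_um}")
    return -math.log10(ic50_um * 1e-6)


@dataclass
class PharmacophoreFeature:
    """Typed interaction point of one ligand."""

    feature_type: str
    centroid: np.ndarray
    radius: float
    ligand_id: str = ""
    pic50: float = float("nan")

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValidationError(f"unknown feature type {self.feature_type!r}")
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.radius = max(1.0, float(self.radius))


@dataclass
class PoseCluster:
    members: list[int]
    representative: int
    population: int


@dataclass
class ConsensusCluster:
    feature_type: str
    medoid: np.ndarray
    member_count: int
    ligand_count: int
    sum_pic50: float
    mean_radius: float
    selected: bool
    member_indices: list[int] = field(default_factory=list)


@dataclass
class ConsensusModel:
    """PAM medoid summary of all ligand features; selected clusters first,
    ordered by summed pIC50 descending."""

    clusters: list[ConsensusCluster]
    n_ligands: int
    coverage_min: float

    @property
    def selected(self) -> list[ConsensusCluster]:
        return [c for c in self.clusters if c.selected]


# ---------------------------------------------------------------------------
# Pose clustering
# ---------------------------------------------------------------------------

def cluster_poses(poses: list[Pose], rmsd_cutoff: float = 2.0) -> list[PoseCluster]:
    """Neighbor-count clustering of docked poses at a fixed RMSD cutoff.

    Pose RMSD is computed without re-superposition — the poses share the
    receptor frame from docking. The representative of each cluster is the
    member with the most in-cluster neighbors within the cutoff; ties go to
    the best (lowest) docking score, then the lowest pose index. Clusters
    are returned largest first.
    """
    if not poses:
        raise ValidationError("no poses")
    n_atoms = poses[0].coords.shape[0]
    for p in poses:
        if p.coords.shape[0] != n_atoms:
            raise TopologyError(
                f"pose atom count mismatch: {p.coords.shape[0]} vs {n_atoms}"
            )
    n = len(poses)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.sqrt(np.mean(
                np.sum((poses[i].coords - poses[j].coords) ** 2, axis=1))))
            matrix[i, j] = matrix[j, i] = d
    clusters, _ = neighbor_cluster(matrix, rmsd_cutoff)
    out = []
    for members in clusters:
        scores = []
        for m in members:
            n_nb = sum(1 for other in members if matrix[m, other] <= rmsd_cutoff)
            ds = poses[m].docking_score
            scores.append((-n_nb, math.inf if ds is None else ds, m))
        rep = min(scores)[2]
        out.append(PoseCluster(members=members, representative=rep,
                               population=len(members)))
    out.sort(key=lambda c: -c.population)
    return out


def most_frequent_pose(poses: list[Pose], rmsd_cutoff: float = 2.0) -> Pose:
    """Representative of the largest pose cluster (the paper's 'most
    frequent binding conformation')."""
    clusters = cluster_poses(poses, rmsd_cutoff)
    return poses[clusters[0].representative]


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _mol_from_record(ligand: LigandRecord):
    if ligand.mol is not None:
        return ligand.mol
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for el in ligand.elements:
        mol.AddAtom(Chem.Atom(el))
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for i, j, order in ligand.bonds:
        mol.AddBond(int(i), int(j), order_map.get(float(order), Chem.BondType.SINGLE))
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(ligand.coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise ParseError(f"{ligand.ligand_id}: unsanitizable molecule ({exc})") from exc
    return mol.GetMol()


def _is_amide_n(atom) -> bool:
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() == "C":
            for bond in nb.GetBonds():
                other = bond.GetOtherAtom(nb)
                if (other.GetSymbol() == "O"
                        and bond.GetBondTypeAsDouble() >= 2.0):
                    return True
    return False


def _feature(ftype: str, coords: np.ndarray, ligand_id: str,
             pic50: float) -> PharmacophoreFeature:
    coords = np.atleast_2d(coords)
    centroid = coords.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))
    return PharmacophoreFeature(ftype, centroid, max(1.0, rms), ligand_id, pic50)


def extract_features(ligand, ligand_id: str | None = None,
                     pic50: float | None = None) -> list[PharmacophoreFeature]:
    """Pharmacophore features of one ligand (rule table in the module docstring).

    Accepts a LigandRecord or an RDKit Mol with a 3D conformer. Centroids
    are means of the matched atoms; the radius is the RMS spread, floored
    at 1.0 Å.
    """
    if isinstance(ligand, LigandRecord):
        mol = _mol_from_record(ligand)
        ligand_id = ligand.ligand_id if ligand_id is None else ligand_id
        if pic50 is None:
            pic50 = ligand.pic50 if ligand.pic50 is not None else float("nan")
    else:
        mol = ligand
        if ligand_id is None:
            ligand_id = mol.GetProp("_Name") if mol.HasProp("_Name") else "LIG"
    if pic50 is None:
        pic50 = float("nan")
    coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    features: list[PharmacophoreFeature] = []

    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        idx = atom.GetIdx()
        charge = atom.GetFormalCharge()
        n_h = atom.GetTotalNumHs()
        if sym in ("N", "O"):
            if n_h >= 1 and charge <= 0:
                features.append(_feature("HDn", coords[idx], ligand_id, pic50))
            if sym == "O" and charge <= 0:
                features.append(_feature("HAc", coords[idx], ligand_id, pic50))
            elif sym == "N" and charge <= 0 and n_h == 0:
                if not _is_amide_n(atom) and not (
                        atom.GetIsAromatic() and atom.GetDegree() >= 3):
                    features.append(_feature("HAc", coords[idx], ligand_id, pic50))

    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if len(ring) in (5, 6) and all(
                mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            features.append(_feature("Arm", coords[list(ring)], ligand_id, pic50))

    apolar = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "C" and all(
                nb.GetSymbol() == "C" or nb.GetSymbol() in _HALOGENS
                for nb in atom.GetNeighbors()):
            apolar.add(atom.GetIdx())
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in _HALOGENS and any(
                nb.GetIdx() in apolar for nb in atom.GetNeighbors()):
            apolar.add(atom.GetIdx())
    seen: set[int] = set()
    for start in sorted(apolar):
        if start in seen:
            continue
        group, stack = [], [start]
        while stack:
            a = stack.pop()
            if a in seen or a not in apolar:
                continue
            seen.add(a)
            group.append(a)
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                if nb.GetIdx() in apolar and nb.GetIdx() not in seen:
                    stack.append(nb.GetIdx())
        if len(group) >= 2:
            features.append(_feature("Hph", coords[sorted(group)], ligand_id, pic50))

    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() > 0:
            features.append(_feature("PIn", coords[atom.GetIdx()], ligand_id, pic50))
        elif atom.GetFormalCharge() < 0:
            group = [atom.GetIdx()]
            if atom.GetSymbol() == "O" and atom.GetDegree() == 1:
                parent = atom.GetNeighbors()[0]
                group = [
                    nb.GetIdx() for nb in parent.GetNeighbors()
                    if nb.GetSymbol() == "O" and nb.GetDegree() == 1
                ]
            features.append(_feature("NIn", coords[sorted(group)], ligand_id, pic50))

    return features


# ---------------------------------------------------------------------------
# PAM (k-medoids) and the consensus model
# ---------------------------------------------------------------------------

def feature_distance_matrix(features: list[PharmacophoreFeature],
                            lam: float = 0.5) -> np.ndarray:
    """d(a, b) = ||centroid_a - centroid_b|| + lam * |radius_a - radius_b|."""
    cents = np.array([f.centroid for f in features])
    radii = np.array([f.radius for f in features])
    diff = cents[:, None, :] - cents[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2)) + lam * np.abs(
        radii[:, None] - radii[None, :])


def pam_cluster(distance_matrix: np.ndarray, k: int,
                exact_limit: int = 3000):
    """Partitioning around medoids on a precomputed distance matrix.

    Small instances (C(n, k) <= `exact_limit` candidate medoid sets) are
    solved exactly by enumeration — build+swap PAM is only locally optimal,
    and at these sizes the global optimum is cheaper to find than to
    approximate. Larger instances use the classic Kaufman-Rousseeuw scheme:
    greedy BUILD seeding followed by steepest-descent SWAP over all
    (medoid, non-medoid) exchanges until no single swap lowers the cost.
    Either way the result is swap-optimal and all ties break to the lowest
    index. Returns (sorted medoid indices, assignment array mapping points
    to medoid positions, total cost).
    """
    import math as _math

    d = np.asarray(distance_matrix, dtype=float)
    n = len(d)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside 1..{n}")

    if _math.comb(n, k) <= exact_limit:
        import itertools

        best_cost, best_set = np.inf, None
        for subset in itertools.combinations(range(n), k):
            c = float(d[:, subset].min(axis=1).sum())
            if c < best_cost - 1e-12:
                best_cost, best_set = c, subset
        medoids = sorted(best_set)
        assignment = np.argmin(d[:, medoids], axis=1)
        return medoids, assignment, best_cost

    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        dmin = d[:, medoids].min(axis=1)
        best_gain, best_j = -1.0, None
        for j in range(n):
            if j in medoids:
                continue
            gain = float(np.maximum(dmin - d[:, j], 0.0).sum())
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    def cost(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    current = cost(medoids)
    while True:
        best = (current, None)
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                cand = list(medoids)
                cand[mi] = h
                c = cost(cand)
                if c < best[0] - 1e-12:
                    best = (c, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        current = best[0]

    medoids = sorted(medoids)
    assignment = np.argmin(d[:, medoids], axis=1)
    return medoids, assignment, cost(medoids)


def _choose_k(d: np.ndarray, k_max: int = 8, structure_min: float = 0.5) -> int:
    """k by maximum mean silhouette over 2..min(k_max, n-1); k=1 when n < 4.

    The silhouette is undefined for k=1, so a single compact feature cloud
    must not be force-split: when the best achievable silhouette stays below
    `structure_min` (0.5, the usual 'reasonable structure' threshold), the
    type is kept as one cluster.
    """
    from sklearn.metrics import silhouette_score

    n = len(d)
    if n < 4:
        return 1
    best_k, best_s = 1, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        _, labels, _ = pam_cluster(d, k)
        if len(set(labels.tolist())) < 2:
            continue
        s = silhouette_score(d, labels, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_s < structure_min:
        return 1
    return best_k


def build_general_model(
    features: list[PharmacophoreFeature],
    n_ligands: int | None = None,
    coverage_min: float = 0.30,
    lam: float = 0.5,
    k_max: int = 8,
    k_override: dict[str, int] | None = None,
) -> ConsensusModel:
    """Consensus interaction model from per-ligand features.

    Features are grouped by type ('nature') and PAM-clustered on position
    and size; per type, k maximizes the mean silhouette. Clusters are scored
    by summed member pIC50 and selected when their distinct-ligand coverage
    reaches `coverage_min` of the ligand series. Deterministic given inputs.
    """
    if not features:
        raise ValidationError("no features to build a model from")
    ligand_ids = sorted({f.ligand_id for f in features})
    if n_ligands is None:
        n_ligands = len(ligand_ids)
    if n_ligands < 2:
        raise ValidationError("consensus model needs >= 2 ligands")

    clusters: list[ConsensusCluster] = []
    for ftype in FEATURE_TYPES:
        group = [(i, f) for i, f in enumerate(features)
                 if f.feature_type == ftype]
        if not group:
            continue
        idx, feats = zip(*group)
        d = feature_distance_matrix(list(feats), lam)
        if k_override and ftype in k_override:
            k = k_override[ftype]
        else:
            k = _choose_k(d, k_max)
        medoids, labels, _ = pam_cluster(d, k)
        for m_pos, medoid in enumerate(medoids):
            members = [i for i, lab in enumerate(labels) if lab == m_pos]
            member_feats = [feats[i] for i in members]
            distinct = {f.ligand_id for f in member_feats}
            clusters.append(ConsensusCluster(
                feature_type=ftype,
                medoid=feats[medoid].centroid.copy(),
                member_count=len(members),
                ligand_count=len(distinct),
                sum_pic50=float(np.nansum([f.pic50 for f in member_feats])),
                mean_radius=float(np.mean([f.radius for f in member_feats])),
                selected=len(distinct) >= coverage_min * n_ligands,
                member_indices=[idx[i] for i in members],
            ))
    clusters.sort(key=lambda c: (not c.selected, -c.sum_pic50))
    return ConsensusModel(clusters=clusters, n_ligands=n_ligands,
                          coverage_min=coverage_min)


def annotate_residues(
    model: ConsensusModel,
    receptor: Structure,
    radius: float = 5.0,
    selected_only: bool = True,
):
    """Receptor residues with any heavy atom within `radius` of each cluster
    medoid, sorted by residue number; residues shared between clusters are
    returned separately (the bold convention of interaction tables)."""
    heavy = np.array([str(e).upper() != "H" for e in receptor.elements])
    coords = receptor.coords[heavy]
    res_ids = receptor.res_ids[heavy]
    res_names = receptor.res_names[heavy]
    clusters = model.selected if selected_only else model.clusters
    per_cluster: dict[int, list[tuple[int, str]]] = {}
    for ci, cluster in enumerate(clusters):
        if radius <= 0:
            per_cluster[ci] = []
            continue
        dist = np.linalg.norm(coords - cluster.medoid, axis=1)
        near = dist <= radius
        found = sorted({(int(r), str(nm))
                        for r, nm in zip(res_ids[near], res_names[near])})
        per_cluster[ci] = found
    counts: dict[int, int] = {}
    for residues in per_cluster.values():
        for rid, _ in residues:
            counts[rid] = counts.get(rid, 0) + 1
    shared = {rid for rid, c in counts.items() if c > 1}
    return per_cluster, shared
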