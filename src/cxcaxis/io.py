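"""Structures, trajectories, ligands, activities and segment definitions.

All coordinates are in Å, times in ns, energies in kcal/mol. Residue
numbering is author/UniProt numbering, 1-based, with inclusive ranges.

Standard formats go through established readers: PDB via biotite (single
structures and multi-model trajectories), XTC/DCD via MDAnalysis, SDF/MOL2
via RDKit, tables via pandas. The in-memory containers are thin array-backed
dataclasses shared by every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chemistry
from .errors import ParseError, SelectionError, TopologyError, ValidationError

# Transmembrane-segment residue ranges for CXCR6 (UniProt O00574), author
# numbering, inclusive. The DRF motif (Asp126-Arg127-Phe128) lies within TM3.
DEFAULT_TM_RANGES = {
    "TM1": (33, 59),
    "TM2": (69, 89),
    "TM3": (104, 128),
    "TM4": (144, 164),
    "TM5": (188, 215),
    "TM6": (232, 259),
    "TM7": (276, 293),
}
DEFAULT_LAST_RESIDUE = 342  # UniProt O00574 sequence length

_ATOM_FILTERS = ("all", "CA", "backbone", "sidechain", "polar-heavy")


@dataclass(frozen=True)
class AtomRecord:
    """One atom with chain/residue identity and Å coordinates."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: np.ndarray
    partial_charge: float | None = None
    mass: float | None = None


@dataclass
class Structure:
    """Ordered atom collection backed by parallel arrays."""

    atom_names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    charges: np.ndarray | None = None
    masses: np.ndarray | None = None
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        for name in ("atom_names", "elements", "res_names", "chain_ids"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        if self.coords.shape != (self.n_atoms, 3):
            raise ValidationError(
                f"coordinate array has shape {self.coords.shape}, "
                f"expected ({self.n_atoms}, 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        if np.any(self.res_ids < 1):
            raise ValidationError("residue numbers must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def validate_unique(self) -> None:
        keys = set()
        for i in range(self.n_atoms):
            key = (self.chain_ids[i], int(self.res_ids[i]), self.atom_names[i])
            if key in keys:
                raise ValidationError(f"duplicate atom {key}")
            keys.add(key)

    def atom_masses(self) -> np.ndarray:
        """Per-atom masses (Da), from the element table when not set."""
        if self.masses is not None:
            return np.asarray(self.masses, dtype=float)
        return np.array(
            [chemistry.ELEMENT_MASSES.get(str(e).upper(), 12.011) for e in self.elements]
        )

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        charges = self.charges if self.charges is not None else [None] * self.n_atoms
        masses = self.masses if self.masses is not None else [None] * self.n_atoms
        for i in range(self.n_atoms):
            yield AtomRecord(
                atom_name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.res_names[i]),
                residue_number=int(self.res_ids[i]),
                chain_id=str(self.chain_ids[i]),
                coordinates=self.coords[i].copy(),
                partial_charge=None if charges[i] is None else float(charges[i]),
                mass=None if masses[i] is None else float(masses[i]),
            )

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            atom_names=self.atom_names[idx],
            elements=self.elements[idx],
            res_names=self.res_names[idx],
            res_ids=self.res_ids[idx],
            chain_ids=self.chain_ids[idx],
            coords=self.coords[idx],
            charges=None if self.charges is None else np.asarray(self.charges)[idx],
            masses=None if self.masses is None else np.asarray(self.masses)[idx],
            title=self.title,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.subset(np.arange(self.n_atoms))
        out.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return out


@dataclass
class Trajectory:
    """A topology plus ordered coordinate frames (n_frames, n_atoms, 3)."""

    topology: Structure
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames have {self.frames.shape[1] if self.frames.ndim == 3 else '?'} "
                f"atoms, topology has {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise ValidationError("times and frames differ in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


@dataclass
class SegmentMap:
    """Named inclusive residue-number ranges (TM1..TM7, loops, termini, DRF)."""

    segments: dict[str, tuple[int, int]]
    chain: str | None = None

    def __post_init__(self) -> None:
        clean = {}
        for name, rng in self.segments.items():
            start, end = int(rng[0]), int(rng[1])
            if end < start:
                raise ValidationError(f"segment {name}: empty range {start}-{end}")
            clean[name] = (start, end)
        self.segments = clean
        tms = [n for n in self.segments if n.startswith("TM")]
        for i, a in enumerate(tms):
            for b in tms[i + 1:]:
                sa, ea = self.segments[a]
                sb, eb = self.segments[b]
                if sa <= eb and sb <= ea:
                    raise ValidationError(f"TM ranges overlap: {a} and {b}")

    def __contains__(self, name: str) -> bool:
        return name in self.segments

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.segments[name]

    def residues(self, name: str) -> list[int]:
        if name not in self.segments:
            raise SelectionError(
                f"unknown segment {name!r}; available: {sorted(self.segments)}"
            )
        start, end = self.segments[name]
        return list(range(start, end + 1))

    def tm_names(self) -> list[str]:
        return sorted(
            (n for n in self.segments if n.startswith("TM")),
            key=lambda n: self.segments[n][0],
        )


def default_segment_map(last_residue: int = DEFAULT_LAST_RESIDUE) -> SegmentMap:
    """CXCR6 segment defaults: TM ranges, DRF, loops inferred from the gaps
    between consecutive TMs (alternating intracellular/extracellular), and
    termini NH2T = 1-32, COOHT = 294-last."""
    segments = dict(DEFAULT_TM_RANGES)
    segments["DRF"] = (126, 128)
    segments["NH2T"] = (1, DEFAULT_TM_RANGES["TM1"][0] - 1)
    segments["COOHT"] = (DEFAULT_TM_RANGES["TM7"][1] + 1, last_residue)
    loop_names = ["ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3"]
    tms = ["TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7"]
    for i, loop in enumerate(loop_names):
        prev_end = DEFAULT_TM_RANGES[tms[i]][1]
        next_start = DEFAULT_TM_RANGES[tms[i + 1]][0]
        segments[loop] = (prev_end + 1, next_start - 1)
    return SegmentMap(segments)


def load_segment_map(config=None) -> SegmentMap:
    """Build a SegmentMap from a YAML path, a dict, or the built-in defaults.

    A config may override individual segments; unlisted segments keep their
    defaults. Overlapping TM ranges raise a validation error.
    """
    if config is None:
        return default_segment_map()
    if isinstance(config, SegmentMap):
        return config
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError(f"cannot build a segment map from {type(config)!r}")
    raw = config.get("segments", config)
    base = default_segment_map().segments
    for name, rng in raw.items():
        if isinstance(rng, str):
            parts = rng.replace("-", " ").split()
            rng = [int(p) for p in parts]
        base[str(name)] = (int(rng[0]), int(rng[1]))
    return SegmentMap(base, chain=config.get("chain"))


# ---------------------------------------------------------------------------
# PDB structures and trajectories
# ---------------------------------------------------------------------------

def _structure_from_atom_array(arr, title: str = "") -> Structure:
    import biotite.structure as struc  # noqa: F401  (annotation access)

    if "ins_code" in arr.get_annotation_categories():
        ins = arr.ins_code
        if np.any(ins != ""):
            bad = np.unique(arr.res_id[ins != ""])
            raise ParseError(
                f"insertion codes are not supported (residues {bad.tolist()})"
            )
    elements = arr.element
    fixed = [
        e if e else chemistry.element_from_atom_name(a)
        for e, a in zip(elements, arr.atom_name)
    ]
    return Structure(
        atom_names=arr.atom_name,
        elements=np.array(fixed, dtype=object),
        res_names=arr.res_name,
        res_ids=arr.res_id,
        chain_ids=arr.chain_id,
        coords=arr.coord,
        title=title,
    )


def _check_pdb_lines(path) -> None:
    """Locate malformed ATOM/HETATM coordinate fields, naming the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fld = line[lo:hi].strip()
                    try:
                        float(fld)
                    except ValueError:
                        raise ParseError(
                            f"{path}: malformed coordinate field {fld!r} "
                            f"on line {lineno}"
                        ) from None


def read_structure(path, fmt: str = "pdb") -> Structure:
    """Read a single-model PDB file into a Structure.

    Chain ids and author residue numbering are preserved verbatim; for files
    with alternate locations only the first altloc is kept.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if fmt.lower() != "pdb":
        raise ValidationError(f"unsupported structure format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="first")
    except ParseError:
        raise
    except Exception as exc:
        _check_pdb_lines(path)
        raise ParseError(f"{path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return _structure_from_atom_array(arr, title=path.stem)


def write_structure(structure: Structure, path) -> None:
    """Write a Structure to PDB (coordinates at the format's 1e-3 Å precision)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = struc.AtomArray(structure.n_atoms)
    arr.coord = structure.coords.astype(np.float32)
    arr.atom_name = structure.atom_names.astype(str)
    arr.element = structure.elements.astype(str)
    arr.res_name = structure.res_names.astype(str)
    arr.res_id = structure.res_ids
    arr.chain_id = structure.chain_ids.astype(str)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_trajectory(topology_path, traj_path=None, fmt: str | None = None) -> Trajectory:
    """Read a trajectory: multi-model PDB, or XTC/DCD with a PDB topology.

    Frame order is preserved. Times are taken from the file when present,
    otherwise synthesized as 0, 1, 2, ... ns.
    """
    topology_path = Path(topology_path)
    if traj_path is None:
        traj_path = topology_path
    traj_path = Path(traj_path)
    if fmt is None:
        fmt = traj_path.suffix.lstrip(".").lower() or "pdb"
    fmt = fmt.lower().replace("multi-model pdb", "pdb")

    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        if traj_path.stat().st_size == 0:
            raise ParseError(f"{traj_path}: empty file")
        pdb = PDBFile.read(str(traj_path))
        stack = pdb.get_structure(altloc="first")
        coords = np.atleast_3d(stack.coord)
        if coords.ndim == 2:  # single model
            coords = coords[None, :, :]
        topo = _structure_from_atom_array(stack[0] if coords.shape[0] else stack,
                                          title=traj_path.stem)
        frames = coords.astype(float)
        times = np.arange(len(frames), dtype=float)
        return Trajectory(topology=topo, frames=frames, times=times)

    if fmt in ("xtc", "dcd"):
        import MDAnalysis as mda

        topo = read_structure(topology_path)
        uni = mda.Universe(str(topology_path), str(traj_path))
        if uni.atoms.n_atoms != topo.n_atoms:
            raise TopologyError(
                f"atom count mismatch: topology has {topo.n_atoms}, "
                f"trajectory has {uni.atoms.n_atoms}"
            )
        frames, times = [], []
        for ts in uni.trajectory:
            frames.append(ts.positions.astype(float).copy())
            times.append(float(ts.time) / 1000.0)  # ps -> ns
        times = np.asarray(times)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            times = np.arange(len(frames), dtype=float)
        return Trajectory(topology=topo, frames=np.asarray(frames), times=times)

    raise ValidationError(f"unsupported trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write a trajectory as a multi-model PDB, or as XTC/DCD (coordinates only)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "pdb"
    if fmt == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        topo = traj.topology
        stack = struc.AtomArrayStack(traj.n_frames, topo.n_atoms)
        stack.coord = traj.frames.astype(np.float32)
        stack.atom_name = topo.atom_names.astype(str)
        stack.element = topo.elements.astype(str)
        stack.res_name = topo.res_names.astype(str)
        stack.res_id = topo.res_ids
        stack.chain_id = topo.chain_ids.astype(str)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif fmt in ("xtc", "dcd"):
        import MDAnalysis as mda

        uni = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as writer:
            for i in range(traj.n_frames):
                uni.atoms.positions = traj.frames[i].astype(np.float32)
                uni.trajectory.ts.time = traj.times[i] * 1000.0
                uni.trajectory.ts.frame = i
                writer.write(uni.atoms)
    else:
        raise ValidationError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_atoms(
    structure: Structure,
    selection,
    atom_filter: str = "all",
    segment_map: SegmentMap | None = None,
    chain: str | None = None,
) -> np.ndarray:
    """Resolve a segment name or residue-number list to atom indices.

    `atom_filter` is one of all / CA / backbone / sidechain / polar-heavy
    (polar-heavy = nitrogen and oxygen heavy atoms). The result is ordered by
    input atom order; an empty result raises rather than returning silently.
    """
    if atom_filter not in _ATOM_FILTERS:
        raise SelectionError(
            f"unknown atom filter {atom_filter!r}; choose from {_ATOM_FILTERS}"
        )
    if isinstance(selection, str):
        smap = segment_map if segment_map is not None else default_segment_map()
        residues = set(smap.residues(selection))
        if chain is None:
            chain = smap.chain
    else:
        residues = {int(r) for r in selection}

    mask = np.isin(structure.res_ids, list(residues))
    if chain is not None:
        mask &= structure.chain_ids == chain

    names = structure.atom_names
    elements = structure.elements
    if atom_filter == "CA":
        mask &= names == "CA"
    elif atom_filter == "backbone":
        mask &= np.isin(names, list(chemistry.BACKBONE_ATOMS - {"OXT"}))
    elif atom_filter == "sidechain":
        mask &= ~np.isin(names, list(chemistry.BACKBONE_ATOMS))
    elif atom_filter == "polar-heavy":
        mask &= np.isin(elements, ["N", "O"])

    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SelectionError(
            f"selection {selection!r} with filter {atom_filter!r} matched no atoms"
        )
    return idx


# ---------------------------------------------------------------------------
# Ligands, poses, activities
# ---------------------------------------------------------------------------

@dataclass
class LigandRecord:
    """One small molecule with 3D coordinates, charges and optional activity."""

    ligand_id: str
    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray
    aromatic: np.ndarray
    bonds: list[tuple[int, int, float]]
    ic50_um: float | None = None
    pic50: float | None = None
    mol: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.aromatic = np.asarray(self.aromatic, dtype=bool)
        if self.ic50_um is not None and self.pic50 is not None:
            expected = -math.log10(self.ic50_um * 1e-6)
            if abs(self.pic50 - expected) > 1e-6:
                raise ValidationError(
                    f"{self.ligand_id}: pIC50 {self.pic50} inconsistent with "
                    f"IC50 {self.ic50_um} µM (expected {expected:.6f})"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Pose:
    """One docked conformer of a ligand in the receptor frame."""

    ligand_id: str
    coords: np.ndarray
    docking_score: float | None = None
    run_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


def ligand_from_rdkit(mol, ligand_id: str | None = None,
                      ic50_um: float | None = None,
                      pic50: float | None = None) -> LigandRecord:
    """Wrap an RDKit molecule (with a 3D conformer) as a LigandRecord.

    Missing partial charges are filled by iterative electronegativity
    equalization (Gasteiger) — the charge model used throughout the package
    when the input format carries none.
    """
    from rdkit.Chem import AllChem

    if ligand_id is None:
        ligand_id = mol.GetProp("_Name") if mol.HasProp("_Name") else "LIG"
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    if not all(a.HasProp("_TriposPartialCharge") for a in mol.GetAtoms()):
        AllChem.ComputeGasteigerCharges(mol)
        charges = np.array(
            [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
        )
        charges = np.nan_to_num(charges, nan=0.0)
    else:
        charges = np.array(
            [float(a.GetProp("_TriposPartialCharge")) for a in mol.GetAtoms()]
        )
    return LigandRecord(
        ligand_id=str(ligand_id),
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        charges=charges,
        aromatic=np.array([a.GetIsAromatic() for a in mol.GetAtoms()]),
        bonds=[
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ],
        ic50_um=ic50_um,
        pic50=pic50,
        mol=mol,
    )


def _iter_rdkit_mols(path):
    from rdkit import Chem

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ParseError(f"{path}: unparseable molecule at record {i}")
            yield mol
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
        if mol is None:
            raise ParseError(f"{path}: unparseable MOL2 file")
        yield mol
    else:
        raise ValidationError(f"unsupported ligand format {suffix!r}")


def read_ligands(path, activities: pd.DataFrame | None = None) -> list[LigandRecord]:
    """Read ligands from SDF/MOL2, joining activities by ligand_id if given."""
    act = {}
    if activities is not None:
        for _, row in activities.iterrows():
            act[str(row["ligand_id"])] = row
    out = []
    for i, mol in enumerate(_iter_rdkit_mols(path)):
        lid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"LIG{i + 1}"
        row = act.get(str(lid))
        out.append(
            ligand_from_rdkit(
                mol,
                ligand_id=lid,
                ic50_um=None if row is None or pd.isna(row.get("ic50_um")) else float(row["ic50_um"]),
                pic50=None if row is None or pd.isna(row.get("pic50")) else float(row["pic50"]),
            )
        )
    return out


def read_poses(path) -> list[Pose]:
    """Read a multi-conformer SDF of docked poses (score in `docking_score`)."""
    counters: dict[str, int] = {}
    poses = []
    for i, mol in enumerate(_iter_rdkit_mols(path)):
        lid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"LIG{i + 1}"
        run = counters.get(lid, 0)
        counters[lid] = run + 1
        score = None
        if mol.HasProp("docking_score"):
            score = float(mol.GetProp("docking_score"))
        poses.append(
            Pose(
                ligand_id=str(lid),
                coords=np.array(mol.GetConformer().GetPositions(), dtype=float),
                docking_score=score,
                run_index=run,
            )
        )
    return poses


def read_activities(path) -> pd.DataFrame:
    """Read an activity CSV (ligand_id plus ic50_um and/or pic50).

    A missing pic50 column is filled from ic50_um; if both are present, every
    row must satisfy pIC50 = -log10(IC50[µM] x 1e-6) within 1e-6.
    """
    df = pd.read_csv(path)
    if "ligand_id" not in df.columns:
        raise ParseError(f"{path}: missing 'ligand_id' column")
    if "ic50_um" not in df.columns and "pic50" not in df.columns:
        raise ParseError(f"{path}: need an 'ic50_um' or 'pic50' column")
    df["ligand_id"] = df["ligand_id"].astype(str)
    if "ic50_um" in df.columns:
        if (df["ic50_um"] <= 0).any():
            raise ValidationError(f"{path}: non-positive IC50")
        derived = -np.log10(df["ic50_um"] * 1e-6)
        if "pic50" in df.columns:
            bad = np.abs(df["pic50"] - derived) > 1e-6
            if bad.any():
                raise ValidationError(
                    f"{path}: inconsistent pic50 for "
                    f"{df.loc[bad, 'ligand_id'].tolist()}"
                )
        else:
            df["pic50"] = derived
    return df


def write_activities(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def structure_from_atoms(atoms: Iterable[AtomRecord], title: str = "") -> Structure:
    """Assemble a Structure from AtomRecords (convenience for fixtures)."""
    atoms = list(atoms)
    return Structure(
        atom_names=np.array([a.atom_name for a in atoms], dtype=object),
        elements=np.array([a.element for a in atoms], dtype=object),
        res_names=np.array([a.residue_name for a in atoms], dtype=object),
        res_ids=np.array([a.residue_number for a in atoms]),
        chain_ids=np.array([a.chain_id for a in atoms], dtype=object),
        coords=np.array([a.coordinates for a in atoms], dtype=float),
        charges=(
            np.array([a.partial_charge for a in atoms], dtype=float)
            if all(a.partial_charge is not None for a in atoms)
            else None
        ),
        title=title,
    )
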