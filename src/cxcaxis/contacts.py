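"""Distance-criterion interaction analysis.

Polar contacts between transmembrane segments, receptor-chemokine interface
tables, the Asp-Arg "arginine cage" state of the DRF motif, and contact
persistence across trajectory frames.

Criteria are heavy-atom only with LigPlot+/HBPLUS-style cutoffs:
hydrogen bond 3.35 Å (donor-capable N/O vs acceptor-capable N/O), ionic
4.0 Å (Asp/Glu carboxylate O vs Lys/Arg — optionally His — cationic N),
hydrophobic 3.9 Å (apolar side-chain carbons). A residue pair may carry
several interaction kinds at once; per pair and kind the closest qualifying
atom pair is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chemistry
from .errors import SelectionError, ValidationError
from .io import SegmentMap, Structure, default_segment_map

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cutoffs:
    hbond: float = 3.35
    ionic: float = 4.0
    hydrophobic: float = 3.9

    def max(self) -> float:
        return max(self.hbond, self.ionic, self.hydrophobic)


@dataclass
class ContactRecord:
    """One typed residue-residue interaction in one frame."""

    frame: int
    residue_a: tuple[str, int, str]   # (chain, number, name)
    residue_b: tuple[str, int, str]
    atom_a: str
    atom_b: str
    kind: str                         # hbond | ionic | hydrophobic
    distance: float

    @property
    def key(self) -> tuple:
        """Canonical (pair, kind) key: lower chain/number first."""
        return (self.residue_a[:2], self.residue_b[:2], self.kind)


@dataclass
class PersistenceTable:
    """Fraction of analyzed frames in which each contact key is present."""

    fractions: dict[tuple, float]
    presence: dict[tuple, list[bool]]
    n_frames: int = 0

    def __getitem__(self, key) -> float:
        return self.fractions[key]


def _residue_groups(structure: Structure, residues) -> dict[tuple, np.ndarray]:
    """Map (chain, resid) -> atom indices for the requested residues."""
    wanted = {(str(c), int(r)) if isinstance(residues[0], tuple) else int(r)
              for c, r in residues} if residues and isinstance(residues[0], tuple) \
        else {int(r) for r in residues}
    groups: dict[tuple, list[int]] = {}
    for i in range(structure.n_atoms):
        key = (str(structure.chain_ids[i]), int(structure.res_ids[i]))
        if isinstance(next(iter(wanted)), tuple):
            if key not in wanted:
                continue
        elif key[1] not in wanted:
            continue
        groups.setdefault(key, []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def _atom_roles(structure: Structure, idx: int, his_charged: bool):
    res = str(structure.res_names[idx])
    atom = str(structure.atom_names[idx])
    if res not in chemistry.STANDARD_RESIDUES:
        return None
    return (
        chemistry.is_hbond_donor(res, atom),
        chemistry.is_hbond_acceptor(res, atom),
        chemistry.is_anion_atom(res, atom),
        chemistry.is_cation_atom(res, atom, his_charged),
        chemistry.is_apolar_carbon(res, atom),
    )


def detect_contacts(
    structure: Structure,
    group_a,
    group_b,
    cutoffs: Cutoffs = Cutoffs(),
    his_charged: bool = False,
    frame: int = 0,
) -> list[ContactRecord]:
    """Typed contacts between two residue groups of one structure/frame.

    Groups are residue-number lists (or (chain, number) pairs) and must be
    disjoint at the residue level. Unknown residue names are skipped with a
    warning. Per residue pair and kind, the closest qualifying atom pair is
    recorded; the pair is stored canonically (lower chain/number first).
    """
    ga = _residue_groups(structure, list(group_a))
    gb = _residue_groups(structure, list(group_b))
    if set(ga) & set(gb):
        raise ValidationError(f"groups share residues: {sorted(set(ga) & set(gb))}")
    idx_a = np.concatenate(list(ga.values())) if ga else np.array([], dtype=int)
    idx_b = np.concatenate(list(gb.values())) if gb else np.array([], dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        return []

    unknown = {
        str(structure.res_names[i])
        for i in np.concatenate([idx_a, idx_b])
        if str(structure.res_names[i]) not in chemistry.STANDARD_RESIDUES
    }
    if unknown:
        logger.warning("skipping unknown residue names: %s", sorted(unknown))

    tree_b = cKDTree(structure.coords[idx_b])
    pairs = tree_b.query_ball_point(structure.coords[idx_a], cutoffs.max())

    best: dict[tuple, ContactRecord] = {}
    for ai, neighbors in zip(idx_a, pairs):
        roles_a = _atom_roles(structure, ai, his_charged)
        if roles_a is None:
            continue
        don_a, acc_a, ani_a, cat_a, apo_a = roles_a
        for bj in (idx_b[j] for j in neighbors):
            roles_b = _atom_roles(structure, bj, his_charged)
            if roles_b is None:
                continue
            don_b, acc_b, ani_b, cat_b, apo_b = roles_b
            d = float(np.linalg.norm(structure.coords[ai] - structure.coords[bj]))
            kinds = []
            if d <= cutoffs.hbond and ((don_a and acc_b) or (don_b and acc_a)):
                kinds.append("hbond")
            if d <= cutoffs.ionic and ((ani_a and cat_b) or (cat_a and ani_b)):
                kinds.append("ionic")
            if d <= cutoffs.hydrophobic and apo_a and apo_b:
                kinds.append("hydrophobic")
            for kind in kinds:
                rec = _make_record(structure, frame, ai, bj, kind, d)
                if rec.key not in best or d < best[rec.key].distance:
                    best[rec.key] = rec
    return sorted(
        best.values(),
        key=lambda r: (r.residue_a[:2], r.residue_b[:2], r.kind),
    )


def _make_record(structure, frame, ai, bj, kind, d) -> ContactRecord:
    res_a = (str(structure.chain_ids[ai]), int(structure.res_ids[ai]),
             str(structure.res_names[ai]))
    res_b = (str(structure.chain_ids[bj]), int(structure.res_ids[bj]),
             str(structure.res_names[bj]))
    atom_a = str(structure.atom_names[ai])
    atom_b = str(structure.atom_names[bj])
    if (res_b[0], res_b[1]) < (res_a[0], res_a[1]):
        res_a, res_b = res_b, res_a
        atom_a, atom_b = atom_b, atom_a
    return ContactRecord(frame=frame, residue_a=res_a, residue_b=res_b,
                         atom_a=atom_a, atom_b=atom_b, kind=kind, distance=d)


def interface_report(
    structure: Structure,
    chain_receptor: str,
    chain_chemokine: str,
    segment_map: SegmentMap | None = None,
    cutoffs: Cutoffs = Cutoffs(),
    his_charged: bool = False,
) -> pd.DataFrame:
    """Cross-chain contact table (receptor vs chemokine), grouped by kind.

    Receptor residues are annotated with their segment names so interface
    partners can be read off per TM/loop.
    """
    chains = set(map(str, structure.chain_ids))
    for ch in (chain_receptor, chain_chemokine):
        if ch not in chains:
            raise SelectionError(
                f"chain {ch!r} not present; available chains: {sorted(chains)}"
            )
    smap = segment_map if segment_map is not None else default_segment_map()
    res_a = sorted({
        (str(c), int(r))
        for c, r in zip(structure.chain_ids, structure.res_ids)
        if str(c) == chain_receptor
    })
    res_b = sorted({
        (str(c), int(r))
        for c, r in zip(structure.chain_ids, structure.res_ids)
        if str(c) == chain_chemokine
    })
    records = detect_contacts(structure, res_a, res_b, cutoffs, his_charged)

    def segment_of(chain: str, resid: int) -> str:
        if chain != chain_receptor:
            return ""
        for name, (lo, hi) in smap.segments.items():
            if name == "DRF":
                continue
            if lo <= resid <= hi:
                return name
        return ""

    rows = []
    for r in records:
        rows.append({
            "kind": r.kind,
            "chain_a": r.residue_a[0], "res_a": r.residue_a[1],
            "name_a": r.residue_a[2],
            "segment_a": segment_of(r.residue_a[0], r.residue_a[1]),
            "atom_a": r.atom_a,
            "chain_b": r.residue_b[0], "res_b": r.residue_b[1],
            "name_b": r.residue_b[2],
            "segment_b": segment_of(r.residue_b[0], r.residue_b[1]),
            "atom_b": r.atom_b,
            "distance": r.distance,
        })
    df = pd.DataFrame(rows, columns=[
        "kind", "chain_a", "res_a", "name_a", "segment_a", "atom_a",
        "chain_b", "res_b", "name_b", "segment_b", "atom_b", "distance",
    ])
    return df.sort_values(["kind", "res_a", "res_b"]).reset_index(drop=True)


class TMInteractionMatrix:
    """Inter-TM polar contacts keyed by ordered segment pair (TMi, TMj), i<j.

    Querying the reversed pair returns the same list.
    """

    def __init__(self, entries: dict[tuple[str, str], list[ContactRecord]]):
        self.entries = entries

    def __getitem__(self, pair: tuple[str, str]) -> list[ContactRecord]:
        a, b = pair
        key = (a, b) if a <= b else (b, a)
        return self.entries.get(key, [])

    def keys(self):
        return self.entries.keys()

    def nonempty(self) -> dict[tuple[str, str], list[ContactRecord]]:
        return {k: v for k, v in self.entries.items() if v}


def tm_interaction_matrix(
    structure: Structure,
    segment_map: SegmentMap | None = None,
    cutoffs: Cutoffs = Cutoffs(),
    his_charged: bool = False,
    frame: int = 0,
) -> TMInteractionMatrix:
    """Polar (hbond/ionic) contacts between every pair of TM segments.

    Intra-segment contacts are excluded; hydrophobic contacts are not part
    of the polar-interaction tables.
    """
    smap = segment_map if segment_map is not None else default_segment_map()
    tms = smap.tm_names()
    present = set(structure.res_ids.tolist())
    entries: dict[tuple[str, str], list[ContactRecord]] = {}
    for i, tm_a in enumerate(tms):
        for tm_b in tms[i + 1:]:
            res_a = [r for r in smap.residues(tm_a) if r in present]
            res_b = [r for r in smap.residues(tm_b) if r in present]
            if not res_a or not res_b:
                entries[(tm_a, tm_b)] = []
                continue
            recs = detect_contacts(structure, res_a, res_b, cutoffs,
                                   his_charged, frame=frame)
            entries[(tm_a, tm_b)] = [r for r in recs
                                     if r.kind in ("hbond", "ionic")]
    return TMInteractionMatrix(entries)


def arginine_cage_state(
    structure: Structure,
    asp_residue: int = 126,
    arg_residue: int = 127,
    cutoff: float = 4.0,
    chain: str | None = None,
) -> tuple[str, float]:
    """State of the DRF-motif Asp-Arg salt bridge ("arginine cage").

    Intact iff the minimum distance over (OD1,OD2) x (NE,NH1,NH2) is within
    the ionic cutoff. Returns ('intact'|'broken', min_distance).
    """
    def side_atoms(resid: int, names: tuple[str, ...]) -> np.ndarray:
        mask = structure.res_ids == resid
        if chain is not None:
            mask &= structure.chain_ids == chain
        found = {str(structure.atom_names[i]): i for i in np.flatnonzero(mask)}
        missing = [n for n in names if n not in found]
        if len(missing) == len(names):
            raise SelectionError(
                f"residue {resid}: missing side-chain atoms {missing}"
            )
        if missing:
            logger.warning("residue %d missing atoms %s", resid, missing)
        return np.array([found[n] for n in names if n in found])

    asp_idx = side_atoms(asp_residue, ("OD1", "OD2"))
    arg_idx = side_atoms(arg_residue, ("NE", "NH1", "NH2"))
    diffs = structure.coords[asp_idx][:, None, :] - structure.coords[arg_idx][None, :, :]
    dmin = float(np.sqrt((diffs ** 2).sum(axis=2)).min())
    return ("intact" if dmin <= cutoff else "broken"), dmin


def persistence(frame_contacts: list[list[ContactRecord]]) -> PersistenceTable:
    """Fraction of analyzed frames in which each (pair, kind) contact occurs."""
    if not frame_contacts:
        raise ValidationError("need at least one analyzed frame")
    n = len(frame_contacts)
    presence: dict[tuple, list[bool]] = {}
    for i, contacts in enumerate(frame_contacts):
        seen = {c.key for c in contacts}
        for key in seen:
            presence.setdefault(key, [False] * n)[i] = True
    fractions = {k: sum(v) / n for k, v in presence.items()}
    return PersistenceTable(fractions=fractions, presence=presence, n_frames=n)


def contacts_to_frame(records: list[ContactRecord], times=None) -> pd.DataFrame:
    """Long-format contact table (frame, residues, atoms, kind, distance)."""
    rows = []
    for r in records:
        rows.append({
            "frame": r.frame,
            "time_ns": None if times is None else times[r.frame],
            "chain_a": r.residue_a[0], "res_a": r.residue_a[1],
            "name_a": r.residue_a[2], "atom_a": r.atom_a,
            "chain_b": r.residue_b[0], "res_b": r.residue_b[1],
            "name_b": r.residue_b[2], "atom_b": r.atom_b,
            "kind": r.kind, "distance": r.distance,
        })
    return pd.DataFrame(rows)
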