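"""Geometric trajectory analyses.

Implements the post-simulation geometry toolbox for receptor trajectories:
least-squares (Kabsch) superposition, per-segment RMSD time series,
per-residue RMSF, center-of-mass distances, neighbor-count ("gromos"/Daura)
conformational clustering, representative-frame selection against the
average structure, and per-helix rotation axis/angle series.

All ties break to the lowest frame index so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, SelectionError, ValidationError
from .io import Trajectory


@dataclass
class RigidTransform:
    """Proper rigid-body transform with its angle/axis decomposition."""

    rotation: np.ndarray
    translation: np.ndarray
    angle_deg: float
    axis: np.ndarray
    rmsd_after: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class MetricSeries:
    """One named metric over time (or residue number, for RMSF profiles)."""

    metric: str
    label: str
    times: np.ndarray
    values: np.ndarray
    x_kind: str = "time_ns"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.metric}/{self.label}: non-finite values")


@dataclass
class ClusterResult:
    """Partition of frames into neighbor-count clusters, largest first."""

    assignments: dict[int, int]
    centers: dict[int, int]
    cutoff: float
    sizes: list[int] = field(default_factory=list)


def _check_points(coords: np.ndarray, what: str) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError(f"{what}: need >= 3 points, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[1] / s[0] < 1e-9:
        raise DegenerateGeometryError(f"{what}: points are collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns the transform minimizing the (weighted) RMSD, with the rotation
    angle in [0, 180] degrees and its unit axis. Angle extraction goes through
    the quaternion representation, which stays stable near 180 degrees.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValidationError(
            f"point counts differ: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    _check_points(reference, "reference")
    _check_points(mobile, "mobile")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (w[:, None] * reference).sum(axis=0) / wsum
    rot, rssd = Rotation.align_vectors(reference - ref_c, mobile - mob_c, weights=w)
    rmsd = float(rssd / np.sqrt(wsum))
    angle_rad = float(rot.magnitude())
    rotvec = rot.as_rotvec()
    if angle_rad > 1e-12:
        axis = rotvec / angle_rad
    else:
        axis = np.array([0.0, 0.0, 1.0])
    matrix = rot.as_matrix()
    translation = ref_c - matrix @ mob_c
    return RigidTransform(
        rotation=matrix,
        translation=translation,
        angle_deg=float(np.degrees(angle_rad)),
        axis=axis,
        rmsd_after=rmsd,
    )


def _fitted_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two point sets after optimal superposition."""
    return kabsch_superpose(a, b).rmsd_after


def _raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _as_indices(selection) -> np.ndarray:
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty selection")
    return idx


def rmsd_series(
    traj: Trajectory,
    analyze_selection,
    fit_selection=None,
    reference_frame: int = 0,
    label: str = "",
) -> MetricSeries:
    """Per-frame RMSD over `analyze_selection` after fitting on `fit_selection`.

    Each frame is superposed onto the reference frame using the fit
    selection; the reported value is the (unfitted) RMSD of the analysis
    selection after that superposition — zero at the reference frame.
    """
    analyze = _as_indices(analyze_selection)
    fit = analyze if fit_selection is None else _as_indices(fit_selection)
    if not (0 <= reference_frame < traj.n_frames):
        raise ValidationError(f"reference frame {reference_frame} out of range")
    ref = traj.frames[reference_frame]
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        tf = kabsch_superpose(frame[fit], ref[fit])
        values[i] = _raw_rmsd(tf.apply(frame[analyze]), ref[analyze])
    return MetricSeries("rmsd", label, traj.times, values)


def _superpose_frames(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """All frames superposed (on `selection`) onto frame 0; full coordinates."""
    ref = traj.frames[0]
    out = np.empty_like(traj.frames)
    for i, frame in enumerate(traj.frames):
        tf = kabsch_superpose(frame[selection], ref[selection])
        out[i] = tf.apply(frame)
    return out


def rmsf_profile(traj: Trajectory, selection, fit_selection=None,
                 label: str = "") -> MetricSeries:
    """Per-residue RMSF about the mean structure.

    Frames are first superposed on the fit selection's average structure
    (the analysis selection itself by default); the atomic RMSF
    sqrt(<|x - <x>|^2>) is then averaged over each residue's selected
    atoms. The abscissa of the returned series is residue number.
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    sel = _as_indices(selection)
    fit = sel if fit_selection is None else _as_indices(fit_selection)
    aligned = _superpose_frames(traj, fit)
    avg = aligned[:, fit, :].mean(axis=0)
    # second pass: superpose every original frame directly on the average
    coords = np.empty((traj.n_frames, len(sel), 3))
    for i, frame in enumerate(traj.frames):
        tf = kabsch_superpose(frame[fit], avg)
        coords[i] = tf.apply(frame[sel])
    mean = coords.mean(axis=0)
    atomic = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    res_ids = traj.topology.res_ids[sel]
    chains = traj.topology.chain_ids[sel]
    keys = list(dict.fromkeys(zip(chains, res_ids)))
    values = np.array(
        [atomic[(chains == c) & (res_ids == r)].mean() for c, r in keys]
    )
    residues = np.array([r for _, r in keys], dtype=float)
    return MetricSeries("rmsf", label, residues, values, x_kind="residue")


def com_distance(
    traj: Trajectory,
    group_a,
    group_b,
    mass_weighted: bool = False,
    label: str = "",
) -> MetricSeries:
    """Per-frame distance between the centers of two disjoint atom groups.

    Centers are geometric by default, mass-weighted on request (masses from
    the topology, falling back to the element table).
    """
    a = _as_indices(group_a)
    b = _as_indices(group_b)
    if np.intersect1d(a, b).size:
        raise ValidationError("groups overlap")
    if mass_weighted:
        masses = traj.topology.atom_masses()
        wa, wb = masses[a], masses[b]
    else:
        wa = np.ones(len(a))
        wb = np.ones(len(b))
    ca = (traj.frames[:, a, :] * wa[None, :, None]).sum(axis=1) / wa.sum()
    cb = (traj.frames[:, b, :] * wb[None, :, None]).sum(axis=1) / wb.sum()
    values = np.linalg.norm(ca - cb, axis=1)
    return MetricSeries("distance", label, traj.times, values)


def pairwise_rmsd_matrix(coords: np.ndarray, fitted: bool = True) -> np.ndarray:
    """Symmetric matrix of (optionally superposed) RMSDs between frames."""
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _fitted_rmsd(coords[i], coords[j]) if fitted else _raw_rmsd(
                coords[i], coords[j]
            )
            mat[i, j] = mat[j, i] = d
    return mat


def neighbor_cluster(matrix: np.ndarray, cutoff: float) -> tuple[list[list[int]], list[int]]:
    """Daura neighbor-count clustering on a precomputed distance matrix.

    Repeatedly takes the element with the most neighbors within the cutoff
    as a cluster center (ties to the lowest index), removes the cluster, and
    continues. Returns member lists and center indices, in discovery order.
    """
    if cutoff < 0:
        raise ValidationError("cutoff must be >= 0")
    n = len(matrix)
    remaining = list(range(n))
    clusters, centers = [], []
    while remaining:
        best_center, best_members = None, None
        for i in remaining:
            members = [j for j in remaining if matrix[i, j] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        clusters.append(sorted(best_members))
        centers.append(best_center)
        remaining = [j for j in remaining if j not in set(best_members)]
    return clusters, centers


def gromos_cluster(traj: Trajectory, selection, cutoff: float) -> ClusterResult:
    """Conformational clustering on the pairwise fitted-RMSD matrix.

    Cluster ids are assigned in decreasing cluster size (ties by discovery
    order, i.e. by the center's neighbor count then lowest frame index).
    """
    sel = _as_indices(selection)
    matrix = pairwise_rmsd_matrix(traj.frames[:, sel, :])
    clusters, centers = neighbor_cluster(matrix, cutoff)
    order = sorted(
        range(len(clusters)), key=lambda k: (-len(clusters[k]), k)
    )
    assignments, center_map, sizes = {}, {}, []
    for new_id, k in enumerate(order):
        center_map[new_id] = centers[k]
        sizes.append(len(clusters[k]))
        for frame in clusters[k]:
            assignments[frame] = new_id
    return ClusterResult(assignments=assignments, centers=center_map,
                         cutoff=cutoff, sizes=sizes)


def representative_frame(traj: Trajectory, selection) -> int:
    """Frame with the smallest fitted RMSD to the uniform-weight average
    structure (computed over frames superposed on the selection)."""
    sel = _as_indices(selection)
    if traj.n_frames == 1:
        return 0
    aligned = _superpose_frames(traj, sel)[:, sel, :]
    avg = aligned.mean(axis=0)
    rmsds = np.array([_fitted_rmsd(traj.frames[i][sel], avg)
                      for i in range(traj.n_frames)])
    return int(np.argmin(rmsds))  # argmin takes the lowest index on ties


def helix_rotation_series(
    traj: Trajectory,
    segment,
    reference_frame: int = 0,
    global_fit_selection=None,
    segment_map=None,
    relative_to: str = "f0",
    label: str = "",
) -> tuple[MetricSeries, list[RigidTransform]]:
    """Per-frame rotation angle of one helix, from its CA atoms.

    Each frame is optionally first superposed on `global_fit_selection`
    (typically all receptor CA atoms) to remove global tumbling, then the
    rigid transform between the reference and current helix CA coordinates
    is computed; its angle is reported. `relative_to='previous'` reports
    frame-to-frame increments instead of angles versus the reference frame.
    """
    from .io import select_atoms

    if isinstance(segment, str):
        seg_idx = select_atoms(traj.topology, segment, "CA", segment_map)
    else:
        seg_idx = _as_indices(segment)
    if len(seg_idx) < 3:
        raise DegenerateGeometryError(
            f"segment needs >= 3 CA atoms, got {len(seg_idx)}"
        )
    if relative_to not in ("f0", "previous"):
        raise ValidationError("relative_to must be 'f0' or 'previous'")
    ref = traj.frames[reference_frame]
    detumbled = []
    for frame in traj.frames:
        if global_fit_selection is not None:
            gf = _as_indices(global_fit_selection)
            tf = kabsch_superpose(frame[gf], ref[gf])
            detumbled.append(tf.apply(frame))
        else:
            detumbled.append(frame)
    transforms, angles = [], []
    for i, frame in enumerate(detumbled):
        if relative_to == "f0":
            base = detumbled[reference_frame]
        else:
            base = detumbled[max(i - 1, 0)]
        tf = kabsch_superpose(base[seg_idx], frame[seg_idx])
        transforms.append(tf)
        angles.append(tf.angle_deg)
    series = MetricSeries("rotation", label or str(segment), traj.times,
                          np.array(angles))
    return series, transforms
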