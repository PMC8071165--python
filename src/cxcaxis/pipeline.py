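"""End-to-end orchestration from one YAML config.

Stages run in dependency order (simulate -> trajmetrics/contacts ->
pharmacophore -> qsar); each stage writes CSV/JSON outputs under the run
directory and the run ends with a manifest recording the config hash,
stage inputs/outputs, seeds and wall-clock. Re-running an identical config
reproduces identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DependencyError, ValidationError
from .io import default_segment_map, load_segment_map, read_activities, \
    read_trajectory, select_atoms, write_trajectory
from . import contacts as contacts_mod
from . import metrics as metrics_mod
from . import pharmacophore as pharm_mod
from . import qsar as qsar_mod
from . import synthetic

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "trajmetrics", "contacts", "pharmacophore", "qsar")


@dataclass
class RunManifest:
    config_hash: str
    stages: list[str]
    stage_io: dict[str, dict]
    seeds: dict[str, int]
    wall_clock_s: float
    version: str = __version__
    outputs: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _log(event: str, **kw) -> None:
    logger.info(json.dumps({"event": event, **kw}, sort_keys=True))


def _validate(config: dict) -> None:
    if not isinstance(config, dict):
        raise ValidationError("config: expected a mapping at the top level")
    if "stages" not in config or not isinstance(config["stages"], dict):
        raise ValidationError("config: missing 'stages' mapping (path: stages)")
    for name in config["stages"]:
        if name not in STAGE_ORDER:
            raise ValidationError(
                f"config: unknown stage {name!r} (path: stages.{name}); "
                f"known stages: {STAGE_ORDER}"
            )
    for path_key in ("traj", "topology", "ligands", "activities", "receptor"):
        for sname, scfg in config["stages"].items():
            if isinstance(scfg, dict) and path_key in scfg:
                p = Path(scfg[path_key])
                if not p.exists():
                    raise ValidationError(
                        f"config: file {p} not found "
                        f"(path: stages.{sname}.{path_key})"
                    )


def run(config, out_dir=None) -> RunManifest:
    """Execute the configured stages; returns (and writes) the run manifest."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    _validate(config)
    t0 = time.time()
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir or config.get("out_dir", "cxcaxis_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    smap = load_segment_map(config.get("segments"))

    stages_cfg = config["stages"]
    products: dict[str, object] = {}
    stage_io: dict[str, dict] = {}
    seeds: dict[str, int] = {}
    outputs: list[str] = []
    ran: list[str] = []

    for stage in STAGE_ORDER:
        if stage not in stages_cfg:
            continue
        scfg = stages_cfg[stage] or {}
        _log("stage_start", stage=stage)
        try:
            io_rec = _STAGE_FUNCS[stage](scfg, seed, smap, out_dir, products)
        except (DependencyError, ValidationError):
            _log("stage_failed", stage=stage)
            raise
        stage_io[stage] = io_rec
        seeds[stage] = seed
        outputs.extend(io_rec.get("outputs", []))
        ran.append(stage)
        _log("stage_done", stage=stage)

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        stages=ran,
        stage_io=stage_io,
        seeds=seeds,
        wall_clock_s=round(time.time() - t0, 3),
        outputs=outputs,
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(scfg, seed, smap, out_dir, products):
    kinds = scfg.get("kinds", ["rotation", "approach", "poses", "ligands"])
    outs = []
    if "bundle" in kinds or "rotation" in kinds:
        bundle = synthetic.make_helical_bundle(smap)
        products["bundle"] = bundle
    if "rotation" in kinds:
        n_frames = int(scfg.get("n_frames", 6))
        angles = {
            name: np.linspace(0.0, 5.0 * (i + 1), n_frames)
            for i, name in enumerate(smap.tm_names())
        }
        traj, truth = synthetic.make_rotation_trajectory(
            products["bundle"], angles,
            jitter=float(scfg.get("jitter", 0.0)), seed=seed,
            segment_map=smap)
        products["trajectory"] = traj
        path = out_dir / "rotation_trajectory.pdb"
        write_trajectory(traj, path)
        truth.to_json(out_dir / "rotation_truth.json")
        outs += [str(path), str(out_dir / "rotation_truth.json")]
    if "approach" in kinds:
        d = np.array(scfg.get(
            "d_schedule", (35.0 * np.exp(-0.4 * np.arange(8)) + 25.0).tolist()))
        traj, truth = synthetic.make_approach_trajectory(
            products.get("bundle", synthetic.make_helical_bundle(smap)),
            d, seed=seed)
        products["approach"] = (traj, truth)
        truth.to_json(out_dir / "approach_truth.json")
        outs.append(str(out_dir / "approach_truth.json"))
    if "poses" in kinds:
        base = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0],
                         [1.5, 1.5, 0.0]])
        poses, truth = synthetic.make_pose_set(
            base, centers=[(0, 0, 0), (6, 0, 0)],
            populations=scfg.get("populations", (7, 3)), seed=seed)
        products["poses"] = (poses, truth)
        truth.to_json(out_dir / "poses_truth.json")
        outs.append(str(out_dir / "poses_truth.json"))
    if "ligands" in kinds:
        ligands, activities, truth = synthetic.make_ligand_series(
            n=int(scfg.get("n_ligands", 82)), seed=seed)
        products["ligands"] = ligands
        products["activities"] = activities
        act_path = out_dir / "activities.csv"
        activities.to_csv(act_path, index=False)
        sdf_path = out_dir / "ligands.sdf"
        synthetic.write_ligands_sdf(ligands, sdf_path)
        truth.to_json(out_dir / "ligands_truth.json")
        outs += [str(act_path), str(sdf_path), str(out_dir / "ligands_truth.json")]
    return {"outputs": outs, "kinds": list(kinds)}


def _require(products, key, stage, hint):
    if key not in products:
        raise DependencyError(
            f"stage '{stage}' is missing upstream input '{key}' ({hint})"
        )
    return products[key]


def _stage_trajmetrics(scfg, seed, smap, out_dir, products):
    if "traj" in scfg:
        traj = read_trajectory(scfg.get("topology", scfg["traj"]), scfg["traj"])
        products["trajectory"] = traj
    traj = _require(products, "trajectory", "trajmetrics",
                    "run the simulate stage or set stages.trajmetrics.traj")
    metrics = scfg.get("metrics", ["rmsd", "rotation"])
    segments = scfg.get("segments", smap.tm_names())
    fit_sel = np.flatnonzero(traj.topology.atom_names == "CA")
    rows = []
    for seg in segments:
        sel = select_atoms(traj.topology, seg, "CA", smap)
        if "rmsd" in metrics:
            series = metrics_mod.rmsd_series(traj, sel, fit_sel, label=seg)
            rows += [(t, "rmsd", seg, v)
                     for t, v in zip(series.times, series.values)]
        if "rotation" in metrics:
            series, _ = metrics_mod.helix_rotation_series(
                traj, seg, segment_map=smap, label=seg)
            rows += [(t, "rotation", seg, v)
                     for t, v in zip(series.times, series.values)]
    if "distance" in metrics and "approach" in products:
        atraj, _ = products["approach"]
        rec = np.flatnonzero(atraj.topology.chain_ids == "R")
        blob = np.flatnonzero(atraj.topology.chain_ids == "Q")
        series = metrics_mod.com_distance(atraj, rec, blob, label="complex")
        rows += [(t, "distance", "complex", v)
                 for t, v in zip(series.times, series.values)]
    df = pd.DataFrame(rows, columns=["time_ns", "metric", "label", "value"])
    path = out_dir / "metrics.csv"
    df.to_csv(path, index=False)
    return {"outputs": [str(path)], "n_rows": len(df)}


def _stage_contacts(scfg, seed, smap, out_dir, products):
    traj = _require(products, "trajectory", "contacts",
                    "run the simulate stage or set stages.trajmetrics.traj")
    frame_records = []
    for f in range(traj.n_frames):
        frame = traj.topology.with_coords(traj.frames[f])
        matrix = contacts_mod.tm_interaction_matrix(frame, smap, frame=f)
        recs = [r for lst in matrix.entries.values() for r in lst]
        frame_records.append(recs)
    table = contacts_mod.persistence(frame_records)
    all_recs = [r for recs in frame_records for r in recs]
    df = contacts_mod.contacts_to_frame(all_recs, traj.times)
    csv_path = out_dir / "contacts.csv"
    df.to_csv(csv_path, index=False)
    pers_path = out_dir / "persistence.json"
    with open(pers_path, "w") as fh:
        json.dump({str(k): v for k, v in sorted(table.fractions.items())},
                  fh, indent=2)
    return {"outputs": [str(csv_path), str(pers_path)],
            "n_contacts": len(all_recs)}


def _stage_pharmacophore(scfg, seed, smap, out_dir, products):
    if "ligands" in scfg:
        from .io import read_ligands
        acts = read_activities(scfg["activities"]) if "activities" in scfg \
            else None
        products["ligands"] = read_ligands(scfg["ligands"], acts)
    ligands = _require(products, "ligands", "pharmacophore",
                       "run the simulate stage or set stages.pharmacophore.ligands")
    features = []
    for lig in ligands:
        features.extend(pharm_mod.extract_features(lig))
    model = pharm_mod.build_general_model(features, n_ligands=len(ligands))
    products["consensus_model"] = model
    payload = [{
        "type": c.feature_type,
        "xyz": c.medoid.tolist(),
        "radius": c.mean_radius,
        "n_ligands": c.ligand_count,
        "sum_pic50": c.sum_pic50,
        "selected": c.selected,
    } for c in model.clusters]
    path = out_dir / "model.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return {"outputs": [str(path)], "n_clusters": len(model.clusters),
            "n_selected": len(model.selected)}


def _stage_qsar(scfg, seed, smap, out_dir, products):
    if "ligands" in scfg:
        from .io import read_ligands
        if "activities" not in scfg:
            raise DependencyError(
                "stage 'qsar' is missing upstream input 'activities' "
                "(set stages.qsar.activities)")
        acts = read_activities(scfg["activities"])
        products["ligands"] = read_ligands(scfg["ligands"], acts)
        products["activities"] = acts
    ligands = _require(products, "ligands", "qsar",
                       "run the simulate stage or set stages.qsar.ligands")
    activities = _require(products, "activities", "qsar",
                          "set stages.qsar.activities")
    fm = qsar_mod.build_field_matrix(
        ligands, spacing=float(scfg.get("spacing", 2.0)),
        truncation=float(scfg.get("truncation", 30.0)))
    acts = dict(zip(activities["ligand_id"].astype(str), activities["pic50"]))
    n_models = int(scfg.get("n_models", 10))
    base_seed = int(scfg.get("seed", seed))
    split = qsar_mod.SplitSpec(
        test_fraction=float(scfg.get("test_fraction", 0.28)),
        n_models=n_models,
        seeds=[base_seed + i for i in range(n_models)],
    )
    models = qsar_mod.fit_qsar_suite(fm, acts, split)
    df = pd.DataFrame([{
        "seed": m.seed, "q2": m.q2, "r2": m.r2, "f": m.f_stat,
        "k": m.n_components, "selected": m.selected,
        "test_ids": " ".join(m.test_ids),
    } for m in models])
    path = out_dir / "qsar_models.csv"
    df.to_csv(path, index=False)
    return {"outputs": [str(path)],
            "best_q2": float(models[0].q2) if models else None}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "trajmetrics": _stage_trajmetrics,
    "contacts": _stage_contacts,
    "pharmacophore": _stage_pharmacophore,
    "qsar": _stage_qsar,
}
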