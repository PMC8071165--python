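"""Build a consensus protein-ligand interaction model from a ligand series.

Generates 50 aligned pseudo-ligands with three planted interaction hotspots
(an H-bond acceptor, an H-bond donor, and a hydrophobic group), extracts
rule-based pharmacophore features from every ligand, clusters them by type
with partitioning around medoids, and selects the activity-ranked consensus
clusters — then compares the selected medoids with the planted truth.
"""

import numpy as np

import cxcaxis as cx

ligands, activities, truth = cx.make_ligand_series(
    n=50, presence_prob=0.7, decoy_rate=0.1, jitter=0.5, seed=1)

features = [f for lig in ligands for f in cx.extract_features(lig)]
print(f"{len(features)} features extracted from {len(ligands)} ligands")

model = cx.build_general_model(features, n_ligands=len(ligands))
anchors = {h["type"]: np.array(h["anchor"]) for h in truth.data["hotspots"]}

print("type  ligands  sum pIC50   medoid (Å)            error vs truth")
for c in model.selected:
    err = np.linalg.norm(c.medoid - anchors[c.feature_type])
    xyz = ", ".join(f"{v:6.2f}" for v in c.medoid)
    print(f"{c.feature_type:4s}  {c.ligand_count:7d}  {c.sum_pic50:9.1f}"
          f"   [{xyz}]   {err:.2f}")

# The selected clusters are the model's pharmacophoric features: each line
# is one consensus interaction point, its ligand coverage, its summed
# activity score, and how far the recovered medoid sits from the planted
# hotspot (well under 1 Å here).
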