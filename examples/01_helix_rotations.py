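"""Recover planted transmembrane-helix rotations from a trajectory.

Builds the idealized 7-helix receptor bundle, plants a known rigid rotation
on each helix (5, 10, ..., 35 degrees about its own axis), adds 0.1 Å of
coordinate noise, and measures the per-helix rotation angle the way the
trajectory-analysis stage does: Kabsch superposition of each helix's CA
atoms against the reference frame.
"""

import numpy as np

import cxcaxis as cx

smap = cx.default_segment_map()
bundle = cx.make_helical_bundle(smap)
angles = {f"TM{i + 1}": np.array([0.0, 5.0 * (i + 1)]) for i in range(7)}
traj, truth = cx.make_rotation_trajectory(bundle, angles, jitter=0.1, seed=1,
                                          segment_map=smap)

print("helix  planted  recovered  error (deg)")
for i in range(7):
    name = f"TM{i + 1}"
    series, transforms = cx.helix_rotation_series(traj, name,
                                                  segment_map=smap)
    planted = truth.data["schedules_deg"][name][1]
    print(f"{name:5s}  {planted:7.1f}  {series.values[1]:9.3f}"
          f"  {abs(series.values[1] - planted):.3f}")

# Each row compares the rotation planted by the generator with the angle the
# analysis recovers; errors stay well below one degree at this noise level,
# which is the regime where per-helix rotations in a 1 µs trajectory can be
# read off reliably.
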