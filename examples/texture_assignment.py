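"""Assign each mesh triangle its best source photograph.

Renders four camera stops around the phantom, runs the mosaic visibility
test and the largest-projected-area selection, and reports how triangles
distribute over views.
"""

import numpy as np

from orthoskin import PhantomSpec, RigidPose, build_phantom
from orthoskin.geometry import CameraCalib
from orthoskin.render import CameraView
from orthoskin.texturing import NO_VIEW, assign_textures

phantom = build_phantom(PhantomSpec(segments=96, rings_per_meter=48))
views = [
    CameraView(
        pose=RigidPose.from_degrees(90.0 * i, 1.0, 0.9),
        calib=CameraCalib.ideal(2e-3, (320, 320)),
        view_id=i,
    )
    for i in range(4)
]

assignment = assign_textures(phantom.mesh, views)
counts = {v: int(np.sum(assignment.view_ids == v)) for v in range(4)}
unassigned = int(np.sum(assignment.view_ids == NO_VIEW))
print(f"triangles: {len(assignment)}")
for v, c in counts.items():
    print(f"  view {v} (alpha = {90 * v:3d} deg): {c} triangles")
print(f"  unassigned (seen by no view): {unassigned}")
print(f"assigned fraction: {assignment.assigned_fraction:.3f}")
# Each view wins the ~quarter of the body it faces most frontally — the
# largest-projected-area rule picks the photograph with the best resolution
# for every skin patch.  Unassigned triangles are off-image (outside the
# narrow test frames) or hidden in every view.
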