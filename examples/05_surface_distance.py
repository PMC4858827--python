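"""Rigidly align two surface models and report symmetric surface-distance
statistics (the comparison used to judge how well one modality's model
matches the reference model).
"""

import math

import trimesh

from aneumorph import AneurysmSpec, build_phantom_mesh, symmetric_distance

lmesh, _ = build_phantom_mesh(AneurysmSpec(mesh_edge_length=0.25))
reference = lmesh.mesh

# a displaced copy stands in for a model reconstructed in another frame
moved = reference.copy()
pose = trimesh.transformations.rotation_matrix(math.radians(12), [0.2, 1, 0.3])
pose[:3, 3] = [3.0, -2.0, 1.0]
moved.apply_transform(pose)

naive = symmetric_distance(moved, reference)
aligned = symmetric_distance(moved, reference, align=True)
print(f"before alignment: mean {naive.mean:6.3f} mm, max {naive.max:6.3f} mm")
print(f"after  alignment: mean {aligned.mean:6.3f} mm, max {aligned.max:6.3f} mm "
      f"(converged={aligned.converged})")
print(f"samples used: {aligned.n_samples}")
print("\nThe aligned mean should be ~0: the models are identical up to a "
      "rigid motion,\nwhich the ICP alignment recovers before distances are "
      "measured.")
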