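"""Build a groupwise atlas from known warps of one phantom and score it.

Eight smooth diffeomorphic deformations of a single base phantom are
registered groupwise (template-free, multi-channel log-demons with
debiasing).  If the atlas machinery works, the evolving template converges
back to the base anatomy: normalised cross-correlation ≥ 0.95 and a residual
mean displacement well under half a voxel.
"""

from fetalatlas.experiments import template_recovery_experiment

res = template_recovery_experiment(seed=42, grid=48, n_scans=8)
print(f"scans: {res['n_scans']} known diffeomorphic warps at {res['grid']}³")
print(f"NCC(template, base image)     = {res['ncc']:.4f}  (target ≥ 0.95)")
print(f"mean displacement after debias = {res['mean_displacement']:.3f} vox "
      "(target ≤ 0.5)")
print(f"min Jacobian determinant       = {res['min_jacobian']:.3f}  "
      "(> 0 ⇒ all fields diffeomorphic)")
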