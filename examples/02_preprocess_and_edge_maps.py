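"""Standardise one scan and compute its monogenic edge map.

Shows the preprocessing contract: isotropic 0.6 mm resampling, brain
masking, histogram matching to a reference, and the multiscale
feature-asymmetry edge map (phase-based, so invariant to intensity rescaling)
that serves as the second registration channel.
"""

import numpy as np

from fetalatlas.preprocess import (histogram_match, mask_brain,
                                   monogenic_feature_asymmetry,
                                   resample_isotropic)
from fetalatlas.synthetic import PhantomSpec, generate_phantom

spec = PhantomSpec(ga_weeks=24.0, grid_size=48, noise_level=0.3, seed=1)
vol, lab = generate_phantom(spec)
ref, _ = generate_phantom(PhantomSpec(ga_weeks=24.0, grid_size=48,
                                      noise_level=0.3, seed=2))

vol = resample_isotropic(vol, 0.6)          # no-op here: already 0.6 mm
vol = mask_brain(vol, lab)
matched = histogram_match(vol, ref, mask=lab.mask(), ref_mask=None)
edge = monogenic_feature_asymmetry(matched)

brain = lab.mask()
print(f"intensity range in brain: {vol.values[brain].min():.3f} "
      f"– {vol.values[brain].max():.3f}")
print(f"edge map range: {edge.values.min():.3f} – {edge.values.max():.3f}")
print(f"mean edge response inside brain: {edge.values[brain].mean():.4f}")
print(f"mean edge response outside brain: {edge.values[~brain].mean():.4f}")

# contrast invariance: rescaling intensities barely moves the edge map
edge2 = monogenic_feature_asymmetry(matched.with_values(
    4.0 * matched.values + 10.0))
print(f"max |change| under a positive affine intensity rescale: "
      f"{np.abs(edge.values - edge2.values).max():.4f} (should be ≈ 0)")
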