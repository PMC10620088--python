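"""Detect an injected hemispheric asymmetry by tensor-based morphometry.

Left-visible phantoms carry a 15% regional dilation; right-visible phantoms
are symmetric.  The right group is mirrored across the midsagittal plane,
a joint groupwise atlas is built, and the per-scan log-Jacobians are
compared left vs right with a max-TFCE permutation test at corrected
P < 0.05.  The significant cluster should land on (and cover most of) the
injected region; a symmetric cohort should come back empty.

Takes a couple of minutes at the default 48³ / 10+10 setting — pass smaller
numbers to explore.
"""

from fetalatlas.experiments import asymmetry_experiment

res = asymmetry_experiment(seed=0, grid=48, n_per_group=10, dilation=0.15,
                           n_perm=300)
print(f"cohort: {res['n_per_group']}+{res['n_per_group']} scans at "
      f"{res['grid']}³, dilation {res['dilation']:.0%}")
print(f"significant voxels at corrected P<0.05: {res['n_significant']}")
print(f"injected region covered by cluster:    "
      f"{100 * res['region_overlap']:.1f}%  (region of "
      f"{res['n_region_voxels']} voxels)")
# A coverage above ~50% means the morphometry pipeline localises the true
# asymmetry, not merely detects that something differs somewhere.
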