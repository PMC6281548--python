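"""How background correction degrades when the hot-region mask goes stale.

The bladder fills during a 90-minute scan (anisotropic growth toward +y),
but the mask segmented at the 1-minute timepoint is used for correction at
every timepoint.  Activity in the unmasked bladder rim is not corrected and
grows with time.
"""

import warnings

from spillrecon.experiments import ExperimentConfig, run_segmentation_mismatch

warnings.simplefilter("ignore")  # late timepoints legitimately overrun lesions

cfg = ExperimentConfig(
    grid_shape=(96, 96), voxel_size_mm=(3.0, 3.0),
    n_views=112, n_tang=112, bin_size_mm=3.0, rays_per_bin=4,
    total_counts=5e5, n_realisations=1, n_subsets=28, n_iterations=10,
    seed=5,
)
report = run_segmentation_mismatch(cfg)

print("timepoint  rim voxels  mean rim activity (SUV)")
for t in report["timepoints"]:
    r = report["residual"][t]
    print(f"  {t:5.0f} min   {r['rim_voxels']:6d}      {r['rim_mean_activity']:8.2f}")
print("\nAt 1 min the mask is exact and the rim is empty; by 90 min the")
print("uncorrected rim carries bladder-level activity — the stale-mask")
print("failure mode that makes segmentation accuracy critical for BC.")
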