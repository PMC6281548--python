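"""Reconstruct one noisy acquisition with OSEM, OSEM+PSF and OSEM+PSF+BC
and compare lesion uptake.

Background correction (BC) segments the hot bladder, multiplies the mask
into a 5-iteration OSEM+PSF image, forward-projects it and holds the result
as a fixed background term in the EM denominator, so the corrected image
excludes the bladder and its spill-in by construction.
"""

import numpy as np

import spillrecon as sr
from spillrecon.metrics import roi_mask

grid = sr.ImageGrid((128, 128), (2.34, 2.34))
geom = sr.ProjectionGeometry(n_views=168, n_tang=180, bin_size=2.0)
psf = sr.PSFModel(4.2, 5.7)
model = sr.SystemModel(geom, grid, rays_per_bin=10, psf=psf)
phantom = sr.make_pelvic_phantom(grid, bladder_suv=55.5)
mask = sr.region_mask(phantom, "bladder")

noise = sr.NoiseModel(total_counts=1e6, n_realisations=1, seed=1)
ss = sr.simulate_acquisition(phantom, model, noise)[0]

configs = {
    "OSEM": sr.ReconConfig("OSEM", 28, 30, post_filter_fwhm_mm=4.0,
                           track_loglik=False),
    "OSEM+PSF": sr.ReconConfig("OSEM_PSF", 28, 30, psf=psf,
                               post_filter_fwhm_mm=4.0, track_loglik=False),
    "OSEM+PSF+BC": sr.ReconConfig("OSEM_PSF_BC", 28, 30, psf=psf,
                                  post_filter_fwhm_mm=4.0,
                                  bc=sr.BackgroundSpec(mask, 5),
                                  track_loglik=False),
}

print("lesion SUVmax / SUVmean at 30 iterations, 4-mm post-filter")
print("(true lesion SUV is 8; L3 is proximal to the bladder)")
for name, cfg in configs.items():
    res = sr.osem_reconstruct(ss, model, cfg)
    row = []
    for lesion in ("L1", "L2", "L3"):
        spec = phantom.region(lesion)
        m = roi_mask(sr.ROISpec(spec.centre, 10.0, lesion), grid)
        row.append(f"{lesion}: {res.final[m].max():5.2f}/{res.final[m].mean():4.2f}")
    bladder_mean = res.final[mask].mean()
    print(f"  {name:12s} {'  '.join(row)}   bladder-region mean {bladder_mean:5.2f}")
print("\nBC leaves the bladder region near zero: its counts are explained by")
print("the fixed background term instead of the image.")
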