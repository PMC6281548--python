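"""Contrast-to-noise ratio of the NEMA-IQ spheres next to a hot bottle.

Each sphere is scored against a same-sized background ROI at the same
distance from the bottle: CNR = (mean_S - mean_B) / sqrt(SD_S^2 + SD_B^2).
Larger spheres recover more activity (less spill-out) and score higher.
"""

import numpy as np

import spillrecon as sr
from spillrecon.metrics import roi_mask

grid = sr.ImageGrid((128, 128), (2.34, 2.34))
geom = sr.ProjectionGeometry(n_views=168, n_tang=180, bin_size=2.0)
psf = sr.PSFModel(4.2, 5.7)
model = sr.SystemModel(geom, grid, rays_per_bin=10, psf=psf)

nema = sr.make_nema_phantom(grid)
noise = sr.NoiseModel(total_counts=1e6, n_realisations=1, seed=3)
ss = sr.simulate_acquisition(nema, model, noise)[0]

bottle = sr.region_mask(nema, "bottle")
cfg = sr.ReconConfig("OSEM_PSF_BC", 28, 3, psf=psf,
                     bc=sr.BackgroundSpec(bottle, 5), track_loglik=False)
res = sr.osem_reconstruct(ss, model, cfg)

print("sphere  diameter  CNR   (OSEM+PSF+BC, 3 iterations, no filter)")
for sphere, bg in zip(nema.regions[2:], nema.rois):
    d = float(np.atleast_1d(sphere.size)[0])
    smask = sr.region_mask(nema, sphere.label)
    bmask = roi_mask(sr.ROISpec(bg.centre, d, bg.label), grid)
    rep = sr.cnr(smask, bmask, res.final_unfiltered)
    print(f"  {sphere.label}     {d:4.0f} mm  {rep.cnr:6.2f}")
print("\nCNR grows with sphere diameter; background correction removes the")
print("bottle's spill-in that would otherwise drown the smallest spheres.")
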