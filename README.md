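# spillrecon

Analytical PET simulation and iterative reconstruction for studying — and
correcting — the **spill-in effect**: apparent activity that a highly
radioactive region (typically the urinary bladder) contributes to nearby
tissue through the scanner's finite resolution. Spill-in inflates the SUV of
lesions near the hot region and can obscure them entirely, which matters for
anyone quantifying pelvic FDG-PET or ⁶⁸Ga-PSMA scans.

The package is aimed at image-reconstruction researchers: it provides a
self-contained desk-scale simulation/reconstruction/evaluation loop — no
scanner data required — with synthetic phantoms standing in for a pelvic
(XCAT-style) geometry and a NEMA-IQ sphere phantom.

## What it implements

**Forward model.** A Siddon-style ray-driven projector (10 sub-rays per bin)
with an image-space Gaussian resolution model, assembled as a sparse system
matrix so projection and backprojection are exact adjoints. Acquisitions are
simulated as `E[y] = M·H′x + A` with attenuation + constant normalisation in
the multiplicative term `M`, expected scatter (35% of prompts) and randoms
(20%) in the additive term `A`, and Poisson noise at a target count level.

**Reconstruction.** Ordered-subset EM in three variants:

- `OSEM` — the plain update;
- `OSEM+PSF` — the system PSF (4.2 mm transverse / 5.7 mm axial FWHM) folded
  into forward and back projection, `H′ = H·PSF`;
- `OSEM+PSF+BC` — background correction: the segmented hot-region mask `S`
  is multiplied into an early (5-iteration) OSEM+PSF image `f⁽ᴺ⁾`, the
  product is forward-projected to a fixed background sinogram
  `P = M ⊙ H′(S ⊙ f⁽ᴺ⁾)`, and the EM update becomes

  ```
  f_j ← f_j / Σᵢ H′ᵢⱼ Mᵢ · Σᵢ H′ᵢⱼ [ yᵢ Mᵢ / (Mᵢ (H′f)ᵢ + Aᵢ + Pᵢ) ]
  ```

  so the reconstructed image excludes the hot region and its spill-in by
  construction.

**Evaluation.** SUVmax/SUVmean statistics over spherical ROIs (mean, SD with
the n−1 denominator, SEM, percent bias), percent SUV change across a bladder
activity sweep, contrast-to-noise ratio against matched background ROIs, and
morphological **shell analysis**: the hot mask is dilated with a Euclidean
ball (2…10 voxels), and each ring shell is summarised by the mean percent
activity difference d̄ between reconstruction and truth (normalised by the
hot region's true SUV), its SD over shell voxels, and the Bland–Altman 95%
limits of agreement d̄ ± 1.96·SD.

## Worked example

```bash
python examples/reconstruct_variants.py
```

simulates one 10⁶-count acquisition of the pelvic phantom (bladder SUV 55.5,
10-mm lesions of SUV 8) and reconstructs it three ways (28 subsets, 30
iterations, 4-mm post-filter):

```
lesion SUVmax / SUVmean at 30 iterations, 4-mm post-filter
(true lesion SUV is 8; L3 is proximal to the bladder)
  OSEM         L1:  7.61/3.68  L2:  3.51/1.62  L3: 10.45/3.02   bladder-region mean 53.11
  OSEM+PSF     L1:  9.71/3.86  L2:  4.38/1.68  L3: 14.24/4.39   bladder-region mean 53.86
  OSEM+PSF+BC  L1:  9.58/3.79  L2:  4.35/1.69  L3: 13.99/4.32   bladder-region mean  0.89
```

The proximal lesion L3 overshoots its true SUVmax of 8 under every variant
at this noise level, and the background-corrected image zeroes the bladder
(mean 0.89 vs 53) while leaving the lesions intact. The companion script
`examples/shell_spill_analysis.py` prints the per-shell d̄ table: at this
scale uncorrected OSEM leaves ~15% of the bladder's activity in the 1–2-voxel
shell (~21% after filtering), OSEM+PSF ~8%, and background correction ~6%,
all decaying to ≲1% beyond 4 voxels.

Other examples: `build_phantoms.py` (phantom geometry), `simulate_acquisition.py`
(count bookkeeping), `nema_cnr.py` (sphere CNR next to a hot bottle),
`segmentation_mismatch.py` (stale-mask failure mode of BC).

A thin CLI wraps the same library for shell use:

```bash
spillrecon experiment --config cfg.yaml --study shells -o report.json
spillrecon recon --sino sim/sino_000.h5 --variant osem+psf+bc --subsets 28 \
    --iters 30 --psf 4.2,5.7 --filter 4 --mask bladder.nii.gz -o out/
```

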