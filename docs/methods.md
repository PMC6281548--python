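# Methods

## Scope and model

`spillrecon` studies spill-in from a hot region into its surroundings with a
fully analytical loop: synthetic phantom → noisy sinogram simulation → OSEM
reconstruction (optionally with PSF modelling and background correction) →
quantitative evaluation. The same linear system model is used to simulate
and to reconstruct. This "inverse crime" is deliberate: it isolates the
behaviour of the reconstruction algorithms from physics mismatch, at the
cost that absolute recovery is optimistic relative to real data. All
statements the test suite makes should be read with that in mind.

### Projector

Parallel-beam sampling: `n_views` angles over 180°, `n_tang` tangential bins
of `bin_size` mm (defaults 168 × 180 × 2.0 mm, chosen to cover the 300-mm
field of view with ~2-mm bins and a view count comparable to the bin count
and divisible by 28 subsets). Each bin averages `rays_per_bin` (default 10)
sub-rays traced through the grid with exact intersection lengths (Siddon
traversal, implemented as a numba kernel that assembles a sparse CSR
matrix). Because forward and back projection are `H` and `Hᵀ` of one stored
matrix, adjointness holds to machine precision — the test suite verifies
this and checks the traced weights against an independent slab-clipping
oracle on toy grids.

The 3D mode is a simplified cylindrical geometry: a stack of direct planes
(one per image slice) sharing the transverse matrix, with the axial PSF
component coupling slices in image space. Oblique-plane (span /
ring-difference) bookkeeping is not modelled; nothing in the shipped studies
needs it, and the desk-scale replication runs in 2D.

### Resolution model

The PSF is a separable Gaussian, FWHM 4.2 mm transverse and 5.7 mm axial by
default, applied in image space: the image is convolved before ray tracing
(and, for the adjoint, after backprojection). Kernels are unit-sum with
reflective boundaries and truncated at 4σ. The same `H′ = H·G` operator
serves simulation and reconstruction. Note that image-space blurring does
not commute with ray tracing; no such identity is assumed anywhere.

### Acquisition simulation

Expected trues are `ACF ⊙ H′(x)` with survival probabilities
`ACF = exp(−∫µ dl)` computed on PSF-free rays (µ in 1/cm; water 0.096).
Scatter uses a documented surrogate for a physical estimate: the emission
blurred with a wide 40-mm FWHM Gaussian, forward-projected and scaled —
reproducing scatter's low-frequency character in projection space. Randoms
are flat. Scaling is exact: expected trues + scatter + randoms equal the
requested total (default 10⁶ counts) with scatter and randoms at exactly
their requested fractions (defaults 35% and 20%). The global
counts-per-activity calibration is absorbed into the constant normalisation
inside the multiplicative term, so reconstructions come out directly in SUV
units. Realisation *k* draws Poisson counts with seed `base_seed + k`; the
reconstruction receives the *expected* additive term, the idealisation
appropriate to a simulation study.

### Reconstruction

Ordered-subset EM with round-robin view assignment (subset *s* owns views
`v ≡ s mod S`) processed in bit-reversed order, uniform initialisation on
the reconstructable support, and per-subset precomputed sensitivities.
Zero-sensitivity voxels are frozen at 0; bins with zero model value
contribute 0 to the backprojection (0/0 := 0). Defaults follow the study
setup: 28 subsets, 30 full iterations, optional 4-mm isotropic Gaussian
post-filter applied to the *output only* (it never feeds back into
iterations). The per-iteration Poisson log-likelihood can be tracked; MLEM
(1 subset) is verified non-decreasing.

Background correction builds `P = M ⊙ H′(S ⊙ f⁽ᴺ⁾)` from the exact hot-region
mask `S` and an internal OSEM+PSF reconstruction at `N = 5` full iterations,
then holds `P` fixed for all subsequent iterations. The convention that `P`
lives in prompt (counts) space with `M` applied during construction is
validated by an exact-cancellation oracle: with hot-region-only data and the
exact `P`, the reconstruction decays to zero (L∞ < 10⁻³ × hot SUV after 50
iterations at 28 subsets). Bias and shell comparisons for corrected images
use the truth with the hot region removed, mirroring how the corrected image
is defined.

## Synthetic phantoms

**Pelvic preset.** A soft-tissue body (SUV 1.0 — the surroundings are
visibly non-zero but no published value exists, µ = 0.096/cm) containing a
spherical bladder of 500 ml at SUV 8.5–55.5, three 10-mm lesions of SUV 8 at
surface-to-surface distances L1 = 25, L2 = 35 and L3 = 15 mm (L3 is the
proximal lesion; published positions give only "15–20 mm" vs ">20 mm", so
the distances are configuration), and a same-sized reference lesion B at
70 mm, far enough to be free of spill-in. Voxel membership is centre-inside;
ground-truth SUVs are carried on region specs and never re-estimated from
images. On a 2D grid the bladder is a disc with the equal-volume sphere's
radius.

**Bladder filling.** Volumes 100/150/250/350/500 ml and SUVs
8.5/19.3/33.8/44.6/55.5 at 1/10/30/45/90 min — literature-style values
chosen to span the activity sweep, since no numeric course is published.
Growth is anisotropic with a 2:1 bias toward +y ("anterior") and the
posterior surface held fixed; an expansion that overruns a lesion issues a
warning rather than an error, because a stale mask overrunning anatomy is
precisely the failure mode under study.

**NEMA-IQ preset.** A central 500-ml hot cylinder (bottle:sphere
concentration ratio 1.38, matching 77.9 MBq/500 ml vs 5.38 MBq across the
six spheres) ringed at 75 mm by spheres of 10/13/17/22/28/37 mm in a cold
water body. Six same-sized cold background ROIs sit interleaved at the same
bottle distance; each ROI centre is snapped to the voxel lattice relative to
its paired sphere so both masks are exact translates (identical voxel counts
by construction). The 75-mm ring departs from the physical phantom's tighter
layout so that the 37-mm sphere and its background ROI remain disjoint.

## Evaluation

SUV statistics follow the standard estimator set: per-realisation SUVmax and
SUVmean over a lesion-sized spherical ROI; mean M̄; SD with the n−1
denominator; SEM = SD/√N; bias (M̄−T)/T × 100 against the spec'd truth.
Percent change across a bladder sweep is (SUV_high − SUV_low)/SUV_low × 100,
computed with *paired* realisation seeds at the two activity levels so the
contrast is not diluted by realisation luck.

Shell analysis dilates the hot mask with a Euclidean ball in voxel units
(anisotropy ignored — "dilate by n voxels"), implemented via the exact
Euclidean distance transform, which the tests verify against brute-force
distance thresholding. Ring shells 1–2, 3–4, …, 9–10 are pairwise disjoint
and exclude the mask. Within a shell, d_k = (recon_k − true_k)/T_hot × 100.
The normalising denominator is the one genuinely open choice here: the
alternative per-voxel normalisation (by true_k) is available behind a flag
but undefined where the true value is 0 and explosive where it is ~1; the
hot-SUV denominator reads naturally as "spill-in as a percentage of the hot
activity" and is the default. d̄, SD (n−1 over shell voxels) and
LOA = d̄ ± 1.96·SD summarise each shell.

CNR is (mean_S − mean_B)/√(SD_S² + SD_B²) per sphere against its matched
background ROI; undefined (signalled) when both SDs vanish.

## Desk-scale study conditions

The shipped studies run on a 2D 128×128 grid at the scanner voxel size
2.34 mm, 10⁶ expected counts (the per-slice equivalent of 65·10⁶ counts over
an 89-slice volume), 5 noise realisations, 28 subsets × 30 iterations. A
full study (three variants, five realisations) takes ~1 minute on one CPU.

What this scale does and does not show:

- Shell spill-in and its ordering (OSEM > OSEM+PSF > BC in the inner shell,
  outward decay, aggravation by the post-filter) reproduce robustly.
- Converged OSEM equals the PSF-blurred truth here (same model simulates and
  reconstructs), so the inner-shell d̄ (~15%) is set by the PSF-to-voxel
  geometry. Scanner-scale reports of ~30% additionally contain
  segmentation/voxelisation boundary effects that an exact analytic mask
  does not produce — visible in published limits of agreement whose lower
  bound requires true-hot voxels inside the shell.
- SUVmax responses to the bladder sweep are noise-dominated at 5
  realisations: the seed-to-seed spread of the proximal lesion's percent
  change (~±30 points) exceeds the systematic effect. With a 4.2-mm FWHM
  kernel there is no direct blur contribution 15 mm from the bladder edge;
  the proximal SUVmax inflation is a noise-amplification effect near the hot
  region and resolves only with many realisations. The suite states the
  qualitative claims at the prescribed scale and some of them are
  legitimately not resolvable there; they are kept rather than weakened.

## Numerical choices

- Ray tracing: 0-based voxel indices, world coordinates at voxel centres,
  intersection lengths in mm (converted to cm only inside the attenuation
  exponent); sub-ray offsets uniform within the bin; segment midpoints
  assign boundary-grazing rays deterministically.
- Sparse matrix in float64; adjointness is exact, verified to 10⁻¹⁰.
- Gaussian convolutions use reflective boundaries (self-adjoint for the
  symmetric kernel), truncation 4σ.
- EM guards: 0/0 := 0 in the ratio; voxels with zero subset sensitivity
  frozen at 0; iterates are nonnegative by construction.
- Degenerate inputs fail loudly: empty ROIs/shells, zero reference values,
  non-positive multiplicative terms, NaNs in images, geometry mismatches.
  The one deliberate warning-not-error is the empty BC mask (degenerates to
  OSEM+PSF) and the growth-overruns-lesion case above.

## Known limitations

No time-of-flight, no spatially variant PSF, no Monte Carlo physics
(positron range, non-collinearity, crystal effects), no listmode, no
dead-time or decay; scatter is a scaled low-frequency surrogate, not a
physical estimate; the 3D mode omits oblique planes. Real-data workflows
(scanner normalisation, MR-based segmentation) are out of scope — masks come
from the phantom's own geometry.
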