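# Methods

## Problem setting

PET resolution is modelled as an isotropic Gaussian point-spread function
(PSF) of 8 mm FWHM (σ = FWHM / (2√(2 ln 2)) ≈ 3.40 mm), the uniform
resolution that harmonised multi-site amyloid data are smoothed to. At that
resolution, a 3–4 mm cortical ribbon loses signal to its neighbours
(spill-out) and receives signal from the tracer-hot white matter
(spill-in). MR-guided PVC corrects this using a label map in MR space —
which makes the correction only as good as the PET–MR rigid registration.
PoR closes that loop by re-registering against a PSF-matched synthetic
image derived from the correction itself.

## Partial volume correction

**GTM.** The spill-over matrix is built by blurring each region's indicator
with the PSF and averaging the result over every region:
W<sub>ij</sub> = mean<sub>x∈i</sub>(I<sub>j</sub> ∗ h)(x). The corrected
concentrations solve `W c = b` by LU decomposition; if cond(W) > 10⁶ the
result is flagged and a least-squares pseudo-solve is used instead (the
matrices here are ~10×10 to ~25×25, so stability costs nothing). W depends
only on the label geometry and the PSF, so it is computed once per study
and cached across loop iterations. Note that the columns of this
regional-*mean* matrix are not mass fractions; the volume-weighted form
V<sub>ij</sub> = W<sub>ij</sub>·n<sub>i</sub>/n<sub>j</sub>
(`mass_fraction_matrix`) is the one whose columns sum to ≤ 1, the
"signal is never created" bound, with the remainder spilling outside all
VOIs. A 15 mm extracerebral shell VOI captures near-brain spill so it is
accounted for rather than lost.

**RBV.** The voxel-wise map is f(x)·s(x)/(s∗h)(x) with s the
piecewise-constant synthetic image. Voxels where |s∗h| falls below
`epsilon_frac` (default 10⁻³) of its maximum are set to zero — this only
touches air, where the ratio would otherwise blow up. Negative corrected
values (possible under noise) are preserved, not clipped; clipping would
bias the registration target.

**Smoothing.** Gaussian filtering uses mirror (reflect) boundaries — which
conserve regional means near the image edge better than zero padding — and
a 4σ kernel cutoff (<10⁻⁴ mass loss). Anisotropic voxels are handled by
converting σ to voxel units per axis from the affine's column norms.

## Registration

Similarity is Studholme-normalized mutual information,
(H(A)+H(B))/H(A,B) ∈ [1, 2], over 64×64 joint histograms spanning the
1st–99th intensity percentiles, masked to voxels where the fixed image is
positive (for the loop's synthetic target: above 10⁻³ of its maximum, so
air never dominates the histogram). Two histogram estimators exist:

* `nmi_score` (reporting) uses hard binning — the pure measure, where
  identical images score exactly 2;
* the optimizer uses partial-volume (bilinear) binning, spreading each
  sample over the 2×2 neighbouring bins. Hard binning leaves the objective
  piecewise-flat under sub-voxel motion, and a derivative-free optimizer
  then chases bin-crossing jitter of ~0.5–1°; the bilinear estimator makes
  the surface smooth enough for sub-0.05° repeatability.

The six rigid parameters (tx, ty, tz in mm; Euler x→y→z rotations in
degrees, right-handed, about the fixed image's FOV centre, recorded in the
transform) are optimised by Powell search, with millimetres and degrees
treated as commensurate steps. Two levels are used: a capture level
(4 mm pre-smoothing, grid decimated 2× below the evaluation step) and a
full-precision level. The fixed grid is evaluated at the moving image's
native resolution (`fine_step`, auto-derived from the voxel-size ratio): a
1 mm target grid carries no extra NMI information about a 2 mm PET, only
cost. Convergence tolerances are 0.1 (coarse) and 0.01 (fine) in the
commensurate units. The returned fit is guaranteed not to degrade the
fine-level objective relative to the initial transform (with a 10⁻⁴ slack
absorbing re-binning noise between levels); a violation raises with the
full evaluation trace attached.

All resampling is a single trilinear (or nearest, for labels) interpolation
through the composed voxel→world→voxel map; the loop always resamples the
*original* PET through the cumulative transform, never chains
interpolations. Out-of-field voxels take the fill value 0 (PET backgrounds
are ~0) and can be counted on request.

## The PoR loop

Iteration 1 is the conventional registration of the PET to the structural
target — a supplied T1 volume, or a pseudo-structural image rendered from
the label map (distinct evenly-spaced intensity per region, 1 mm
pre-smoothing; NMI needs label-consistent classes, not realistic T1
contrast). Each subsequent iteration corrects at the current transform,
renders and smooths the synthetic, and re-registers. The loop stops when
max |Δt| < 0.05 mm **and** max |Δr| < 0.05° between iterations
(`max_iter` = 10 default; non-convergence is flagged on the Results object,
not raised). The final GTM/RBV correction is recomputed at the converged
transform so all reported quantities are mutually consistent.

Two re-estimation modes exist for step (iv). The default, `full`,
re-registers the original PET to each iteration's synthetic, warm-started
at the current estimate. The alternative, `incremental`, registers the
currently-resampled PET to the synthetic and composes the increment. In
our experiments the incremental mode can enter a two-state limit cycle
~0.6° wide — the re-resampled PET and re-derived synthetic each shift the
NMI optimum to the other state — and then never meets the stopping rule,
while the full mode converges monotonically in ≤ 3–5 iterations; hence the
default. Both modes leave iteration 1 as the conventional baseline, so
conventional-vs-PoR comparisons read off the first and last trace rows.

## The phantom

The generator emulates the features of an amyloid study that matter for
PVC and registration, at desk scale (labels 96³ @ 1 mm standing in for a
clinical 256³ MR space; PET 48³ @ 2 mm):

* a WM ellipsoid (semi-axes 26/32/20 mm) wrapped in a ~3.5 mm cortical GM
  ribbon whose thickness is modulated in both angular coordinates
  (amplitude 1 mm) — a gyral-folding stand-in that stresses partial volume
  and, importantly, makes all three rotations identifiable (a smooth
  near-spherical object leaves rotations undetermined to ~1°, which no
  registration method could resolve; real FreeSurfer label maps constrain
  rotation strongly, so the generator must too);
* four GM sectors (frontal/parietal/temporal/occipital) split by direction,
  asymmetric subcortical nuclei, and a cerebellum tucked directly beneath
  the posterior cerebrum with a tracer-hot WM core (corpus medullare)
  inside the cerebellar-GM reference — the adjacency that makes the
  reference sensitive to axial misregistration, as in real heads;
* WM-dominant activity (WM 2.0, cortical GM 1.0, cerebellar GM 1.0,
  cerebellar WM 2.0, subcortical 1.6; the amyloid-positive preset raises
  cortical GM to 2.2), mirroring PiB-like contrast;
* simulation order truth → PSF blur → rigid motion → PET grid → additive
  Gaussian noise (default SD 0.05 = 5% of cortical GM), all behind one
  seed; identical spec + seed is bitwise reproducible.

What the phantom does **not** emulate: spatially correlated PET noise
(reconstruction kernels correlate neighbours; additive white noise is
harsher per-voxel but easier to reason about), attenuation/scatter
artefacts, MR intensity inhomogeneity, and segmentation error. Passing
tests therefore demonstrate correctness of the mechanics and the claimed
qualitative behaviours, not clinical performance.

## The axial-bias experiment

With a 2.74 mm +z misalignment injected, the experiment compares GTM
estimates under two transforms: the PoR fit, and a "conventional
registration that missed the shift" (the identity). The miss is injected
deliberately: a well-posed NMI registration on clean phantom data simply
recovers the shift (residuals ~0.1 mm), and the causes of the systematic
conventional failures seen on clinical data are unknown — they cannot be
manufactured from first principles, so the experiment reproduces their
documented magnitude instead. The mechanism then shows plainly: the
superior (parietal) sector is depressed (its VOI samples beyond the
displaced brain), while the inferior cortex and the cerebellar GM
reference are inflated (cerebral and cerebellar-WM activity displaced into
them) — and an inflated reference depresses SUVR everywhere. PoR removes
the bias.

## Numerical conventions and edge cases

* Voxel indices are 0-based; world coordinates are NIfTI RAS+ mm.
  Rotations are stored in (−180°, 180°].
* Regional SD is the sample SD (n−1); CoV = SD/mean × 100%. Empty regions
  yield n = 0 rows with NaN statistics, never exceptions.
* SUV assumes 1 g/mL tissue density; SUVR's reference-region output mean
  is exactly 1 by construction. The cortical composite SUVR is an
  unweighted mean of region means (voxel-weighted available via a flag).
* The shell is built from an exact Euclidean distance transform
  (anisotropy-aware, computed on a padded grid so FOV truncation is
  detected and reported).
* Paired effect size mean(d)/SD(d) raises on zero difference variance
  rather than returning a spurious large number.
* trilinear round-trip resampling (T then T⁻¹) is exact only for
  lattice-preserving transforms; for generic sub-voxel motion the error is
  curvature × voxel², a few percent of the peak for realistic smoothness —
  the motivation for never chaining resamplings in the loop.

## Problem sizes

The shipped evaluation uses the default phantom (96³ labels, 48³ PET,
9 regions including shell): GTM/RBV exactness on one clean scan,
registration recovery on three injected offsets, PoR recovery on five
noisy studies at the worst-case misregistration, one axial-bias study, and
one amyloid-positive SUVR study — about a minute end-to-end on one CPU.
Unit tests run the same machinery on a 64³ @ 1.5 mm phantom.

## Known limitations

* Rigid-body motion only; no non-rigid registration, no 4-D dynamic data.
* The GTM/RBV formulations are the standard published ones; boundary
  handling or mask conventions in other implementations may differ in
  detail.
* The FreeSurfer merge table shipped in `petpor/data` is an editable
  template, not a validated reproduction of any published 113→22 mapping.
* Registration accuracy below ~0.05 mm/0.05° is limited by interpolation
  and histogram noise; tolerances tighter than that are not meaningful.
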