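# petpor — iterative registration and partial volume correction for brain PET

Quantitative brain PET — amyloid imaging in particular — is limited by the
scanner's spatial resolution (~8 mm FWHM): activity spills out of thin
cortical gray matter and in from the tracer-hot white matter, biasing
regional estimates. MR-guided partial volume correction (PVC) undoes this
mixing, but it inherits every millimetre of PET–MR misregistration, and the
registration itself is hard precisely because PET and MR have different
contrasts. `petpor` implements **PVC-optimized registration (PoR)**: an
iterative loop that alternates PVC with re-registration of the PET to a
PSF-smoothed synthetic image built from the corrected values — a target
that carries MR anatomy but PET-like contrast, so the registration optimum
moves toward the true alignment as the correction improves.

The package is aimed at PET methodologists and image analysts: it consumes
NIfTI volumes and FreeSurfer-style label maps, and it ships a synthetic
brain phantom so every component can be validated against known ground
truth without any clinical data.

## The model

With PSF kernel *h* and region indicators *I<sub>j</sub>*, the **geometric
transfer matrix (GTM)** has entries

> W<sub>ij</sub> = mean over voxels x ∈ region i of (I<sub>j</sub> ∗ h)(x)

(row = observing region, column = source region), and the true regional
concentrations **c** solve `W c = b`, where **b** holds the observed
regional means of the registered PET. The **region-based voxel-wise (RBV)**
map extends this to voxels using the piecewise-constant synthetic image
*s* built from **c**:

> f<sub>RBV</sub>(x) = f(x) · s(x) / (s ∗ h)(x)

The **PoR loop** is then: (i) register PET to the structural image
(conventional baseline); (ii) GTM-correct the registered PET (W is computed
once and cached) and render *s*; (iii) smooth *s* with the PSF; (iv)
re-register the PET to the smoothed synthetic; (v) repeat until the
6-parameter rigid transform changes by less than 0.05 mm / 0.05° per
iteration. Registration maximises normalized mutual information,
NMI = (H(A)+H(B))/H(A,B), with a derivative-free Powell search.
Quantification follows as SUV = c/(dose/weight) and SUVR = SUV divided by
the cerebellar-GM reference mean.

## Worked example

Simulate an amyloid-like phantom scan misaligned by the worst-case rigid
offset seen in clinical conventional-vs-refined comparisons, then recover
the alignment with PoR:

```python
from petpor import PoRModel, RigidTransform
from petpor.phantom import default_pet_grid, simulate_pet_scan
from petpor.psf import PSFModel
from petpor.studies import standard_phantom

labels, truth, spec = standard_phantom()           # 96^3 @ 1 mm labels + shell
injected = RigidTransform(t_mm=[0.32, 0.65, 2.74], r_deg=[3.02, 0.34, 0.35])
pet = simulate_pet_scan(labels, truth, injected, PSFModel(8.0),
                        noise_sd=0.05, seed=1, pet_grid=default_pet_grid(spec))

res = PoRModel(pet, labels, psf=8.0).fit()
print(res.summary())
```

```
PVC-optimized registration (PoR) results
========================================================================
iterations: 3    converged: True    PSF FWHM: 8 mm
regions: 9    cond(W): 7.25
------------------------------------------------------------------------
 iteration       tx       ty       tz       rx       ry       rz  delta_t_max  delta_r_max      nmi
         1   0.3852   0.7647   2.7228   3.0762   0.0350   0.0318       2.7228       3.0762   1.1861
         2   0.3528   0.7273   2.7268   3.0374   0.1346   0.1277       0.0374       0.0997   1.4628
         3   0.3524   0.7072   2.7286   3.0484   0.1344   0.1282       0.0202       0.0111   1.4630
------------------------------------------------------------------------
final transform   t (mm): [+0.352 +0.707 +2.729]  r (deg): [+3.048 +0.134 +0.128]
conventional      t (mm): [+0.385 +0.765 +2.723]  r (deg): [+3.076 +0.035 +0.032]
PoR - conventional: [-0.033 -0.058 +0.006] mm  [-0.028 +0.099 +0.096] deg
```

Iteration 1 is the conventional PET-to-structural registration; the next
two iterations refine it against the smoothed synthetic until the change
drops below tolerance. The final transform matches the injected
(0.32, 0.65, 2.74) mm / (3.02, 0.34, 0.35)° to about 0.05 mm and 0.25°
despite 5% noise. `res.gtm` holds the spill-corrected regional
concentrations, `res.rbv_map` the voxel-wise corrected volume, and
`res.plot_trace()` draws the per-iteration Δt/Δr convergence curves.

The same pipeline is scriptable from the shell:

```sh
por phantom --preset amyloid-positive --seed 1 --shift 0 0 2.74 --out study/
por por --pet study/pet.nii.gz --labels study/labels.nii.gz --out study/out/
```

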