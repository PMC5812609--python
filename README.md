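# ibsa — image-derived body surface area from CT

Body surface area (BSA, m²) is the standard scaling variable for cytotoxic
chemotherapy dosing, yet it is almost always *estimated* from height and
weight with formulas fitted a century ago on small samples. Cancer patients,
however, routinely undergo CT — a direct 3-D picture of the body. This
package measures BSA directly from CT volumes (**iBSA**) and quantifies what
the choice of method means for dosing:

* **Measurement** — fully automatic body segmentation (HU thresholding +
  mathematical morphology) and iso-surface meshing; iBSA is the total
  triangle-face area of the body surface, in cm² and m².
* **Anthropometric models** — the five classical formulas (Du Bois & Du Bois,
  Mosteller, Haycock, Boyd, Gehan & George), e.g. Du Bois

  `BSA = 0.20247 · H^0.725 · W^0.425`  (H in m, W in kg),

  with the first-order error propagation
  `ΔBSA/BSA = 0.725·ΔH/H + 0.425·ΔW/W`.
* **Validation statistics** — percent relative error against analytic truth,
  Bland-Altman agreement (bias, SD, limits of agreement bias ± 1.96·SD),
  bootstrap CIs, and F/t comparison of inter-method variances and biases.
* **Dose-banding simulation** — a Monte Carlo that injects zero-mean Gaussian
  relative error (`sBSA = BSA·(1+ε)`, `ε ~ N(0, σ)`) into a uniform BSA
  population and measures how often the assigned capecitabine dose band
  changes, with an independent quadrature oracle.
* **Phantom factory** — synthetic CT phantoms with analytically known surface
  areas (sphere, cube, cylinder, ellipsoid, composite body), test-retest
  perturbation pairs and correlated height/weight cohorts, so every pipeline
  stage is validated end to end without patient data.

## Worked example

```python
import ibsa

# a 50 mm sphere "scanned" at 1 mm isotropic resolution
phantom = ibsa.sphere_phantom(50.0, spacing=1.0)
cfg = ibsa.SegmentationConfig(min_component_volume_ml=10.0)
m = ibsa.measure_ibsa(phantom.ct, cfg)
print(f"measured {m.area_cm2:.3f} cm^2, truth {phantom.analytic_surface_cm2:.3f}")
print(f"error {ibsa.percent_relative_error(m.area_cm2, phantom.analytic_surface_cm2):+.3f}%")
```

prints

```
measured 314.550 cm^2, truth 314.159
error +0.125%
```

i.e. the pipeline recovers the analytic 4πr² of the sphere to 0.13% at the
default settings. The same from a shell:

```bash
ibsa phantom --shape sphere --radius-mm 50 --spacing-mm 1 --out sphere.nii.gz
ibsa measure --input sphere.nii.gz --out report.json --mask-out mask.nii.gz
ibsa formula --model dubois --height-m 1.70 --weight-kg 70   # 1.8097 m^2
ibsa simulate --sigma-pct 4.11 --n 1000000 --seed 42 --out sim.json
```

The simulation command reports a reclassification rate of ≈32% — with an
inter-method SD of 4.11% between image-derived and Du Bois BSA, roughly one
patient in three would receive a different capecitabine dose band depending
on which method measured their BSA.

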