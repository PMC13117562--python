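# cranioland

**Sella-turcica prediction and sella–nasion realignment of 3D cranial
surface meshes.**

Craniosynostosis follow-up increasingly relies on 3D stereophotogrammetry
— radiation-free surface captures of an infant's head.  Comparing such
captures over time requires aligning them in the standard
sella–nasion (S-N) cephalometric frame, but the sella turcica (ST) is a
*bony* landmark that surface scans cannot show.  `cranioland` predicts
the ST coordinate from the cranial surface alone and uses it to realign
meshes into the S-N frame.  It is written for researchers in 3D
craniofacial image analysis who need a reproducible, clinically-shaped
pipeline they can run end to end on synthetic phantoms or on their own
annotated STL meshes.

## Method

Given a triangulated cranial surface (STL, mm) with three annotated
soft-tissue landmarks (nasion *N*, left/right supra-aurale):

1. **Standardize.** Rigidly align to a canonical horizontal pose, then
   resample by casting rays from the supra-aural midpoint along the 1016
   fixed directions of a hemi-icosphere template, keeping the farthest
   hit per ray.  Every subject becomes 1016 corresponded vertices.
2. **Shape features.** PCA of the flattened vertex data to 32
   components; the first 10 standardized scores **s** plus a 4-element
   subtype indicator **c** (control / plagiocephaly / trigonocephaly /
   scaphocephaly) form the 14-vector input **x** = [**s**, **c**].
3. **Regress.** A residual feedforward network
   `dense(14→8) → ReLU → dropout(0.5) → 3 × [x + ReLU(dense(8→8)x)] →
   dropout(0.1) → dense(8→3)` maps **x** to the ST coordinate (mm),
   trained with Adam (MSE, batch size 1, 400 epochs, lr 10⁻³ halved
   every 100 epochs) under subtype-stratified 5-fold cross-validation.
4. **Baseline.** The Computed Cranial Focal Point — the least-squares
   convergence point **p** of the surface normal lines,
   argmin<sub>p</sub> Σᵢ ‖(I − nᵢnᵢᵀ)(p − vᵢ)‖² — plus a per-subtype
   offset calibrated on training folds.
5. **Evaluate.** Euclidean and per-axis ST deviations; S-N realignment
   quality via signed distance maps (5th/95th percentile, mean) between
   each method's alignment and the true-ST alignment; paired t or
   Wilcoxon signed-rank comparisons gated by a Shapiro–Wilk normality
   check.

Because no clinical data ship with the package, a seeded phantom
generator produces superellipsoid head shells with class-specific
deformations and an analytically known interior ST (see
`docs/methods.md`).

## Worked example

```python
from cranioland import SellaLandmarkModel, RunConfig

model = SellaLandmarkModel.from_synthetic(n_per_class=10, seed=7,
                                          config=RunConfig(epochs=100, seed=7))
results = model.fit(compute_maps=True)
print(results.summary())
```

```
Sella landmark prediction — cross-validated results
=========================================================
subjects: 40    folds: 5    seed: 7
epochs: 100    features: 10 PC scores + 4 class indicators

method       Euclid mean±SD (mm)   dx mean   dy mean   dz mean
--------------------------------------------------------------
ffnn               3.26 ± 1.82      -0.02     -0.22      0.33
ccfp               6.13 ± 2.70      -0.00     -0.00      0.00

method        map p5   map p95  map mean  (S-N realignment, mm)
ffnn           -3.02      3.39      0.24
ccfp           -6.49      7.05      0.42

euclidean  paired-t      p = 1.043e-07   (Shapiro p = 0.562)
...
network error by subtype (mm):
  control         3.08 ± 1.56   (n = 10)
  plagiocephaly   3.08 ± 1.85   (n = 10)
  scaphocephaly   3.68 ± 2.49   (n = 10)
  trigonocephaly  3.19 ± 1.41   (n = 10)
```

Reading this: on a 40-subject phantom cohort the network predicts the ST
with a mean error of 3.26 mm against 6.13 mm for the CCFP baseline
(paired-t p ≈ 10⁻⁷), and meshes realigned with the network's ST sit
within ±3.4 mm (5th–95th percentile band) of the true-ST alignment
versus ±7 mm for the baseline.  The per-axis columns are signed means:
near zero for both methods, i.e. neither is systematically biased; the
baseline's zeros are by construction (its offset is a fitted mean).

The same pipeline is available from the shell:

```sh
cranioland simulate --n-per-class 10 --seed 7 --out phantoms/
cranioland train --manifest phantoms/manifest.csv --seed 7 --out run/
cranioland predict --model run/predictor --mesh phantoms/scap-003.stl \
                   --landmarks phantoms/scap-003.json --subtype scaphocephaly
cranioland align --mesh phantoms/cont-000.stl --landmarks phantoms/cont-000.json \
                 --st-source true --out aligned.stl
```

## Layout

```
src/cranioland/
  meshio.py        STL + landmark JSON + manifest I/O, coordinate convention
  standardize.py   horizontal alignment, ray template, raycast resampling
  geometry.py      ray/triangle and point/triangle kernels
  shape.py         PCA shape model and feature vectors
  network.py       residual regression network, training, cross-validation
  ccfp.py          focal-point baseline and offset model
  frames.py        S-N reference frame construction and realignment
  metrics.py       deviations, signed distance maps, paired testing
  phantoms.py      seeded synthetic cohorts with analytic ground truth
  model.py         SellaLandmarkModel / SellaLandmarkResults facade
  persist.py       deployable predictor container (save/load/predict)
  cli.py           `cranioland` command-line interface
```
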