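# pypquant

Quantitative technetium-99m pyrophosphate (⁹⁹ᵐTc-PYP) SPECT/CT analysis for
transthyretin amyloid cardiomyopathy (ATTR-CM).

⁹⁹ᵐTc-PYP scintigraphy is the standard non-invasive test for ATTR-CM, but
planar readings (Perugini grade, heart-to-contralateral-lung ratio) are
confounded by ribs and blood pool. Quantitative SPECT/CT turns the
reconstructed volume into standardized uptake values (SUV) and lets one
measure both *how much* tracer the myocardium binds (disease burden) and
*where* it binds (disease extent). This package implements that analysis
chain for researchers in nuclear cardiology and medical physics:

* **SUV calibration** — a uniform cylinder phantom of known activity
  concentration yields the cross-calibration factor (CCF), and

  `SUV = counts [count/voxel] × CCF [(Bq/mL)/(count/voxel)] / (dose [Bq] / weight [g])`

* **Differentiation metrics** — mean SUV of an ellipsoidal whole-heart VOI
  (SUV_H), the mean of three 19.5 mm-tall cylinder VOIs on the descending
  aorta (SUV_Ao), their ratio rSUV_H/Ao (the ATTR discriminator), and the
  classical planar H/CL ratio.
* **Polar maps** — short-axis reslicing, maximal SUV along radial rays from
  each slice centre arranged concentrically (apex at the centre), and AHA
  17-segment parcellation with per-segment mean/SD.
* **Regional heterogeneity indices** —
  total cardiac SUV `= Σ₁₇ mean SUV`;
  COV `= Σ₁₇ (SD/mean × 100)`;
  `%DS = (Summed SUV_septal − Summed SUV_lateral)/Summed SUV_All × 100`;
  `%BA = (Summed SUV_basal − Summed SUV_apical)/Summed SUV_All × 100`.
* **Cohort statistics** — Pearson correlation, Kruskal–Wallis with
  Steel–Dwass all-pairs post-hoc (asymptotic studentized-range and exact
  permutation modes), Fisher–Freeman–Halton exact tests with Bonferroni
  pairwise correction, and cutoff sensitivity/specificity.
* **Digital phantoms** — seeded generators for the calibration cylinder and
  for cardiac volumes with an ellipsoidal LV shell, per-segment uptake
  multipliers, blood pool / lung / aorta background, Gaussian PSF blur and
  Poisson noise, with exact ground-truth labels and indices.

A 20-patient table of published per-patient regional measurements (total
cardiac SUV, COV, summed basal/apical/septal/lateral SUV; 15 wild-type and
5 hereditary-variant ATTR cases) ships as a checksummed fixture.

## Worked example

Correlate the regional indices with total cardiac SUV on the packaged
patient table:

```python
from pypquant import load_table2, derive_table2_indices, reproduce_table4

cohort = derive_table2_indices(load_table2())
print(reproduce_table4(cohort).to_string(index=False))
```

```
      subset  index         r        p  n
ATTRwt+ATTRv    cov -0.254040 0.279784 20
ATTRwt+ATTRv pct_ds -0.296000 0.205104 20
ATTRwt+ATTRv pct_ba -0.098921 0.678198 20
 ATTRwt only    cov -0.384956 0.156514 15
 ATTRwt only pct_ds -0.727928 0.002094 15
 ATTRwt only pct_ba  0.225689 0.418644 15
  ATTRv only    cov -0.739865 0.152902  5
  ATTRv only pct_ds -0.040688 0.948209  5
  ATTRv only pct_ba -0.486002 0.406508  5
```

The one strong relationship is in the wild-type subset: %DS falls as total
cardiac SUV rises (r = −0.73, p = 0.002) — septal-predominant uptake is a
feature of low-burden disease that washes out as deposition becomes
diffuse.

Measure a simulated septal-predominant heart through the full chain:

```python
from pypquant import make_cardiac_phantom, PhantomSpec
from pypquant.pipeline import suv_from_phantom, cardiac_indices

mult = [2.0 if s in (2, 3, 8, 9, 14) else 1.0 for s in range(1, 18)]
spec = PhantomSpec(grid_shape=(96, 96, 96), voxel_mm=3.9, psf_fwhm_mm=0.0,
                   seed=None, count_scale=1.0, segment_multipliers=tuple(mult))
counts, truth = make_cardiac_phantom(spec)
idx = cardiac_indices(suv_from_phantom(counts, spec, 370e6, 70e3), spec)
print(f"%DS measured {idx.pct_ds:.2f} (voxel truth {truth.true_indices.pct_ds:.2f})")
```

```
%DS measured 17.28 (voxel truth 22.73)
```

The doubled septal segments produce a strongly positive difference score;
the polar-map estimate sits below the voxel-level truth because radial-
maximum sampling bleeds across sector boundaries (see `docs/methods.md`).

The same operations are available from the shell:

```bash
pypquant simulate cardiac --config spec.yaml --seed 7 --out phantom/
pypquant calibrate --phantom cyl/counts.nii.gz --labels cyl/segment_labels.nii.gz \
    --concentration 5000 --out ccf.json
pypquant suv --in phantom/counts.nii.gz --ccf ccf.json --dose-mbq 370 --weight-kg 70 --out suv.nii.gz
pypquant polarmap --suv suv.nii.gz --axis axis.yaml --out pm/
pypquant indices --polarmap pm/polarmap.npz --out indices.csv
pypquant reproduce-table4 --out table4.csv
```

## Layout

```
src/pypquant/
  phantom.py    digital phantoms + synthetic echo parameters
  suv.py        CCF estimation, SUV conversion, dose protocol helper
  voi.py        ellipsoid/cylinder VOIs, rSUV_H/Ao, H/CL, classification
  polarmap.py   reslicing, radial-max sampling, AHA-17 parcellation
  indices.py    summed regional SUVs, total cardiac SUV, COV, %DS, %BA
  stats.py      Pearson, Kruskal-Wallis, Steel-Dwass, Fisher, sens/spec
  cohort.py     packaged patient table, derived indices, correlation table
  pipeline.py   end-to-end drivers and the synthetic differentiation cohort
  cli.py        `pypquant` command-line entry point
docs/methods.md   model, conventions and numerical choices
```
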