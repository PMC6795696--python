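# habitatmap

Tumor **habitat mapping** from multi-parametric MRI of soft-tissue sarcoma.

Soft-tissue sarcomas are heterogeneous: cellular tumor, necrotic/cystic
change and fat coexist in one mass, and each compartment can respond
differently to radiotherapy while the overall tumor size barely changes.
`habitatmap` segments the tumor into tissue *habitats* from three voxel-wise
quantitative MRI parameters and quantifies how each habitat's volume and ADC
change between imaging timepoints — a compositional response readout for
radiologists and imaging scientists, where whole-tumor size is blind.

## Method

Per voxel, three parameters are computed and rescaled to the unit cube:

- apparent diffusion coefficient **ADC** (mm²/s), inversely related to
  cellularity; `adc_n = ADC / 3×10⁻³`
- fractional enhancement from pre-/post-gadolinium T1-weighted images,
  `EF = (S_post − S_pre)/(S_post + S_pre) × 100 %`; `ef_n = (EF + 100)/200`
- Dixon fat fraction `FF = S_fat/(S_fat + S_water) × 100 %`; `ff_n = FF/100`

A supervised classifier maps each `(adc_n, ef_n, ff_n)` triple to one of
five classes: **1** enhancing cellular tumor (red), **2** non-enhancing
cellular tumor (green), **3** necrotic/cystic (blue), **4** fat (yellow),
**5** novelty (gray). Class 5 is trained on feature triples sampled
uniformly over the intrinsic parameter ranges, so voxels resembling no
annotated tissue are flagged instead of mis-assigned. Gaussian naive Bayes —
`P(c|x) ∝ π_c ∏_d N(x_d; μ_cd, σ²_cd)` — is the natively implemented
reference; seven other families (LR, RBF-SVM, MLP, RF, kNN, KDE with fixed
or Silverman bandwidth) plug into the same probability contract for
comparison studies, selected by exhaustive one-ROI-per-class
cross-validation (highest median accuracy over all validation combinations).

The voxel-wise label map is then de-noised as a Markov random field:
minimize `E(l) = Σ_v −log p_v(l_v) + β Σ_{(v,u)∈N} 1[l_v ≠ l_u]` by iterated
conditional modes, slice by slice with an 8-connected in-plane neighborhood.
Finally each habitat's voxel count, volume, volume fraction and mean ADC are
summarized, compared across timepoints, and rendered as Spie charts (angle =
volume fraction, radius = mean ADC).

No patient imaging ships with the package; a phantom generator emulates
co-aligned studies with known per-class parameter distributions so every
stage is testable against ground truth.

## Worked example

`python examples/01_phantom_pipeline.py` runs the full pipeline on a seeded
phantom:

```
phantom VOI: 19896 voxels on grid (64, 64, 16), 2 mm isotropic
training set: 23 ROIs, 1454 voxels (per-class ROI counts {1: 2, 2: 2, 3: 2, 4: 2, 5: 15})
voxel accuracy vs ground truth: raw argmax 98.57 %, after MRF 99.99 % (median 2 ICM sweeps per slice)

recovered habitat composition (designed phantom in parentheses):
  class 1: fraction 0.699 (0.699), mean ADC 0.90e-3 mm^2/s
  class 2: fraction 0.222 (0.222), mean ADC 1.00e-3 mm^2/s
  class 3: fraction 0.040 (0.040), mean ADC 2.41e-3 mm^2/s
  class 4: fraction 0.039 (0.039), mean ADC 1.53e-3 mm^2/s  [ADC not interpretable: fat]
  total tumor volume: 159.2 mL
```

The MRF step removes the salt-and-pepper misclassifications of the
voxel-independent classifier (98.6 % → 99.99 % agreement with ground truth),
and the recovered volume fractions and class ADC means match the phantom's
design. `examples/02_crossval_model_selection.py` demonstrates exhaustive CV
and family comparison; `examples/03_longitudinal_response.py` recovers a
designed pre-/post-radiotherapy response (30 % enhancing→non-enhancing
conversion, +0.3×10⁻³ mm²/s ADC rise).

## Command line

For file-based studies (NIfTI volumes + ROI sidecar CSV) the same stages are
exposed as subcommands:

```sh
habitatmap simulate --seed 1 --out study/          # phantom study on disk
habitatmap run-study --config config.json          # maps -> train -> MRF -> summary
habitatmap compute-maps / crossval / train / predict / mrf-smooth /
          summarize / compare / spie-chart         # individual stages
```

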