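# Methods

This note documents the models, numerical choices and limitations behind
`habitatmap`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Feature construction

Each study contributes three co-aligned scalar volumes per voxel: ADC
(mm²/s), fractional enhancement EF (%) from the pre-/post-contrast T1 signal
ratio, and Dixon fat fraction FF (%). Grid equality (shape and spacing to
10⁻⁴ mm) is a hard precondition — the package performs no registration or
resampling, so misaligned inputs are rejected rather than silently paired.

Normalization to the unit cube uses fixed linear maps: `adc_n = ADC/3e-3`,
`ef_n = (EF+100)/200`, `ff_n = FF/100`. ADC above 3×10⁻³ mm²/s (possible in
fluid) is **clipped** to 1.0 rather than excluded: the novelty class is
trained on exactly the `[0,1]³` cube, so clipping keeps every voxel inside
the trained domain while an exclusion would silently shrink the VOI. Voxels
with a zero ratio denominator, negative raw signal, or NaN in any source map
are masked invalid and never imputed — an imputed value would be
class-informative noise.

## Tissue taxonomy and training data

Five classes: (1) enhancing cellular tumor, (2) non-enhancing cellular
tumor, (3) necrotic/cystic, (4) fat, (5) novelty. Classes 1–4 are trained
from small square ROIs (45–100 voxels, a 1–2 cm² square at typical in-plane
resolutions) placed well inside homogeneous regions; sizes outside that
range warn but do not fail. Class 5 is synthesized: 15 ROIs (sizes uniform
in [45, 100], mirroring the image-ROI range) of feature triples drawn
uniformly over the intrinsic parameter ranges and passed through the same
normalization, making each normalized component Uniform(0,1). The novelty
class converts "unlike anything annotated" from a silent failure mode into
an explicit label; the cost is a uniform density floor that can claim
in-class voxels from broad-variance tissues (see Limitations).

Patient-level hold-out: all ROIs of a held-out patient move to the test
set; a tissue class left without CV ROIs is a hard error because a
five-class model can no longer be fitted.

## Classifiers

Gaussian naive Bayes is implemented natively (not via a library): per class
and feature, sample mean and variance (ddof 0) with a variance floor of
`1e-9 × max_d Var_total(x_d)` so a constant feature cannot collapse the
density; priors are empirical class frequencies (configurable to uniform —
which the training data's ROI imbalance makes a real choice, since the 15
novelty ROIs outnumber any tissue class). Posteriors are computed in the
log domain and normalized; a brute-force density-product oracle agrees to
< 10⁻⁹, which is the gate the native implementation must pass because the
MRF stage consumes these posteriors directly.

The seven comparison families wrap scikit-learn estimators behind one
contract (per-row probabilities summing to 1): logistic regression,
RBF-SVM (Platt-calibrated probabilities, recorded in model metadata), a
fully-connected network with one 20-node hidden layer (ReLU, L-BFGS),
random forest, kNN (Euclidean), and class-conditional Gaussian KDE. Each
family carries one tunable scalar with a fixed search range (LR C 10⁻³–10¹⁰,
SVM C 10⁻³–10⁵, NN α 10⁻⁸–10⁵, RF 10–1000 trees, kNN 10–1000 neighbors,
KDE bandwidth 10⁻⁴–10); NB and automatic KDE take none. The automatic KDE
bandwidth uses Silverman's rule `h = σ̂ (4/((d+2)n))^(1/(d+4))` with σ̂ the
mean per-dimension sample SD, evaluated per class on that class's samples
(a scalar bandwidth; a per-dimension variant would be equally defensible),
floored at the 10⁻⁴ lower search bound for degenerate samples.

## Cross-validation and model selection

Validation cycles are the Cartesian product of per-class ROI lists: each
cycle holds out one ROI per class, trains on the rest, and scores the
percentage of pooled validation voxels classified correctly (voxel pooling,
not macro-averaging over ROIs). Hyperparameter grids default to 25
log-spaced points over the family's range; the value with the highest
median cycle accuracy wins, ties breaking toward the smaller value (the
smoother model). A class contributing a single ROI keeps that ROI in
training while it also validates — the only way to keep the taxonomy intact
— and every affected cycle is flagged as leaky. Family comparison uses a
two-tailed Welch t-test (the unequal-variance form, since cycle-accuracy
variances differ across families), annotated at p < 0.05 / 0.005 / 0.0005.

## MRF de-noising

Energy: `E(l) = Σ_v −log max(p_v(l_v), ε) + β Σ_{(v,u)} 1[l_v≠l_u]`, each
neighbor pair counted once; ε = 10⁻¹² keeps the log finite, β defaults
to 1.0 (unitless; 0 disables smoothing, values ≳2 visibly erode thin
structures on phantoms). Neighborhood default is 8-connected within an
axial slice — each slice is an independent MRF, matching slice-wise
radiological review — with 6-connected 3-D as an option. Inference is
iterated conditional modes in fixed raster order starting from the argmax
labels, ties toward the lowest class id. Sequential (not synchronous)
updates make every accepted move non-increasing in global energy, so the
sweep count is finite; the per-sweep changed-voxel counts form the reported
convergence trace, and a run that exhausts `max_iterations` (default 100)
surfaces `converged = false` rather than raising.

## Habitat quantification

Per class: voxel count, volume (count × voxel volume), volume fraction of
the VOI, and **mean** ADC (mean, not median, is the summarized statistic).
Voxels with invalid ADC count toward volume but not toward the mean. The
fat class's mean ADC is computed but flagged non-interpretable —
fat-suppressed DWI leaves mostly noise in fat — and the novelty class's ADC
is likewise flagged. Spie-chart geometry: angle = 360° × fraction, radius =
mean ADC normalized by the largest interpretable class mean across the
summary and its reference, so paired pre/post charts share one radial
scale; pre-treatment radii ride along as dashed reference arcs.
Longitudinal comparison reports per-class fraction and ADC deltas plus the
total VOI volume change; the radiologist's VOI (not the classified
non-novelty voxels) defines tumor volume.

## Phantom generator

The phantom emulates one co-aligned study: a 64×64×16 grid at 2 mm
isotropic (≈2×10⁴ VOI voxels — large enough for stable per-class statistics,
small enough for desk-scale runs), nested ellipsoidal compartments
(enhancing rim, non-enhancing mantle, necrotic core, fat pocket) painted in
list order so later compartments override earlier ones. Per-voxel
parameters are Gaussian draws from the compartment's class distribution,
clipped to the intrinsic ranges. Defaults (a design choice of this package,
chosen to respect the taxonomy's contrasts): class 1 ADC 0.9×10⁻³/EF 60/FF
5; class 2 ADC 1.0×10⁻³/EF 5/FF 5; class 3 ADC 2.4×10⁻³/EF 5/FF 5; class 4
ADC 1.5×10⁻³ (SD 0.6×10⁻³, deliberately broad to mimic noise-corrupted fat
DWI)/EF 0/FF 85; SDs otherwise 0.1×10⁻³ mm²/s, 8 %, 4 %. Raw Dixon and T1
signal pairs are synthesized with a fixed total signal as exact pre-images
of the target FF/EF, so the map-computation stage reproduces the designed
maps bit-for-bit. Optional Gaussian boundary blur and ground-truth label
noise provide stress conditions. Everything is deterministic given the
spec's seed.

Training ROIs are placed by 2-D erosion of each compartment with a
`(size+2)` square, guaranteeing interior, boundary-free squares — the
phantom analogue of drawing ROIs far from visible interfaces.

The longitudinal generator reuses the pre-treatment geometry and converts a
designed fraction of a source class into a target class as one contiguous
lowest-x sub-region (a responding sub-volume, not salt-and-pepper — which
slice-wise MRF smoothing would otherwise erase), with optional per-class
ADC mean shifts; the exact designed deltas are returned for recovery tests.

**What the phantom does not emulate:** MR physics (coil bias, Rician noise,
distortion), partial-volume mixing at boundaries (unless blurred),
inter-observer ROI variability, registration error between maps, and
non-Gaussian tissue heterogeneity. Passing recovery tests therefore
demonstrates correctness of the pipeline's computations under its own model
assumptions, not clinical accuracy on patient data.

## Numerical and design notes

- Probabilities are validated to sum to 1 within 10⁻⁶ after storage;
  NB posteriors are exact to ~10⁻¹⁵ of the oracle.
- Argmax ties (exactly equal posteriors) break toward the lowest class id
  everywhere — classification, ICM, and selection — so results are
  order-independent and reproducible.
- All randomness (phantoms, novelty synthesis, RF/NN fits, ROI placement)
  descends from explicit integer seeds; reruns are bit-identical.
- A +0.3×10⁻³ mm²/s ADC shift is 3 designed SDs: a classifier frozen at
  baseline will route much of the shifted tissue to the novelty class —
  intended behavior, as the tissue genuinely left the trained
  distribution. Longitudinal delta recovery is therefore validated on
  ground-truth habitat maps, and a separate check confirms that a
  within-distribution response (+0.1×10⁻³) is tracked end-to-end by the
  frozen baseline model.

## Known limitations

- The novelty class's uniform density acts as a floor: tissues with broad
  in-class variance (the phantom's fat ADC) lose a few percent of interior
  voxels to class 5 before MRF smoothing; empirical priors amplify this
  when novelty ROIs outnumber tissue ROIs.
- Classes with one ROI leak between training and validation (flagged, not
  hidden); their cycle accuracies are optimistic.
- ICM is greedy: it reaches a local, not global, energy minimum, and the
  result depends on the (fixed) sweep order.
- SVM "probabilities" are Platt-calibrated scores, monotone in the decision
  values but not calibrated posteriors; they satisfy the simplex contract
  only.
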