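# Methods

## The measurement being modelled

A pH-responsive SERS reporter on a plasmonic microarray produces Raman
spectra with two analytically useful bands: a pH-responsive band near
303 cm⁻¹ whose intensity rises with pH, and a pH-invariant
internal-reference band near 520 cm⁻¹. Their intensity ratio
`r = I(520)/I(303)` follows a line in pH over the working range
pH 2–9, `r = −0.4201·pH + 5.3972`, so a single spectrum yields a pH
estimate without absolute intensity calibration. Applied on a 3.0 mm
sampling grid over a resected gastric specimen, the per-point estimates
form a pH topographic map; because malignant mucosa secretes less acid
(ATP4B loss), tumor appears as a connected high-pH region (class
distributions used throughout: tumor 7.056 ± 0.4138, para-tumor
6.046 ± 0.8352 pH units).

## Synthetic-spectrum forward model

`SpectrumModelParams` defines, per spectrum:

* axis 200–1800 cm⁻¹ sampled at 2 cm⁻¹ (801 channels) — wide enough to
  cover both reporter bands with realistic margins;
* two Lorentzian bands, FWHM 15 cm⁻¹ (typical SERS band width), centered
  at 303 and 520 cm⁻¹;
* an additive fluorescence-like baseline, polynomial in the normalized
  axis coordinate, default `80 − 60u + 40u²` intensity units (positive,
  slowly varying);
* additive i.i.d. Gaussian noise, default σ = 5.5 intensity units.

Two calibration constraints pin the band amplitudes at a requested pH:

1. the raw (noise-free, baseline-free) intensity at the reference band's
   axis position equals `peak2_amplitude` exactly, independent of pH —
   this enforces the internal-reference property at machine precision;
2. the ratio measured by the package's own default preprocessing +
   band-height extraction equals the calibration line at the requested
   pH, solved by a secant fixed point on the responsive band's amplitude
   that runs the actual measurement path.

Constraint 2 is deliberate: targeting the *measured* ratio rather than an
idealised continuous profile means sampling-grid phase (303 cm⁻¹ falls
between the 2 cm⁻¹ channels), cross-band Lorentzian tails, smoothing
attenuation and residual baseline effects are all absorbed into the
amplitudes, so the noise-free pipeline sits exactly on the generating line
and pH round-trips are exact to ≪ 0.01 pH.

The default noise σ = 5.5 was chosen so the ratiometric pH estimate
scatters by ≈ 0.1 pH units at mid-range (pH 5.5), a scatter consistent
with a calibration R² in the high 0.99s on replicated standards.
Ground-truth pH attaches to the grid point, not to any particular noise
realisation of its spectrum.

Virtual specimens draw per-cell pH from the class-conditional normal
distributions above, truncated to [2, 9] (the calibration's validity
range), tumor cells from the tumor distribution and all others from the
para-tumor distribution. Grid size is configurable (clinically ≈ 36
points cover a 2 × 2 cm specimen at 3 mm pitch).

## Preprocessing and band-height estimation

The cleanup chain is standard Raman practice, all parameters in
`PreprocessOptions`:

1. **Despiking** — Hampel detector, window 5, threshold 6 robust SDs: a
   sample is replaced by the window median only when it is an outlier.
   (A plain median filter would flatten the sampled peak tops by an
   amount that depends on where the band center falls relative to the
   sampling grid — and differently for the two bands — corrupting the
   ratio; the conditional detector leaves smooth peaks untouched while
   still removing single-channel spikes.)
2. **Baseline** — asymmetric least squares (λ = 1e5, p = 0.001, 10
   iterations), solved with a banded Cholesky factorisation
   (pentadiagonal system; < 1 ms per spectrum).
3. **Smoothing** — Savitzky–Golay, window 9, order 3.

Band heights are estimated per band over a fixed ±10 cm⁻¹ window around
the nominal center: first a linear local background fitted through
flanking shoulders (1–3 window widths either side) is subtracted, then
the height is the vertex of a least-squares parabola over the window.
Two properties motivated this estimator over a windowed maximum:

* it is (almost) **linear in the intensities** with data-independent
  sample positions, hence unbiased under zero-mean noise. A windowed
  maximum inflates with noise through its argmax selection, and does so
  more for the weaker band, which biases the ratio and — because the
  bias varies with pH — the recovered calibration slope, by tens of
  standard errors at the default noise level;
* the local linear background cancels the small positive offset an ALS
  baseline leaves under noise (it tracks the lower noise envelope),
  which would otherwise pull both band heights up by a constant and push
  the ratio toward 1.

The parabola vertex also tolerates a few cm⁻¹ of axis miscalibration.
Heights, not areas, are used (a configuration choice; the two are
proportional for fixed band shape).

## Calibration models

`RatiometricCalibration` fits `ratio ~ pH` by OLS (statsmodels behind the
interface) and reports slope/intercept with standard errors, R² and the
calibrated pH domain. Inversion is algebraic,
`pH = (ratio − intercept)/slope`; predictions outside the calibrated
domain are flagged, never clamped — clamping is purely a rendering
concern. The orientation (ratio as a function of pH, inverted at
prediction time) is fixed by the sensor physics: it is the orientation
that reproduces the endpoint ratios ≈ 4.5 at pH 2 and ≈ 1.7 at pH 9.

`QuadraticInversion` is the conventional nonlinear comparator:
`pH = a·r² + b·r + c` by least squares. It nests every linear
ratio-to-pH predictor, so its in-sample SSE never exceeds the inverted
line's — the relevant property for a fair baseline.

## 2-D encodings

Each (preprocessed) spectrum is linearly resampled to L points and imaged
as three L × L channels, stacked in the order RP, GASF, GADF:

* **RP** (recurrence plot): unthresholded, globally normalised similarity
  `R_ij = 1 − |x_i − x_j| / max|x_a − x_b|` — symmetric, unit diagonal,
  entries in [0, 1]. The parameter-free form was chosen over the
  classical ε-thresholded recurrence plot: no free threshold, no
  embedding (dimension 1, delay 1).
* **GASF/GADF**: with `x̃` affinely rescaled to [−1, 1] and
  `φ = arccos(x̃)`, `G_ij = cos(φ_i + φ_j)` (symmetric, diagonal
  `2x̃² − 1`) and `D_ij = sin(φ_i − φ_j)` (antisymmetric, zero diagonal).
  Inputs within 1e-9 of ±1 are clamped; anything further out is an error.

Degenerate constant sequences have defined fallbacks (zeros after
rescaling; all-ones RP) with a flag set. All three channels are invariant
to positive affine transforms of the intensities, so detector gain/offset
cannot leak into the image. Channel-stacking (not tiling) was chosen so
the three fields stay spatially registered for the convolutional
backbone. Encodings use the full spectrum; a region of interest around
the reporter bands is a possible configuration refinement, not the
default.

## The multimodal network

Architecture (`PHNetConfig` defaults in parentheses):

* **1-D branch**: the preprocessed spectrum resampled to `seq_len` (256)
  and standardised per channel on the training split, through two fully
  connected layers → `d_1d` (64) features.
* **2-D branch**: the 3-channel encoding at `image_side` (64), through a
  residual convolutional backbone — stem stride-2 conv then four
  channel-preserving residual blocks interleaved with stride-2
  downsampling convs, widths (8, 16, 32, 32) — ending in a 4 × 4 token
  grid (16 tokens × 32 channels).
* **Co-attention fusion**: the 1-D features are projected to queries; the
  2-D tokens to keys and values (`d_attn` 64, 1 head by default;
  multi-head supported). Softmax attention weights (nonnegative, summing
  to 1 per head) pool the tokens into a context vector, which is
  concatenated with the 1-D features.
* **Head**: two fully connected layers → scalar pH (trained on
  standardised targets, de-standardised at prediction).

The backbone is residual in the spirit of an 18-layer residual network
with its classification layer removed, but deliberately small, sized so a
2,000-spectrum experiment trains in a few minutes on one CPU core. No
pretrained weights are used — everything trains from random (He)
initialisation, fully seeded. The network and its gradients run on a
compact reverse-mode autodiff core over numpy (`acidmap.nn`): im2col
convolutions, softmax, broadcasting arithmetic; gradients are verified
against finite differences in the test suite.

Training protocol: MSE loss, Adam (lr 1e-3, decoupled weight decay 1e-3
on weight matrices), batch 32, up to 100 epochs (30 in the shipped
experiments), early stopping on internal-validation loss with patience
10 (8 in the shipped experiments), best-epoch weights restored. During
training, fresh Gaussian noise (SD 0.3 in standardised units) is added to
the 1-D sequences each time a batch is visited: the physical measurement
noise is i.i.d. per acquisition, so resampling it per visit prevents the
network from memorising the specific noise realisation of each training
spectrum — without it, held-out R² drops by several points from pure
noise memorisation.
**Splitting is by specimen, never by point** — 60/20/20 train /
internal-validation / external-validation fractions of specimens — so no
specimen contributes to more than one partition (leakage guard tested).
All randomness (initialisation, splits, batch order) derives from one
seed recorded in the model artifact; weights persist as individual
`.npy` files so a rerun reproduces the artifact byte for byte.

On the synthetic task (2,000 spectra, 50 virtual specimens, default
noise) the network recovers pH with held-out external-split R² ≈ 0.98,
approaching the ratiometric oracle's ≈ 0.99 even though the network must
rediscover the ratio structure from raw channels while the oracle is
told where the bands are. Its predictions are strictly monotone in true
pH on a noise-free ladder (Spearman ρ = 1.0).

## Maps and diagnostics

Grid convention: 0-based (row, col), x right / y down, point position
(col·pitch, row·pitch). `build_map` validates completeness (duplicates
and missing cells are errors naming the cells). `classify_map` marks a
cell tumor-suspect iff **pH ≥ threshold** — tumor mucosa is the less
acidic class — and groups suspect cells into 4-connected regions
(8-connectivity optional) with areas in mm². Ties at the threshold are
suspect, consistent with the ROC convention below. No spatial smoothing
is applied to stored values; rendering shades each raw cell (green family
at/above threshold, red below) and is byte-deterministic for fixed
inputs. Published cutoffs are available as presets: 6.735 (animal model),
6.855 (clinical, classical pipeline), 6.845 (clinical, AI pipeline).

ROC analysis calls a point positive when its score (pH) is ≥ the
threshold, sweeping all distinct scores plus a +∞ sentinel; the trapezoid
AUC then equals the Mann–Whitney probability estimate exactly (ties
counted half), which the tests assert to 1e-10. The Youden-optimal
threshold maximises TPR − FPR with ties broken toward higher specificity,
then lower threshold; the returned cutoff is the midpoint of the empty
score gap below the optimal candidate (for separated classes: the
midpoint between the class extremes), which classifies identically to the
candidate. Confusion-matrix metrics come with exact Clopper–Pearson 95%
CIs; metrics with zero denominators are reported absent rather than NaN.
Cohen's κ is the unweighted binary form. R²/SSE for regression
comparisons use `SSE = Σ(pred − ref)²`, `R² = 1 − SSE/SST`.

A note on magnitudes: with the published class distributions taken as
normal, the closed-form binormal AUC is
Φ(1.010/√(0.4138² + 0.8352²)) ≈ 0.861. Observed clinical AUCs on real
specimens are higher (≈ 0.94) because the real pH distributions are not
normal; the simulator reproduces the published moments, not the full
shapes, so 0.861 is the correct expectation for the synthetic experiment
and is what the tests check.

Similarly, thresholding a simulated 6×6 specimen with a 2×2 tumor block
at 6.845 recovers ≥ 3 of the 4 tumor cells in only ≈ 63% of runs — the
per-cell suspect probability under the tumor distribution is
Φ((7.056 − 6.845)/0.4138) ≈ 0.695, giving a binomial P(≥ 3 of 4) ≈ 0.64.
High per-specimen recovery at that cutoff would require either a lower
threshold (≈ 6.6 pushes it above 95%) or spatial pooling across
neighbouring cells; the package reports the honest per-cell figure.

## What the synthetic experiments do and do not show

The generator reproduces: the calibration line and its noise scatter, the
internal-reference invariance, the class-conditional pH moments, and the
grid geometry. It does **not** reproduce: non-normal tails of real pH
distributions (hence lower AUC, above), instrument drift, spatial
correlation of pH within a specimen beyond the tumor/para-tumor split,
variable droplet contact, or patient-level covariate structure. Passing
tests therefore demonstrate correctness of the algorithms and parameter
recovery under the stated statistical model — not clinical performance.
The published clinical figures that depend on patient spectra (external
R² 0.79, SSE 71.83, AUC 0.9367/0.9513) are used only as reconstruction
inputs (confusion-matrix arithmetic) or as documented contrasts, never as
targets for the synthetic experiments.

## Numerical choices

* float64 everywhere except the network (float32).
* ALS solved by `scipy.linalg.solveh_banded`; weights iterated to a fixed
  point or 10 iterations.
* Secant amplitude calibration stops at |measured − target| ≤ 1e-10·target
  or 20 iterations (typically 3).
* arccos inputs clamped within 1e-9 of [−1, 1]; further out is an error.
* Degenerate inputs: constant sequences (encoders), all-zero spectra
  (preprocessing), single-class label sets (ROC, an error), zero-variance
  references (R² absent) all have defined, tested behaviour.
* Seeds: one master seed fans out to pipeline stages by fixed offsets;
  every stochastic default in tests and the acceptance script is seeded.
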