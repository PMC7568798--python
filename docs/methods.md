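# Methods

## The scattering representation

Each 250-sample heartbeat `f` (360 Hz, R-peak at index 99) is mapped to a
75 × 8 matrix of nonnegative coefficients by a two-order wavelet scattering
cascade. Order 0 is the Gaussian-low-passed signal `|f ⋆ φ|`; order 1
low-passes the modulus of each band-pass channel, `||f ⋆ ψ_{j1}| ⋆ φ|`; order
2 repeats the modulus/band-pass step once more before averaging. The modulus
demodulates each band to low frequency, so the final averaging loses little
information while conferring invariance to translations up to the support of
φ and Lipschitz stability to small time-warps — exactly the nuisances
(R-peak annotation jitter, heart-rate-dependent morphology stretch) that
plague template-based beat features. Orders above 2 are omitted: the modulus
contracts energy so quickly that the first two orders retain ~99% of it.

## Filter-bank construction

The wavelets are analytic Gabor (Morlet) filters, built directly in the
frequency domain on the padded FFT grid: a Gaussian bump centered at +ξ
minus a DC-matched correction Gaussian so that `ψ̂(0) = 0` exactly. The
low-pass φ is a Gaussian whose ±3σ time support equals the invariance scale
T = 0.5 s (σ_t = T·fs/6 = 30 samples).

Per layer with quality factor Q, center frequencies descend geometrically
from 0.35 cycles/sample in steps of 2^(−1/Q); the relative bandwidth
α(Q) = (1 − 2^(−1/Q)) / (2√ln2) makes adjacent filters cross at half power.
When the wavelet bandwidth α·ξ would fall below the low-pass bandwidth
σ_φ, spacing switches to linear with constant bandwidth σ_φ, stepping by
one σ_φ down to a floor of 1.5 σ_φ. Second-order paths (j1, j2) are kept
only when the center of ψ_{j2} lies below the FWHM (2√(2 ln 2) σ) of
ψ_{j1} — below that bandwidth `|f ⋆ ψ_{j1}|` carries energy, above it the
path is numerically negligible. These constants (0.35, ±3σ support, unit
step, 1.5 σ floor, FWHM rule) are the package's fixed design; under the
default configuration they give 33 order-1 wavelets, 6 order-2 wavelets and
41 frequency-decreasing order-2 paths: 1 + 33 + 41 = 75 paths.

Each layer is rescaled by one common factor chosen so the Littlewood–Paley
function |φ̂|² + Σ(|ψ̂(ω)|² + |ψ̂(−ω)|²)/2 has supremum exactly 1 — this
makes every wavelet-modulus stage nonexpansive, hence the whole transform
(‖Sf − Sg‖ ≤ ‖f − g‖, asserted in tests). The measured infimum over the
covered band is ≈ 0.53 for layer 1 and ≈ 0.50 for layer 2 (dips between the
linearly spaced filters); tests assert a 0.45 floor.

Numerics: signals are reflection-padded from 250 to 512 samples; all
convolutions are FFT products at full resolution; only the final averaged
output is subsampled, at hop = 2^⌊log₂(1/(2·FWHM_φ))⌋ = 32 samples — the
largest power-of-two hop not exceeding the low-pass Nyquist rate — giving
⌈250/32⌉ = 8 time windows at sample positions 0, 32, …, 224. An
`oversampling` flag halves the hop per unit for denser grids. No logarithm
or renormalization is applied to the coefficients.

## Dataset handling

Beat symbols map onto the five AAMI superclasses through one editable table
accepting both single-character WFDB codes and spelled-out beat-type names;
class Q is dropped at segmentation. Segmentation windows are [r−99, r+150]
inclusive and beats whose window crosses a record boundary are dropped.
R-peak positions come from the reference annotations — beat detection is a
solved, separate problem and re-implementing a detector would only add a
confound. The four canonical pacemaker records (102, 104, 107, 217) are
refused by default; the list is configurable.

Balancing targets 90 000 beats per class: majority classes are subsampled
without replacement (kept beats retain input order, no noise), minority
classes keep all originals and append copies of uniformly resampled
originals plus i.i.d. N(0, 0.05) noise per sample — the variance is in
squared signal units (mV²) on the raw beat, since no normalization or
denoising is applied anywhere. Balancing precedes fold splitting by
default, so noisy copies of one source beat can land in different folds;
this mirrors the augment-then-split protocol but is an optimistic bias on
real data. Two strict, off-by-default variants avoid it: a source-grouped
fold split that keeps all copies of one (record, R-index) in the same
fold, and fold-local balancing (`augment_train_to`) that defers
augmentation to inside each training fold. The pure arithmetic of the
policy lives in `plan_balance` so the bookkeeping is testable without
materialising arrays.

## Reduction and classifiers

Window indexing is 0-based everywhere; "the 4th time window" of the
published tables is `window:3`. The per-path PC1 reducer treats the 8
windows of each path as variables and beats as observations, centers by the
fitting-set mean, and projects onto the leading covariance eigenvector (no
standardization — covariance, not correlation), with the sign fixed so the
largest-magnitude loading is positive. By default the component is fitted
on the training fold only; a fit-on-all mode reproduces the looser
protocol. Zero-variance paths score 0 with a warning. Contribution rates
are per-path eigenvalue fractions, averaged as plain fractions when
summarized.

KNN uses Euclidean distance, k = 4; a tied vote is broken by the class of
the single nearest neighbour among the tied classes (deterministic, and the
natural limit of the vote as k shrinks). The PNN scores each class by the
*mean* Gaussian kernel value over that class's pattern units — mean and sum
coincide up to the class prior once training classes are balanced — with
spread σ = 0.01 applied on the raw coefficient scale; when every kernel
value underflows the classifier falls back to the nearest pattern unit
(the σ → 0 limit) and warns. The feedforward net is 75-70-60-45-30-20-10-4
with ReLU on all six hidden layers (the published description activates
five and leaves the sixth unstated; uniform ReLU is used, configurable),
softmax output, categorical cross-entropy, Adam (lr 10⁻³, β₁ 0.9,
β₂ 0.999, ε 10⁻⁸), minibatch 256, 50 epochs; batch size and learning rate
were unstated and the defaults here are the common choices, exposed as
flags. It is backed by scikit-learn's `MLPClassifier`, which implements
exactly this loss/architecture family; the parameter count of the default
architecture is 14 579.

## Evaluation protocol

10-fold cross-validation with stratified, seed-shuffled folds (the balanced
classes make plain and stratified splits nearly identical, but
stratification plus a seed gives determinism). Multi-window feature rows of
a test beat are merged by majority vote; ties fall back to the largest
summed confidence (class posterior for PNN/NN, negative mean neighbor
distance for KNN), then to AAMI class order. Confusion counts accumulate
across folds so row sums equal class sizes exactly. Metrics are one-vs-rest
PPV/SEN/SPEC per class and a binary collapse with N negative and {S, V, F}
pooled positive; undefined ratios (zero denominators) are reported as NaN,
never as 0. Printed tables round to one decimal.

## Synthetic study set

The generator emulates only what the pipeline needs: 250-sample beats with
the R component at index 99 and four morphologically distinct classes, each
a sum of Gaussian bumps for the P/Q/R/S/T waves with per-beat jitter on
amplitude (±5% relative), width (±5%) and position (σ = 1 sample) plus
baseline noise (variance 4·10⁻⁴ mV²). N is a full P-QRS-T complex; S
shrinks and advances the P wave; V widens the QRS, removes P and inverts T;
F is the N and V component sets at half amplitude. Template cross-
correlations are pinned in tests (N–V ≈ 0.22, N–S ≈ 0.98 — S is
deliberately the hard class). The default study set is 200 beats per class,
a size at which the full 10-fold scattering+KNN pipeline runs in seconds.

What passing on this set shows: the geometry of the transform, the
index arithmetic of the reducers, the classifier contracts and the
bookkeeping of cross-validated evaluation. What it does not show:
performance on real ECG — the templates lack rhythm context, inter-patient
variability, baseline wander, electrode artefacts and the extreme class
imbalance of clinical data, so the near-perfect synthetic accuracies are a
wiring check, not a clinical claim.

## Known limitations

- Evaluation is patient-independent (beats pooled across records);
  inter-patient train/test division is out of scope.
- Augment-before-split leakage in the default protocol, as discussed
  above; the strict variants must be opted into.
- The WFDB reader covers signal formats 212 and 16 and MIT annotations
  only, and assumes all signals share one `.dat` file (the MIT-BIH layout).
- PNN inference is O(n_train · n_query) in memory-chunked exact form; it is
  meant for single-window features, not the 8-window expansion.
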