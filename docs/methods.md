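# Methods

## Problem and pipeline

EOTRH (Equine Odontoclastic Tooth Resorption and Hypercementosis) is graded
0–3 from radiographic signs on the incisor teeth. Radiographically, the
disease overlays the bright tooth silhouette with an alternating mosaic of
dark resorptive lucencies and bright hypercementotic deposits, so disease
severity manifests as increasing *texture irregularity* inside a tooth ROI.
The pipeline quantifies that irregularity: each rectangular tooth ROI is
filtered (Normalize, Median, Laplacian sharpening), five two-dimensional
entropy measures and six GLCM features are extracted per filtered ROI
(5×3 = 15 and 6×3 = 18 values per tooth), the measures are compared across
grade groups, and grade 0 vs grade 3 detection is scored by thresholding.

## Entropy measures

All five operate on the real-valued ROI matrix directly.

**SampEn2D.** Square windows of side `m` and `m+1` are taken at the common
grid of positions where both fit. `A` (resp. `B`) counts ordered pairs
(i ≠ j) of `m`- (resp. `(m+1)`-) windows whose Chebyshev distance is at most
`r = r_coeff · SD(image)` (population SD). The value is `−ln(B/A)`. When
`A = 0` or `B = 0` the statistic is undefined; this is reported as a typed
undefined marker (serialized `NA`), never as a silent NaN, and such rows are
excluded from downstream group statistics. A constant image gives `r = 0`
with all distances zero, hence value 0.

**FuzzEn2D.** Same geometry, but windows are mean-subtracted and matching is
graded by the fuzzy similarity `μ = exp(−d^n / r)`; `φ_m` is the mean
similarity over ordered pairs and the value is `−ln(φ_{m+1}/φ_m)`. Because
`d^n` scales as `a^n` while `r` scales as `a` under `img → a·img`, FuzzEn2D
is scale invariant only for `n = 1`; with the default `n = 2` it is shift-
but not scale-invariant. This follows the canonical fuzzy-entropy
similarity; making it scale-free would change the statistic. A numerical
point worth recording: the ordered-pair similarity sum is accumulated with
self-pairs excluded *before* summation — subtracting the `n` self-terms
afterwards catastrophically cancels when all off-diagonal similarities are
tiny.

**PermEn2D.** Each `dm×dn` window is flattened row-major and mapped to the
permutation that sorts it ascending, ties broken by position (stable
argsort). The value is the Shannon entropy of the pattern frequencies.
Optional normalization divides by `ln((dm·dn)!)` — the log of the number of
possible ordinal patterns of a `dm·dn` vector, so the normalized value
cannot exceed 1 (a `dm!·dn!` denominator would not bound it).

**DispEn2D.** Pixels are standardized by the image's own mean/SD, pushed
through the standard normal CDF to `v ∈ (0,1)`, and quantized to classes
`z = round(c·v + 0.5)` clipped to `[1, c]` (round-half-even; the boundary
case has measure zero for continuous data). The value is the Shannon
entropy of the `dm×dn` class-pattern frequencies; optional normalization by
`ln(c^{dm·dn})`. A constant image (SD = 0) yields a single class and value
0 with a degenerate-input warning.

**DistEn2D.** All `m×m` windows are compared pairwise (unordered pairs,
i < j) by Chebyshev distance; the distances are binned into `M` equal-width
bins spanning `[0, max distance]` and the value is the Shannon entropy (in
bits) of that empirical distribution, divided by `log2 M` when the default
normalization is on, so it lies in `[0, 1]`. A constant image has all
distances zero and value 0.

An opt-in flag reproduces a window-count-reciprocal prefactor
`1/((rows−dm+1)(cols−dn+1))` on PermEn2D/DispEn2D. It is off by default:
the prefactor makes values depend on image size, which contradicts the
originating definitions of both measures, and the conventional Shannon form
is what the downstream grade statistics assume.

### Default parameters

`m = 2`, `r_coeff = 0.2`, fuzzy exponent `n = 2`, `dm = dn = 2`, `c = 6`,
`M = 512`, natural log for Samp/Fuzz/Perm/Disp, log2 with normalization for
DistEn2D. These are the canonical defaults of the originating method
family; every one is overridable through `EntropyParams` / the run config.

### Pixel budget

Pairwise window comparison is quadratic in window count. Inputs larger than
a configurable budget (default 64×64) are block-downsampled by local mean
with the smallest integer factor that fits, trailing part-blocks dropped;
the factor is recorded on each result (`note` field) for provenance. The
default 96×160 phantom is reduced by factor 3 to 32×53, giving ~1.3 M
window pairs per measure — a deliberate, deterministic accuracy/cost
trade-off rather than random subsampling.

## Filters

*Normalize* rescales to zero mean and unit **population** variance ("unit
variance of the pixel set"); a constant image maps to zeros with a warning.
*Median* uses a `(2r+1)²` neighborhood, default radius 1 (the smallest
standard neighborhood; the radius is not pinned down by the reporting
convention we follow, so it is configurable). *Laplacian sharpening* is
`out = in − w·∇²in` with the 4-neighbor kernel `[[0,1,0],[1,−4,1],[0,1,0]]`
and default weight 1, the canonical unsharp-by-Laplacian form. All
neighborhood operations replicate edges so no artificial zeros leak into
ROI borders, and filtering is applied to the cropped ROI (whole-image
filtering would differ only in a border band of the ROI).

Note that because all five entropies are shift invariant and all but
FuzzEn2D scale invariant, the Normalize filter changes entropy values
little; it matters for the GLCM baseline and mirrors the reference
protocol.

## GLCM baseline

The ROI is min–max quantized to `n_levels` (default 32) equal-width levels
1..L; co-occurring level pairs are counted at offset distance 1 in the four
standard directions (0°, 45°, 90°, 135°), symmetrized, normalized, and the
six features are computed per direction and averaged (feature averaging;
matrix averaging is available). Feature definitions, with `p(i,j)` the
normalized matrix and `p_{x−y}(k)` its absolute-difference marginal:
contrast `Σ(i−j)²p`, cluster prominence `Σ(i+j−μ_x−μ_y)⁴p`, difference
average `Σ k·p_{x−y}`, difference entropy `−Σ p_{x−y} log2 p_{x−y}`,
difference variance `Σ(k−DA)² p_{x−y}`, inverse variance
`Σ_{i≠j} p/(i−j)²`. The counting is cross-checked in the tests against
`skimage.feature.graycomatrix` and a naive double-loop reference.

## Phantom generator

The generator emulates the statistical structure the analysis assumes, not
tooth anatomy. One phantom is: background (60/255) + superellipse tooth
mask (exponent 4, long axis vertical, base intensity 180/255) + `n_dark`
Gaussian-profile lucencies (amplitude −0.45 × base, σ = radius/2, radius
uniform in 3–10 px) at uniform in-mask positions + `n_bright` bright blobs
(+0.45 × base) restricted to the apical third (hypercementosis concentrates
at the apex) + Gaussian noise, clipped to 8-bit. Grade scaling:
dark counts 0/2/5/9, bright counts 0/1/3/6, noise SD 4/6/8/12 gray levels
for grades 0–3. Lesion contrast has no published calibration target, so
±0.45 was fixed once as a visually plausible, clearly separable synthetic
convention and documented as such.

Cohort generation mirrors the clinical group sizes 37/94/20/8 (159 teeth;
consecutive phantoms are paired into horses as teeth 101/201) and writes
8-bit PNGs plus a manifest CSV; everything is deterministic in the base
seed, with per-image seeds recorded.

What passing phantom-based tests shows: the pipeline detects monotone
increases in mosaic-like irregularity at realistic group sizes. What it
does not show: performance on real radiographs, where projection overlap,
exposure variation, anatomical texture (pulp cavity, periodontal space) and
annotation variability are absent from the phantom.

## Grade statistics

Groups are the per-grade value lists of one (filter, measure) combination,
each tooth one realization. Each group is Shapiro–Wilk tested; the
parametric branch (one-way ANOVA + Tukey HSD) is taken only when **all**
groups pass at α = 0.05, otherwise Kruskal–Wallis + Dunn's test with
Bonferroni adjustment over all pairs (Dunn's z uses mean ranks with the
standard tie correction; no pre-installed package provides it, so it is
implemented here and exercised against its closed-form small cases).
Letters are assigned by insert-and-absorb compact letter display; two
groups share a letter iff their adjusted pairwise p ≥ α (property-tested on
random p maps).

The monotone-increase flag operationalizes "significantly increases with
grade": no *significant decrease* between consecutive grades, and a
significant lowest-vs-highest difference with the higher grade larger. The
strict alternative (sample means non-decreasing) was rejected because a
non-significant dip between grades with equal population means would
extinguish the flag on roughly half of random replicates, which is not what
the flag is meant to capture; under the null the flag still fires at most
at the pairwise α rate (simulation-tested).

Regression similarity between an entropy measure and each GLCM feature
follows the sequential logic: per-series OLS of value on numeric grade
(0–3, per-ROI points); slope equality tested via the grade-by-series
interaction in the pooled model; on non-significance (p > α) the model is
refit with a common slope and the intercepts compared; on further
non-significance a common intercept is reported. Perfect-fit degeneracies
(zero residual variance, e.g. noiseless construction or duplicated series)
make the usual t-statistics 0/0; they are resolved by convention —
coefficient materially zero → p = 1, otherwise p = 0 — which reproduces the
closed-form expectations.

## Detection

Grade 3 is the positive class, called when the measured value is strictly
**above** the threshold (ties negative). The threshold is the mean,
mean + SD, or mean + 2SD (sample SD) of a reference population, by default
the pooled grade-0 ∪ grade-3 values (the reference is configurable:
grade0-only and all-grades are supported, as is the reversed direction).
The above-positive direction is the one consistent with the reported
monotone behaviour of the accuracy metrics (sensitivity falls as the
threshold rises) for a grade-increasing measure; the opposite reading would
invert that trend. Se/Sp/PPV/NPV are kept at full precision internally and
reported rounded half-up to two decimals; a ratio with an empty denominator
(e.g. PPV when nothing is called positive) is undefined and rendered `-`.

## Problem sizes used in the checked runs

Oracle equivalence uses random matrices up to 6×6 over three gray values,
where exhaustive pure-Python enumeration is exact and fast. The end-to-end
grade-monotonicity check uses the full 37/94/20/8 cohort for the
significance test plus 30 phantoms per grade for the replicated means, at
the default 64×64 pixel budget. These sizes were chosen as the smallest
that exercise every code path at the cohort structure the package targets.

## Known limitations

- No DICOM input; PNG/JPEG only, single-channel after fixed-weight
  luminance collapse.
- Two teeth per horse are treated as independent realizations (each ROI
  considered separately); no mixed-effects modelling.
- FuzzEn2D with the default exponent is not scale invariant (see above).
- SampEn2D is frequently undefined on small, high-entropy ROIs (no window
  matches); this is inherent to the statistic, and the pipeline propagates
  it as `NA` rather than imputing.
- The phantom's lesion contrast and counts are synthetic conventions, not
  calibrated to clinical image statistics.
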