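# eotrh-texture

Texture analysis of equine incisor radiographs for grading Equine
Odontoclastic Tooth Resorption and Hypercementosis (EOTRH), a degenerative
dental syndrome of older horses scored radiographically from 0 (normal) to 3
(severe). Resorption appears as low-radiopacity lucencies and
hypercementosis as high-radiopacity bulbous deposits; their alternating
mosaic makes diseased teeth *texturally irregular*, which is what this
package quantifies.

The package is aimed at veterinary imaging researchers who want a tested,
scriptable implementation of the full analysis chain:

1. **ROI handling** — load PNG/JPEG radiographs, parse a CSV manifest of
   rectangular tooth ROIs tagged with horse ID, Triadan tooth number
   (101/201) and EOTRH grade.
2. **Filtering** — Normalize (zero mean, unit variance), Median
   (rank filter), Laplacian sharpening.
3. **Five two-dimensional entropies** per filtered ROI:
   - `SampEn2D = −ln(B/A)`, with `A`/`B` the counts of ordered window pairs
     within Chebyshev tolerance `r = 0.2·SD` at sizes `m` and `m+1`;
   - `FuzzEn2D = −ln(φ_{m+1}/φ_m)` with graded similarity
     `μ = exp(−d^n / r)` on mean-subtracted windows;
   - `PermEn2D = −Σ p(π) ln p(π)` over ordinal patterns of `dm×dn` windows;
   - `DispEn2D = −Σ p(π_v) ln p(π_v)` over normal-CDF class patterns
     (`c` classes);
   - `DistEn2D = −Σ p_t log2 p_t` over the `M`-bin histogram (ePDF) of all
     pairwise inter-window distances, normalized by `log2 M`.
4. **Six GLCM features** as the comparison baseline: Cluster Prominence,
   Contrast, Difference Average, Difference Entropy, Difference Variance,
   Inverse Variance.
5. **Grade statistics** — Shapiro–Wilk-gated ANOVA+Tukey or
   Kruskal–Wallis+Dunn, compact letter display, and slope/intercept
   similarity testing between measures by sequential linear regression.
6. **Detection** — EOTRH 0 vs 3 threshold classification (mean, mean+SD,
   mean+2SD of a reference population) with Se/Sp/PPV/NPV reporting.

Because clinical radiographs are not distributable, the package ships a
first-class **phantom generator**: synthetic graded tooth ROIs with a bright
superellipse tooth on a dark background, grade-scaled dark/bright
Gaussian-profile lesions (bright ones concentrated apically) and
grade-scaled noise. The generator's defaults mirror the clinical cohort
structure (37/94/20/8 teeth for grades 0–3, 159 in total).

## Worked example

```python
import numpy as np
from eotrh_texture import (PhantomSpec, generate_phantom, filter_normalize,
                           EntropyParams, entropy_suite)

roi = generate_phantom(PhantomSpec(grade=3, seed=1))      # severe disease
filtered = filter_normalize(roi.pixels.astype(float))
for res in entropy_suite(filtered, EntropyParams()):
    print(f"{res.measure:9s} {res.value:.4f}")
```

prints

```
SampEn2D  0.7240
FuzzEn2D  0.5639
PermEn2D  3.1467
DispEn2D  2.6213
DistEn2D  0.8573
```

— the five irregularity measures of one severe-grade phantom after
Normalize filtering (a grade-0 phantom under the same seed scores
DistEn2D ≈ 0.69; the distance-distribution entropy rises with lesion load,
which is exactly the grade-separating behaviour the analysis relies on).

Detection from a small two-group cohort:

```python
from eotrh_texture import RunConfig, run_extract, run_detect

cfg = RunConfig(group_sizes={0: 10, 3: 8}, seed=1,
                entropy_measures=("DistEn2D",), glcm_enabled=False)
table = run_extract(cfg)          # long feature table (ROI × filter × measure)
print(run_detect(table, cfg))     # Se/Sp/PPV/NPV at the three thresholds
```

At the pooled-mean threshold these well-separated synthetic groups classify
perfectly (Se = Sp = 1.00); at mean+2SD no tooth exceeds the threshold, so
Se = 0.00 and PPV is undefined (rendered `-`).

The same pipeline is available from the shell:

```bash
eotrh-texture phantom --out cohort/ --seed 1 --sizes 37,94,20,8
eotrh-texture extract --manifest cohort/manifest.csv --out features.csv
eotrh-texture stats   --features features.csv --out reports/
eotrh-texture detect  --features features.csv --measure DistEn2D --out detection.csv
```

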