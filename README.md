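# fibroquant

Quantifies fibrotic content in muscle from 2-D grey-scale images — the kind
of question that arises when asking whether obesity remodels the calf and
plantar muscles that load the ankle joint. Fibrous tissue appears bright
against darker muscle; the package segments the two tissues, measures the
fibrous-to-muscle pixel ratio per subject (averaged bilaterally), extracts
second-order texture features, and compares four cohorts (lean/obese ×
youth/aged) with a one-way ANOVA. Because patient MRI data for such studies
are rarely shared, a synthetic phantom generator plants known ratios so every
stage of the pipeline is testable end to end.

## Method

**Segmentation.** Edge strength is computed with the Sobel operator
E = [1, 0, −1; 2, 0, −2; 1, 0, −1] and its transpose
(|∇f| = √(Gx² + Gy²), reflect padding). Grey levels are min–max quantized to
G levels (default 64) over the ROI, and every horizontally/vertically
adjacent pixel pair is accumulated into an *edge co-occurrence matrix* with
weight 1 + s̄, where s̄ is the pair's mean edge strength normalized to [0, 1]
— transition zones between tissues are emphasized. The matrix's leading
diagonal concentrates within-tissue grey levels: its two dominant,
valley-separated modes define the muscle (darker) and fibrous (brighter)
classes, and labelling every grey level by its side of the inter-peak valley
turns the matrix into a look-up table (LUT) applied pixel-wise to the ROI.
The fibrous-to-muscle ratio is the fibrous/muscle pixel-count quotient.

**Texture.** The grey-level co-occurrence matrix P(i, j | Δx, Δy) = W·Q is
accumulated at distance d = 1 for θ ∈ {0°, 45°, 90°, 135°} and three
features are averaged over orientation:

- correlation: Σᵢⱼ (i − μx)(j − μy) P(i, j) / (σx σy)
- entropy: −Σᵢⱼ P(i, j) log₂ P(i, j)  (bits)
- angular second moment: Σᵢⱼ P(i, j)²

where Px(i) = Σⱼ P(i, j), Py(j) = Σᵢ P(i, j) and μx, μy, σx, σy are their
means and standard deviations.

**Cohort statistics.** Group summaries are mean ± SEM; the four-group
comparison is a one-way ANOVA with explicit bookkeeping:
MS_between = Σ nᵢ(ȳᵢ − ȳ)²/(k − 1), MS_within = Σᵢⱼ(yᵢⱼ − ȳᵢ)²/(N − k),
F = MS_between/MS_within. Because published ANOVA lines often omit the
per-group n, `reconcile_sample_size` brute-forces the balanced n that
reproduces a printed between-groups mean square from printed group means.

**Phantoms.** Fibrous regions are thresholded low-pass Gaussian noise
("blobs") planted inside a rectangular ROI so the pixel-count ratio matches
the target exactly up to one boundary-pixel quantum, with additive Gaussian
grey noise. Cohorts draw per-subject ratios from Normal(mean, SEM·√n)
truncated at zero; the shipped configuration
(`fibroquant/data/default_cohort.json`) carries group means ± SEM for three
muscle compartments and n = 24 per group.

## Worked example

```python
import numpy as np
from fibroquant import (PhantomSpec, generate_phantom, segment_image,
                        fibrous_muscle_ratio, texture_profile)

spec = PhantomSpec(target_ratio=0.23)          # 128x128, noise sd 5
out = generate_phantom(spec, seed=42)
mask, ecm = segment_image(out.image, roi=spec.roi_mask(), levels=64)
print(f"planted ratio   : {out.true_ratio:.4f}")
print(f"recovered ratio : {fibrous_muscle_ratio(mask):.4f}")
print(f"diagonal peaks  : {ecm.diagonal_peaks}")
feats = texture_profile(out.image, roi=spec.roi_mask(), levels=64)
print(f"correlation={feats.correlation:.4f} "
      f"entropy={feats.entropy:.4f} bits asm={feats.asm:.6f}")
```

prints

```
planted ratio   : 0.2300
recovered ratio : 0.2300
diagonal peaks  : (9, 56)
correlation=0.8269 entropy=7.4814 bits asm=0.009220
```

The planted fibrous-to-muscle ratio (23 fibrous pixels per 100 muscle
pixels) is recovered exactly; the LUT's two diagonal peaks sit at the
quantized muscle and fibrous grey modes. The positive correlation reflects
spatially coherent tissue blobs, and the entropy/ASM quantify how dispersed
the co-occurrence distribution is.

The same stages are available from the shell:

```sh
fibroquant run --seed 1 --out-dir run1            # full default cohort
fibroquant report --manifest run1/manifest.json   # bar histograms + summary
fibroquant segment --image slice.tif --roi roi.png --levels 64 \
    --out-mask mask.png --out-csv ratios.csv
fibroquant anova --in run1/cohort.csv --by compartment --value-col ratio
```

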