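# Methods

## Scope and model

fibroquant treats muscle fibrosis quantification as a two-class, 2-D
grey-scale problem: within a region of interest (ROI), every pixel is either
muscle (darker) or fibrous tissue (brighter), and the quantity of interest
is the fibrous/muscle pixel-count ratio, averaged over the left and right
limbs of each subject. Three muscle compartments (anterolateral calf,
posterior calf, plantar) are analysed independently; four cohorts
(lean/obese × youth/aged) are compared per compartment with an unpaired
one-way ANOVA. Working on 2-D slices is a deliberate simplification: slice
ratios stand in for volumetric ratios, and no 3-D reconstruction, scanner
physics, or anatomical parcellation is modelled — compartment membership is
assumed given via the ROI.

## Edge-driven segmentation

1. **Edge strength.** The 3×3 Sobel pair (E and Eᵀ) is correlated with the
   raw image (reflect padding); the magnitude √(Gx²+Gy²) is zero on
   constant images and linear in contrast.
2. **Quantization.** The ROI is min–max scaled to G = 64 levels
   (`floor((p − min)/(max − min) · G)` clipped to G−1). Min–max over the
   ROI keeps the two tissue modes near the ends of the grey axis at any
   contrast; no gamma correction or histogram equalization is applied at
   any stage.
3. **Edge co-occurrence matrix.** Each 4-neighbour pixel pair inside the
   ROI adds weight 1 + (s₁+s₂)/2 to counts[i, j] and counts[j, i], where
   s are edge strengths normalized by the image maximum. The weighting
   emphasizes tissue-transition zones while reducing to plain grey-level
   adjacency co-occurrence in the zero-edge limit.
4. **Leading-diagonal labelling.** The diagonal profile (within-tissue
   mass) is smoothed with a moving average (window G/16, min 3, forced
   odd). The tallest local maximum is the dominant tissue mode. A second
   tissue class is accepted only if some other local maximum (a) reaches at
   least 1% of the dominant peak's smoothed height and (b) is separated
   from it by a valley whose minimum drops below half the lower peak.
   Among qualifying candidates the tallest wins. The boundary is the
   midpoint of the minimal valley plateau; the boundary level itself goes
   to the darker (muscle) class, and the brighter peak is always fibrous.
   If no candidate qualifies, the ROI is treated as single-tissue: every
   level is labelled muscle and a `SinglePeakFallbackWarning` is raised
   (surfaced in the run manifest).
5. **LUT segmentation.** The per-level label map is applied pixel-wise to
   the quantized ROI; outside-ROI pixels are background. The ratio is the
   fibrous/muscle count quotient (undefined, and an error, when the muscle
   count is zero).

### Why the valley and height conditions

On ROIs with little or no fibrous tissue, min–max quantization stretches
pure muscle noise across the full grey axis; smoothing leaves small local
maxima riding on one physical cluster. Accepting any "two highest peaks"
then places the class boundary inside the muscle cluster and mislabels
roughly half the ROI. The two conditions encode what actually distinguishes
two tissue classes in this contrast model: bimodality with a near-empty
grey band between the modes, and a second mode carrying non-negligible
area. The 1% height floor acts as a detection limit — fibrous fractions
below about 1% of the ROI are reported as 0, which for the shipped cohort
parameters introduces at most ~0.01 absolute ratio error on a handful of
lean subjects while eliminating catastrophic (order-1) mislabelling. The
0.5 valley factor is far from both regimes it separates: genuine two-tissue
valleys sit near zero, intra-cluster dips near one.

## GLCM texture features

GLCMs are accumulated from ordered pixel pairs (both endpoints in the ROI)
at an integer displacement (Δx, Δy); symmetric mode also counts the
reversed pair. P = W·Q with W the reciprocal total count, so P sums to 1.
The orientation-averaged profile uses symmetric GLCMs at d = 1 and
θ ∈ {0°, 45°, 90°, 135°} (Δx = d·cosθ, Δy = −d·sinθ, x rightward along
columns, y downward along rows) and averages each feature across the four
orientations. Entropy is reported in bits (base 2, configurable); ASM is
Σ P², the standard second angular moment; correlation is the Pearson
correlation of the pair's grey levels under P and raises an explicit error
when a marginal is degenerate (constant ROI). Entropy lies in
[0, 2·log₂ G], ASM in [1/G², 1], and ASM = 1 ⇔ entropy = 0 ⇔ a single
occupied cell. Higher fibrous granularity at fixed area fraction increases
boundary pair diversity and hence entropy; the test suite freezes this
ordering on seeded phantoms.

Note one documented tension: descriptions of entropy as high for
"homogeneous" tissue invert the convention implied by −Σ P log P, under
which homogeneous regions score low. The implementation follows the
formula; the wording discrepancy is noted, not resolved.

## Cohort statistics

Summaries are mean ± SEM (sample s.d./√n, requiring n ≥ 2). The one-way
ANOVA keeps explicit mean squares: MS_between = Σ nᵢ(ȳᵢ − ȳ)²/(k−1),
MS_within = Σ(yᵢⱼ − ȳᵢ)²/(N − k), F = MS_between/MS_within, p from
F(k−1, N−k). Zero within-group variance with unequal means yields F = ∞
with p reported as the limiting 0 and a `degenerate` flag. Unbalanced
designs are handled, though the generator produces balanced ones. No
multiple-testing correction is applied across compartments — per-compartment
ANOVAs are reported unadjusted, and the run manifest records this choice.

`reconcile_sample_size` inverts the balanced-design identity
MS_between = n·Σ(ȳᵢ − ȳ)²/(k−1) by brute force over n ∈ [2, 200]. Against
the shipped group means, the anterolateral and plantar mean squares
reconcile at n = 24 (residuals < 0.002); the posterior compartment
reconciles at n = 25 (residual 0.0034), a discrepancy consistent with the
printed means being rounded to two decimals. The package's default n per
group is 24.

## Synthetic phantoms: what they emulate, and what not

A phantom is a rectangular ROI (margin 8 px of dark background) in a
128×128 8-bit slice; muscle grey 80, fibrous grey 180, additive Gaussian
noise sd 5 clipped to [0, 255]. Fibrous regions are the top-k pixels of a
Gaussian random field low-pass filtered at `blob_scale` = 4 px, which
yields spatially coherent blobs with sharp, realistic boundaries for the
edge detector; k is chosen so the planted ratio is exact up to one
boundary-pixel quantum. Defaults summary:

| parameter | default | units | role |
|---|---|---|---|
| image size | 128×128 | px | slice resolution at desk scale |
| muscle / fibrous grey | 80 / 180 | grey level | distinct two-tissue contrast |
| grey noise sd | 5 | grey level | acquisition noise (~20σ class separation) |
| blob_scale | 4 | px | fibrous granularity |
| roi_margin | 8 | px | background border |
| G (quantization) | 64 | levels | co-occurrence resolution |
| n per group | 24 | subjects | reconciled balanced design |
| bilateral asymmetry sd | 0.01 | ratio | left/right difference magnitude |

Cohorts draw per-subject ratios from Normal(mean, SEM·√n) clipped at zero
(clipping, not resampling, keeps the group mean calibrated for near-zero
means). Left/right ratios are the subject ratio ± half a zero-mean
asymmetry draw (sd 0.01, small and non-significant by design), so their
average equals the subject ratio. Seeds are counter-based
(`SeedSequence((master, group, compartment, subject))`), making every
subject's data independent of cohort size and every run bit-reproducible.

Phantoms deliberately omit: bias fields and T1/T2 contrast mechanisms,
partial-volume voxels and fat infiltration as a third class, anatomical
shape, inter-slice structure, and motion artefacts. Passing recovery tests
therefore demonstrates that the pipeline is unbiased and precise under the
stated two-class contrast model — not that it would segment clinical MRI
unaided.

## Numerical choices and degenerate inputs

- Quantization ties: `floor` scaling; constant ROIs map to level 0.
- Boundary grey level at the valley goes to muscle (darker) class.
- Correlation overshoot beyond ±1 is clamped only within 1e−9.
- GLCM validation tolerates 1e−9 in the sum-to-1 invariant.
- Ratio undefined (no muscle) and empty-ROI cases raise rather than return
  sentinels; impossible phantom geometry (no muscle pixel left) raises
  `PhantomGeometryError`.
- Problem sizes: the replicated end-to-end significance check runs 20 full
  cohort replicates (4 groups × 24 subjects × 3 compartments, bilateral,
  128×128), chosen to keep the whole suite under a minute on one CPU while
  leaving the per-group Monte-Carlo error far below the group separations.

## Known limitations

- The LUT is a pure grey-level threshold once labelled; spatial context
  enters only through the edge weighting of the co-occurrence counts.
- Fibrous fractions below the ~1% detection limit are reported as zero.
- Only two tissue classes; images whose ROI genuinely contains three or
  more grey populations will fold the extras into the nearest class.
- The texture features are three of the classical second-order set;
  contrast, inverse difference moment and the rest are out of scope.
- 2-D slice ratios are used as proxies for volumetric ratios.
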