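# Methods

## The measurement problem

A false-color infrared thermogram of a horse's back encodes surface
temperature in an 8-bit RGB image. After exercise under load, the heat
pattern over the withers and thoracic spine becomes more irregular, and
the irregularity grows with the rider:horse bodyweight ratio. The
package quantifies that irregularity with five bidimensional entropy
measures computed per ROI and per color component (grayscale, red,
green, blue), selects the informative (measure, component, ROI)
combinations with a three-criterion procedure, and scores how well the
selected combinations separate light from heavy rider groups.

## Entropy measures

All five operate on a single 2-D intensity patch. Windows are
enumerated densely at stride 1 in row-major order; all window distances
are Chebyshev (maximum absolute difference of corresponding pixels).

**Sample entropy** (`sampen2d`). The m-stage and (m+1)-stage windows
share the same top-aligned anchor grid — the `(N−m)²` positions where an
`(m+1)×(m+1)` window fits — so `Φ_{m+1}/Φ_m` is a genuine conditional
probability. Match densities count ordered window pairs with distance
≤ r, self-pairs excluded. `SampEn = −ln(Φ_{m+1}/Φ_m)`. If either count
is zero the value is *undefined* (an error distinct from 0); this
happens routinely on small or very noisy patches and is itself
informative — measures that cannot be evaluated cannot be selected.

**Fuzzy entropy** (`fuzzen2d`). Same windowing; each window's own mean
is removed (local baseline), and the hard threshold is replaced by the
membership `exp(−d^n / r)` averaged over ordered pairs. A constant
patch returns 0 by short-circuit (every membership is 1 regardless of
r); r = 0 on a non-constant patch is a parameter error. Note the
membership exponent scales as `a^(n−1)` under `x → a·x`, so fuzzy
entropy with a fraction-of-SD tolerance is affine-invariant only for
n = 1; with the default n = 2 it remains rotation-insensitive but not
scale-free.

**Permutation entropy** (`permen2d`). Each `dn×dm` window is flattened
row-major and reduced to its ordinal pattern by a stable argsort (ties
broken by position, deterministically). The default output is the
Shannon entropy of the pattern distribution divided by `ln((dn·dm)!)`,
in [0, 1].

**Dispersion entropy** (`dispen2d`). Pixels are mapped through the
normal CDF under the patch mean and SD (population SD, ddof = 0) and
discretized to classes `z = round(c·v + 0.5)`, rounding half away from
zero and clamping to 1..c. The entropy of the `dn×dm` class-pattern
distribution is divided by `ln(c^(dn·dm))`. A zero-variance patch is a
documented degenerate: one class, one pattern, entropy 0, with a
warning rather than an error.

**Distribution entropy** (`disten2d`). The Chebyshev distances between
all distinct pairs of `m×m` windows (here the full `(N−m+1)²` window
set; no centring) are histogrammed into M equal bins spanning
[0, d_max] per patch, making the measure scale-invariant; the output is
the base-2 Shannon entropy of the bin probabilities, divided by
`log2(M)` when normalized. An all-zero distance multiset occupies one
bin and yields 0.

### Parameter defaults

| symbol | meaning | default | rationale |
|---|---|---|---|
| m | sample/fuzzy/distribution window size | 2 | prevailing convention for small textures |
| r | similarity tolerance | 0.2 × patch SD | scale-free; standard fraction |
| n | fuzzy exponent | 2 | standard fuzzy membership sharpness |
| dn, dm | embedding window | 2 × 2 | 24 ordinal / 81 dispersion patterns stay estimable on small ROIs |
| c | dispersion classes | 3 | keeps 3⁴ = 81 patterns estimable |
| M | distance histogram bins | 512 | fine-grained ePDF, standard choice |

`paper_literal=True` replaces the pattern-count normalization of
permutation/dispersion entropy with division by the *window count* —
a prefactor that also appears in the literature but does not map to
[0, 1]; both conventions are provided because sources disagree.

### Invariances (as tested)

Positive affine intensity maps: SampEn (fractional r), DispEn, DistEn
exactly; FuzzEn exactly for n = 1; PermEn under any strictly increasing
map. 90° rotation: PermEn, DispEn, DistEn exactly (rotation permutes
their pattern/distance censuses bijectively); SampEn and FuzzEn only
approximately, because the top-aligned shared anchor grid drops a
different boundary row/column after rotation (an O(1/N) edge effect —
the price of the exact conditional-probability pairing).

## GLCM entropy features

The baseline features come from the gray level co-occurrence matrix:
64 gray levels (uniform binning of [0, 255]), offset distance 1, four
directions (0°, 45°, 90°, 135°) symmetrically accumulated, each
direction normalized before averaging. `Entropy = −Σ P ln P`;
`SumEntrp` and `DifEntrp` apply the same functional to the diagonal
(`p_{x+y}`) and antidiagonal (`p_{x−y}`) marginals; `0·ln 0 ≡ 0`.
Natural logs throughout. Exact numeric agreement with any particular
external GLCM program is not claimed — the selection criteria only need
internally consistent behaviour.

## Selection procedure

Every statistical branch is gated by Shapiro–Wilk at α = 0.05; the
parametric branch is used only when *all* series entering a test pass
the gate (the conservative combination rule). Zero-variance series are
non-Gaussian by rule.

1. **Exercise dependence.** Per rider group, pre vs post values paired
   by (horse, rider): paired t-test (Gaussian) or Wilcoxon signed-rank.
   A combination passes only with p < α in L *and* M *and* H. All-zero
   differences report p = 1 with a warning. A (combination, group) with
   fewer than 3 complete pairs — typically undefined sample entropy on
   small patches — fails the criterion (`insufficient_pairs`).
2. **Rider-group dependence.** Post-exercise values: one-way ANOVA +
   Tukey HSD, or Kruskal–Wallis + Dunn's test (tie-corrected z tests,
   Bonferroni over the 3 pairs). Pass = omnibus p < α and at least one
   adjusted pairwise p < α.
3. **Slope similarity.** For each surviving combination, its
   post-exercise values are regressed on the rider:horse bodyweight
   ratio (the only continuous ordering of the groups) and compared with
   each retained GLCM feature by the ANCOVA slope-equality F-test
   (pooled-vs-separate-slope residual comparison; on equality the
   pooled slope is reported and intercept equality tested the same
   way). The GLCM baseline set consists of the feature instances that
   pass criteria 1–2 themselves. A feature is dropped when its slope is
   below half the entropy slope for more than half of the compared
   survivor combinations (the half-slope rule needs a fixed threshold;
   majority is the neutral choice). A combination is selected when its
   slope is statistically equal (p > α) to at least two retained
   features. Because the measures carry different units (normalized
   entropies in [0, 1] vs GLCM entropies in nats, up to ln 4096), raw
   slopes are incommensurable; responses are z-scored before these
   regressions so slopes are unit-free. Series are aligned on
   (horse, rider) labels, so missing values reduce n instead of
   breaking the comparison. No multiplicity correction is applied
   across the 40 combinations, by design.

## Detection

Light (L) vs heavy (H) groups only; heavy is the positive class. Three
cutoffs at mean − SD / mean / mean + SD (sample SD, n − 1) of the
*pooled* L+H post-exercise values — pooling uses no group labels at
threshold-setting time. An observation strictly above the cutoff is
called heavy (ties → light). Se, Sp, PPV and NPV are reported to two
decimals with full precision retained internally; ratios with zero
denominators are NaN, never 0. Se is non-increasing and Sp
non-decreasing in the cutoff by construction.

## Synthetic study generator

The generator reproduces the study *design*, not equine physiology: a
temperature field is Gaussian-smoothed white noise (correlation length
8 px, SD 4 intensity units) on a base level of 30, plus i.i.d. Gaussian
irregularity noise with amplitude 0.5 pre-exercise in every group and
(1.0, 1.5, 2.0) post-exercise for (L, M, H) — irregularity rises after
exercise everywhere and rises with rider group after exercise. Post-
exercise fields get a ×1.2 gain inside both ROI masks, which moves the
ROIs into the warm (red-dominated) part of the colormap, concentrating
the measurable signal in the red channel as in real thermograms. The
field is min-max normalized per image and rendered through a fixed
256-entry blue→green→red lookup table (red non-decreasing, blue
non-increasing in temperature; a constant field renders mid-colormap by
rule). Rider weights default to the two published per-group values
(58/60, 75/77, 91/92 kg — group means 59.0/76.0/91.5), horse weights
are drawn around 566.7 ± 13.7 kg and saddles uniformly in 4.1–4.5 kg,
so the design-table ratios land in the published 11.2/14.2/16.9 %
bands. One global seed fans out deterministically (design: the seed
itself; image of design row i: `SeedSequence([seed, i])`), making every
run byte-reproducible.

The effect magnitudes are free parameters of the emulation, not
estimates — no quantitative texture effect size is available to fit.
What passing tests show is that the *machinery* recovers a planted
monotone irregularity signal at realistic sample sizes; they say
nothing about effect sizes, anatomy, ambient conditions or camera
response in real horses.

## Numerical and scale choices

* Pairwise window distances are computed with C-optimized Chebyshev
  `cdist` in row blocks; results are exact (no approximation), verified
  to 1e-10 against pure-Python exhaustive enumeration oracles on 50
  seeded patches per measure.
* Replicate-study simulations (tests and the acceptance script) run the
  full 144-image design with 24×24-px ROIs; the generator's default ROI
  is 64×64. The planted-effect conditions (amplitudes, group sizes,
  design) are identical at both sizes; 24 px keeps a 20-replicate study
  sweep within minutes on one core. At this size sample entropy is
  frequently undefined on post-exercise patches, so SampEn combinations
  are rarely selected — mirroring its documented small-image behaviour.
* Monotonicity of the measures in the planted noise amplitude is
  validated on the rendered 8-bit red channel — the quantity the
  pipeline actually measures. On raw float fields the scale-invariant
  distribution entropy depends only on the noise/background ratio and
  is not monotone increasing; 8-bit quantization restores the monotone
  response for all five measures.

## Known limitations

* Rectangular ROIs only; no segmentation of the horse's back.
* The grayscale conversion is fixed to BT.601 luma (round half away
  from zero); thermal cameras may use other renderings.
* Sample entropy is undefined (not zero) whenever either match count
  vanishes; downstream stages treat such values as missing.
* The criterion-3 z-scoring makes slope comparisons unit-free but means
  the reported pooled slopes are in SD units, not raw measure units.
* The classifier distinguishes only light vs heavy groups; the moderate
  group informs selection but is never classified.
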