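# Methods

This note documents the models implemented in `wildfuse`, the defaults they
ship with, the numerical choices that affect results, and what the synthetic
data can and cannot tell you about real survey imagery.

## Scene model (synthdata)

A scene is a pair of rasters of the same ground area: a 3-channel visible
frame and a smaller single-channel thermal frame related by a similarity
transform `x_vis = s·x_th + t` (pixel-center convention, origin top-left,
x rightward, y downward, half-open boxes). Defaults use a 448×358 visible /
160×128 thermal frame at the sensor ratio s = 2.8; full-size 4000×3000 /
640×512 generation is a config change. Backgrounds are independent draws of
Gaussian-smoothed uniform noise (smoothness 8 px) for the two modalities, so
all cross-modal structure comes from the objects; this deliberately makes
fusion gains measurable and registration non-trivial.

Animals are rendered as a rotated body ellipse with an overlapping head
ellipse. Species profiles control conspicuousness:

| profile | visible contrast | thermal contrast | body semi-axis (px) | shadow prob |
|---|---|---|---|---|
| deer-like | 0.02 | 0.5 | 14–24 | 0.6 |
| cow-like | 0.35 | 0.5 | 16–28 | 0.05 |
| horse-like | 0.30 | 0.5 | 18–30 | 0.05 |

The deer profile is the cryptic case: near-zero luminance offset and a 60%
chance of sitting in a multiplicatively darkened (×0.4) shadow patch that
affects the visible raster only. Object sizes are chosen so bodies span at
least ~6 thermal pixels; below that, resampling smears a warm body into its
surroundings and the object's thermal box contrast (contract: box mean minus
background mean ≥ half the thermal offset) degenerates — real survey frames
image animals at tens of thermal pixels. Boxes are tight bounds of the
rendered mask, placed without overlap by rejection sampling (bounded
retries, then a placement error).

The simulated detector drops each truth box with probability `fn_rate`,
jitters surviving corners with Gaussian noise, relabels with probability
`misclass_rate`, adds Poisson-distributed spurious boxes, and scores each
detection 1/(1 + mean corner displacement) so an exact box has confidence
1.0. Every output is a pure function of (config, seed).

**What passing tests do not show:** ellipse animals have no pose, occlusion
or motion blur; backgrounds are stationary noise, not vegetation; the
misregistration is a pure similarity (no lens distortion or parallax).
Results transfer to real imagery only at the level of algorithmic behavior,
not absolute metric values.

## Registration

The thermal-to-visible scale is fixed by lens geometry (2.8 by default;
640→1792 px), not estimated. Residual translation is estimated by phase
correlation between Hann-windowed Sobel gradient magnitudes — gradients
survive the modality change far better than intensities — with a
three-point quadratic refinement of the correlation peak per axis. The peak
search is restricted to `max_shift`; if the dominant unrestricted peak lies
outside and is clearly stronger, registration fails loudly with the raw
estimate attached. Same-modality recovery is accurate to ≲0.2 px; full
cross-modal recovery on synthetic scenes is typically ≲0.3 px and bounded by
~0.7 px in stress tests.

All resampling uses explicit pixel-center alignment (output pixel r samples
input r/s, bicubic, edge-clamped). The area-based convention used by some
libraries introduces a systematic (1−s)/2 ≈ −0.9 px offset at s = 2.8
against this package's transform definition and is deliberately avoided.
The visible frame is cropped to the estimated thermal field of view
(overhangs up to 2 px — noise-level estimates on aligned pairs — are
clamped; larger ones error) and both rasters are resampled to the common
working size, by default the upscaled thermal size.

## Fusion methods and defaults

All methods consume the visible **luminance** (BT.601) and the normalized
thermal raster in [0, 1] and clip their output to [0, 1]. Chroma is not
fused; metrics stay single-channel. In every max-selection rule exact ties
average the candidates, which makes fuse(A, A) = A hold structurally.
Borders use symmetric padding. Defaults are canonical literature settings,
all config-exposed:

- **laplacian** — 4-level Burt–Adelson pyramid (binomial 5-tap kernel);
  detail levels merge by max-|coefficient|; the approximation layer merges
  8×8 block-wise by higher local variance. Reconstruction of an unmodified
  stack is exact to float precision.
- **guided_filter** — two-scale split (31×31 box mean + residual);
  saliency = Gaussian-smoothed |Laplacian| (σ = 5); binary saliency argmax
  weights refined by guided filtering (base: r = 45, ε = 0.3; detail: r = 7,
  ε = 10⁻⁶) with the respective source as guide, renormalized pixelwise.
- **svd** — 8×8 blocks scored by singular-value energy Σσᵢ² (equivalently
  the squared Frobenius norm); the higher-energy block is emitted.
- **sparse** — 8×8 patches, stride 2, mean-removed, coded by OMP (≤8 atoms)
  against a fixed 256-atom overcomplete separable DCT dictionary; the code
  with larger L1 norm wins per patch; overlap-averaged reconstruction. A
  full patch of padding on every side gives each output pixel full overlap
  coverage, which keeps the identity-fusion error within OMP truncation.
- **gradient** — pointwise stronger source gradient (forward differences,
  Neumann boundary); least-squares integration by a DCT-II Poisson solve;
  mean fixed to the average source mean. The solver reproduces the Neumann
  eigenfunction cos(πx)cos(πy) from its analytic gradients to ≤10⁻⁴ at
  256², and O(h²) generally.
- **tvm** — gradient transfer: minimize Σ(f−b)² + λΣ|∇f−∇a| with λ = 4,
  by iteratively reweighted least squares (ε = 10⁻⁶ smoothing, CG inner
  solves, ≤200 outer iterations, relative-energy tolerance 10⁻⁵). A
  backtracking safeguard keeps the recorded energy trace non-increasing and
  raises a solver-divergence error if no damped step descends. The thermal
  raster is the fidelity target and the visible raster the gradient source:
  warm bodies keep their intensity, visible texture supplies edges.
- **wl_tvm** — db2 wavelet, 3 levels; detail subbands by max-|coefficient|;
  the approximation subband fused by the TVM objective above (unclipped in
  transform space); inverse transform.
- **wl_swarm** — db2, 3 levels; one convex weight per subband (1 + 3·levels
  weights, fused subband = w·A + (1−w)·B) optimized by global-best particle
  swarm (20 particles, 40 iterations, inertia 0.7, c₁ = c₂ = 1.5, positions
  clamped to [0, 1], one particle seeded at the 0.5 blend) maximizing the
  entropy of the reconstructed image. Deterministic per seed; the global
  best is non-decreasing by bookkeeping.

A note on the swarm hybrid: because its objective is information content, it
willingly blends toward the higher-entropy (often noisier) source and
therefore does *not* dominate naive 50/50 averaging on the Petrovic
edge-preservation metric, unlike the other seven methods on
modality-unique-texture fixtures. This trade-off is inherent to the
objective, not a solver defect.

## Quality metrics

Computed per annotated object box (half-open, clipped to the raster), never
averaged across methods. Entropy uses a 256-bin histogram over the fixed
range [0, 1]; mutual information uses a 64×64 joint histogram (finite-sample
stability in small boxes; MI of independent regions is bounded by the
(bins−1)²/(2N ln 2) bias). Both choices are config-exposed.

The Petrovic score compares Sobel edge strength and orientation between each
source and the fused image. Relative strength G = min(g₁,g₂)/max(g₁,g₂) and
orientation agreement A = 1 − Δα/(π/2) (orientations folded to [−π/2, π/2))
pass through the published sigmoid models (Γ_g = 0.9994, κ_g = −15,
σ_g = 0.5; Γ_α = 0.9879, κ_α = −22, σ_α = 0.8), each **normalized by its
value at perfect preservation** so that an exactly transferred edge scores
1.0 and the metric is a true [0, 1] scale with Q = 1 on identical triples;
without the normalization, perfect transfer saturates at ≈0.975. Per-pixel
scores are averaged weighted by source edge strength (exponent L = 1);
zero-gradient pixels carry no weight, and an entirely flat triple scores 1
by convention (nothing to preserve).

## Detection evaluation and rank aggregation

Matching is greedy per class in descending confidence order against the
unmatched truth of highest IoU ≥ 0.5 — the convention required for
PR-curve semantics. It agrees with exhaustive optimal assignment on random
small instances; a constructed counterexample (documented in the tests)
shows the known one-pair gap. Undefined ratios (zero denominators) raise a
typed signal and are reported as absent, never coerced to 0 or 1. AP uses
101-point interpolation (all-points integration available); mAP50 is the
unweighted mean over classes present in the truth. Relative improvements
are rounded half-away-from-zero to integer percent.

The packaged mAP50 grid (10 methods × 3 species × 2 detector architectures)
is a printed input: those values come from GPU-trained detectors on survey
imagery and are not recomputable here. Aggregation dense-ranks each of the
six columns descending — tied values share a rank and the next distinct
value takes the next integer — and sums ranks per method. Dense ranking is
the only ranking scheme consistent with all ten published rank-score sums,
which is why it is the one implemented.

## Problem sizes and runtime

Default test-suite problem sizes: 96–256 px rasters for fusion and metric
properties, 224×180 scenes for the 20-scene cryptic-target entropy suite,
496×400 scenes for registration recovery, 1000 objects for detection
statistics. These sizes keep the full suite around three minutes on one CPU
while leaving every effect far from marginal (e.g. the sparse-fusion entropy
gain on cryptic targets is ~1.6 bits at the median).

## Known limitations

- The exact merge rules and solver settings behind the published mAP50 grid
  are not public; this package's defaults are canonical, not a claimed
  match, so per-object metric values on real imagery will differ.
- Registration assumes a pure similarity transform with known scale; no
  homography, lens distortion, or temporal offset.
- The sparse method's identity-fusion error is bounded by OMP truncation
  (≤8 atoms); on unstructured white noise the dictionary cannot represent
  patches and the 1e-2 identity tolerance does not apply.
- K-SVD-style dictionary learning (`learned_dictionary`, seed required) can
  replace the analytic DCT dictionary, but the analytic default is kept for
  determinism and reproducibility.
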