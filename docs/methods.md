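# Methods

This note records the scientific and numerical choices behind the
package: what the simulation emulates, how its parameters were fixed, and
what passing tests do and do not establish.

## Stimulus model

Every stimulus is a five-component stack — specular `S`, diffuse `D`,
multiplicative texture `T`, object mask `α`, background `B` — mixed
linearly by the specular weight `w`:

    I = S·w + D·T·(1−w) + (1−α)·B

computed in linear float with no clipping; gamma-2.2 encoding and clipping
happen only at PNG export. The corpus pairs every scene at w = 0.98
(high gloss) and w = 0.02 (low gloss), so the classes differ *only* in the
mixing weight; scenes whose object covers less than 20% or more than 90%
of the frame (object pixel = α > 0.5; boundaries kept) are re-drawn until
the scene quota is met.

The components are procedural stand-ins for physically based renders:

* `α` — thresholded low-pass noise blob with a random target coverage
  drawn from U(0.08, 0.97), so the coverage filter is genuinely exercised
  on both sides;
* `D` — smooth directional shading with gentle mottle and a random tint;
* `S` — warped fine noise thresholded at its 88th percentile, giving
  sparse, high-contrast highlight fields;
* `T` — a marbled mid-frequency pattern in [0, 1] (low-gloss images are
  not separable by mean brightness);
* `B` — low-contrast large-scale field.

**Ambiguity tail.** A fixed 15% of scenes get a graded "confusable"
appearance: either the specular field is low-pass filtered with a
severity-scaled sigma up to size/32 (a glossy object under diffuse
illumination, reading as matte), or the texture fades toward black while
sparse bright glint marks appear (a dark varnished look, reading as
glossy). Without this tail the two classes' image statistics are so
cleanly separated that the diagnostic-set construction has no genuinely
ambiguous images to harvest; real render corpora supply such images at low
density (which is why the original-scale study screened tens of thousands
of images to find hundreds of candidates). The rate and severity grading
were fixed once when the generator was designed and are part of the study
conditions.

All randomness flows through one integer seed per scene; a corpus is
reproducible byte-for-byte from `(n_scenes, seed)`.

## Simulated observers

An observer's decision variable is a latent scalar evidence

    e = Σ_k  u_k · (c_k − μ_k) / σ_k

over three cues computed inside the object mask: high-spatial-frequency
contrast (residual sd after Gaussian blur, sigma 2 px), bright-pixel
coverage (fraction above max(2×mean luminance, 0.3)), and an
edge-sharpness proxy (mean gradient magnitude over a 2-px-eroded mask,
normalized by mean luminance — the erosion keeps object/background border
gradients from dominating dark objects). The normalisation constants
(μ, σ) are frozen population statistics of the shipped generator at 64 px
(200-scene pooled sample), and the weights are (0.5, 0.1, 1.4), chosen
once so that the sharpness cue — the strongest single discriminator —
dominates. Evidence is therefore a z-score-scale quantity, symmetric
around 0 between the classes.

Responses are noisy-threshold judgments: binary response = 1 iff
`e + bias + N(0, σ_obs) > criterion`, with a lapse rate (uniform guess)
capped at 0.1; five-point ratings discretize a logistic squash of the
noisy evidence into equal-width bins; triangular-field responses place
the squashed evidence horizontally within the triangle row selected by a
noisy realism coordinate. Observers are drawn from population
distributions (bias and criterion sd 0.22, noise sd |N(0.55, 0.25)|,
lapse U(0, 0.04)) under one master seed. With these defaults a
10-observer panel scores ≈ 87–88% correct on random corpus images at
64 px — the accurate-but-imperfect regime — and 64-rater panels show
leave-one-out correlations well inside (0, 1), i.e. idiosyncratic but
consistent raters. The calibration was performed once, against the
shipped generator, and frozen; 64 px is the calibrated evidence scale
(network training uses 32 px inputs for speed, which is fine because
networks never consume the evidence signal).

## Diagnostic-set construction

The pipeline mirrors the multi-round human study: (1) a 10-observer
binary prescreen of the full corpus; (2) per ground-truth material,
images are binned seven ways by mean response (equal width on the
nominal [0, 1] range, half-open bins, top bin closed) and a quota is
selected visiting bins most-incorrectly-judged first, carrying shortfalls
to the next bin — plus a wrap-around backfill pass so the quota is met
whenever total supply suffices; (3) a 99-rater crowd gives five-point
ratings on the candidates, with exclusions for wrong trial counts or
failed catch trials (a clearly glossy teapot-like probe rated < 4, or a
clearly matte sandcastle-like probe rated > 2; 35 simulated raters are
constructed to violate a rule, leaving a 64-rater panel); (4) candidates
are binned five ways by panel-mean rating — equal width over the
*observed* rating range, since panel means compress toward the scale
midpoint and nominal-range bins would leave outer bins empty — and 10
images per material are drawn from each of the three central bins,
giving 60 images, 30 per material.

If a central cell lacks 10 candidates for a given corpus draw, the
pipeline extends the corpus by 50% and repeats the harvest (up to three
extensions). This mirrors the original procedure, which ran a second
search round when incorrectly perceived low-gloss images ran short; the
selection thresholds themselves are never relaxed.

The endpoint is a construction property, verified end-to-end in the
tests: on the selected set, thresholded mean observer responses score
at chance (binomial test, α = 0.01) and correlate near zero with ground
truth, across seeds (measured r ∈ [−0.02, 0.12], accuracy 47–57% over a
12-seed sweep).

## Classifiers

* **Pixel-statistic baseline** — linear max-margin classifier on 8
  statistics: mean, variance, skewness (g1) and kurtosis (non-excess) of
  the Rec. 709 luminance and HSV-saturation histograms. Degenerate
  channels define skew/kurtosis as 0.
* **Texture-statistic baseline** — logistic regression on principal
  components (smallest k explaining ≥ 99% variance, projection reused on
  test folds) of a reduced texture-statistic vector over a wavelet
  pyramid (db2, 3 scales): per-channel marginal moments, subband
  variance/skew/kurtosis, lowpass autocorrelations, cross-scale magnitude
  correlations, and cross-channel subband correlations (216 statistics at
  the default configuration). This is a deliberately reduced stand-in for
  full steerable-pyramid color texture statistics; the vector length is
  config-derived.
* Both baselines use scene-level twofold cross-validation repeated 10
  times (scenes, not images, are split, so a scene's two materials never
  straddle a fold), giving each image exactly 10 held-out predictions.
* **CNN family** — depth 1–12; each conv layer (odd kernels, same
  padding, rectified-linear) is followed by a stride-2 2×2 max-pool for
  depths ≤ 6; deeper stacks have exactly depth−6 pool-free layers at
  searchable positions. Head: single linear unit with logistic squash, so
  the response is P(high gloss). Training: SGD with momentum and L2 decay
  (the three searched training hyperparameters); batch size fixed at the
  config default. Early stopping: validate every `val_interval` steps
  (default 100; desk-scale runs use 25–50), stop after 5 consecutive
  validations without a strictly lower loss, return the best-loss
  checkpoint. Networks with non-finite losses or response sd < 1e−6 on a
  probe set are "dead" and excluded from every analysis.
* **Readout training** — a frozen backbone exposes post-activation
  features per layer; only a fresh linear head is trained, under the same
  early-stopping contract. An in-repo fixed-seed random CNN serves as the
  frozen backbone in tests; any object with a `features(X, layer)` method
  can be plugged in.

All networks are implemented directly in NumPy (im2col convolutions,
float32) — at 32 px and a few hundred images per corpus this trains a
3-layer network to >90% validation accuracy in seconds on one CPU.

## Human-likeness search

The search objective is the Pearson correlation between a trained
network's diagnostic-set responses and mean simulated-observer ratings
(rescaled to [0, 1]); zero-variance responses mark the trial dead rather
than propagating NaN. The default sampler is an independent
tree-structured Parzen estimator (top-25% / rest kernel-density split,
24 candidates per parameter, 5 random startup trials); a Gaussian-process
expected-improvement sampler and pure random search are available behind
the same interface. The desk-scale search space is filters 4–32
(log-uniform), kernels {3,5,7}, learning rate 1e−4–1e−1 (log), momentum
0–0.99, L2 1e−6–1e−2 (log), plus pool-free position sets for depths > 6.
Dead trials are recorded but excluded from the sampler's history. Full
scale is 300 trials at each of 9 depths (2,700 networks); the desk-scale
smoke test runs 3 depths × 20 trials on a 200-scene corpus in a few
minutes.

## Highlight probes

Probes recompose 120 fresh coverage-filtered scenes (never used in
training) under three manipulations at base specular weight 0.1:
contrast (w ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0}), size (per-channel
grayscale erosion/dilation with a disk element, radii 2–5 px), and
orientation (rotate the specular field ±10°–±90° in 10° steps about the
image center, bilinear interpolation; the support is S > 1e−3 on any
channel). Each rotated image is paired with a coverage-matched control:
the *unrotated* specular restricted to the same rotated-support ∩ object
mask, so the pair differs only in highlight orientation. Effect sizes:
Δ_contrast = R(1.0) − R(0.01); Δ_erode = R(unmanipulated) − R(erode 5);
Δ_dilate = R(dilate 5) − R(unmanipulated); Δ_rotate = max over angles of
R(control) − R(rotated).

**Limitation.** At 32 px with training classes at w ∈ {0.02, 0.98},
trained networks' responses at the intermediate w = 0.1 sit near the
saturated low end of the logistic head, so erosion/dilation effects are
near zero with unstable sign (a representative network measured −0.006
and −0.05); the contrast effect is large and positive (≈ +0.8), and that
direction is what the test suite asserts. Resolving graded size effects
would need larger images and intermediate-weight training exposure.

## DCGAN family

Five generator/discriminator pairs are derived from four principles:
resolution doubles per generator layer and halves per discriminator
layer; filter counts halve for later generator layers and double for
later discriminator layers; a depth-d generator starts at 128/2^d pixels
(4×4 for depth 5 … 64×64 for depth 1); the latent input is 100×1
everywhere. The generator is a dense projection followed by
upsample-then-convolve transposed convolutions (odd 5×5 kernels);
the discriminator uses 4×4 stride-2 convolutions with leaky-rectifier
(slope 0.2) activations. Batch normalization is omitted: at desk-scale
batch sizes (8) batch statistics are unreliable, and the family's tested
contracts (shape schedules, mirroring, sampling determinism) do not
depend on it. Note that while the convolutional stacks grow strictly
with depth, *total* parameter counts are U-shaped in depth: the dense
latent projection scales with the squared start resolution, which is
largest for shallow generators. Training is the standard adversarial
alternation (non-saturating generator loss) at deliberately tiny scale,
with a generator-variance mode-collapse warning and no convergence claim.

## Metrics

Pearson correlations use the standard product-moment form (checked to
1e−12 against a brute-force oracle). Leave-one-out observer correlation:
each observer's per-image means vs the mean of the remaining observers.
The depth trend fits a least-squares quadratic to per-depth
accuracy-likeness correlations (depths need ≥ 3 live networks and
nonzero variance) and reports the smallest real root inside the observed
depth range. Top-decile composition selects ceil(0.1·n) live networks by
objective, ties broken deterministically by trial id. Triangle responses
decompose into realness = y and glossiness = (x − y/2)/(1 − y), apex
→ 0.5, invariant to canvas scaling. Rating accuracy counts responses
strictly on the correct side of 0.5 (midpoint incorrect). d′ uses the
pooled-variance form (mean_h − mean_l)/√((var_h + var_l)/2) with
unbiased variances — a distributional sensitivity index independent of
any threshold criterion; zero pooled variance yields a signed-infinity
sentinel.

## What the synthetic study does and does not show

Passing tests establish that every *procedure* — composition, filtering,
splits, selection quotas, exclusion rules, training contracts, search
bookkeeping, probe constructions, metrics — behaves exactly as specified,
and that the pipeline's central construction (decorrelating mean
observer response from ground truth) works end to end under realistic
noise. They do not establish anything about real human gloss perception:
the observers are a noisy-threshold model driven by hand-chosen image
cues, the stimuli are procedural rather than rendered, and absolute
numbers (best human-likeness r, d′ values, effect magnitudes) are
properties of the simulation, not of people. Problem sizes (600-scene
pipeline corpus, 200-scene training corpora at 32 px, 20-trial searches)
are the package's desk-scale defaults, chosen so the full study runs on
one CPU in minutes; all of them scale up by argument.
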