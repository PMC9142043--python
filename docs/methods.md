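# Methods

## Spectral geometry

A CARS sweep probes the Raman shift `ν̃ = 10⁷/λ_pump − 10⁷/λ_Stokes`
(wavelengths in nm, shift in cm⁻¹). The default axis sweeps the pump from
804.0 to 826.4 nm in 0.7 nm steps against a fixed 1064 nm Stokes beam:
33 channels covering 3039.3 down to 2702.2 cm⁻¹, stored in acquisition
order (increasing pump, decreasing wavenumber). Grid termination uses a
10⁻⁶ nm tolerance so the final step lands on 826.4 nm despite binary
rounding; wavenumbers are stored unrounded and rounded to one decimal only
for display.

## Preprocessing

Per cube, in a fixed order:

1. **Saturation masking.** A pixel is excluded if any channel reaches the
   detector ceiling `sat_value` (metadata, not a constant — detectors
   differ). Masking precedes pooling so one hot pixel cannot bias its
   2×2 block.
2. **2× spatial down-sampling.** Each output pixel is the mean of its 2×2
   block per channel, over unmasked inputs only; a block is masked only
   when all four inputs are. Odd trailing rows/columns are trimmed.
   For fully unmasked cubes the global mean is conserved to 1e-9
   (block means are computed in float64).
3. **Baseline correction.** A two-anchor straight line in wavenumber,
   through the (mean wavenumber, mean intensity) of the first and last
   `anchor_m = 3` channels, is subtracted per pixel spectrum. The window
   edges are signal-poor in the CH-stretch region, which makes the linear
   two-anchor model deterministic and adequate; negative residuals are
   kept. More elaborate baselines (rubber-band, polynomial, asymmetric
   least squares) are deliberately out of scope.
4. **Vector normalization.** Division by the Euclidean norm
   `sqrt(Σ xᵢ²)`, the standard chemometric vector normalization. Pixels
   with norm < 1e-12 are dropped as degenerate. Normalization follows
   baseline correction, matching the order in which the steps are
   conventionally listed.

## Clustering

Pixel spectra of all images of both genotypes are pooled — a shared model
is what makes per-genotype cluster percentages comparable — and clustered
with Lloyd's algorithm under k-means++ seeding, 10 restarts, keeping the
restart with minimal within-cluster SSE (inertia). The fit uses a seeded
uniform subsample of at most `pixels_per_image_cap` (default 20 000)
pixels per image; assignment afterwards covers every pixel. Euclidean
distance on unit-norm spectra is equivalent to cosine dissimilarity up to
a monotone transform. Within-run inertia monotonicity is asserted during
iteration; empty clusters are re-seeded with the point farthest from its
centroid.

Clusters are reported in canonical order of descending centroid
lipid:protein ratio — intensity at the channel nearest 2850 cm⁻¹ over
that nearest 2940 cm⁻¹ — so index 0 is always the most lipid-dominant.
Numerator intensities are clipped at zero and the denominator floored at
1e-6: a centroid with lipid signal but no protein signal is maximally
lipid-dominant, one with neither band ranks last, and the ordering is
immune to the ±1e-7 numerical noise that baseline correction leaves in
empty channels. Ties break by descending cluster size, then raw index.
Rendered maps use a fixed palette keyed to canonical indices (red =
lipid-dominant), so colors are stable across runs.

A note on optimality: Lloyd's algorithm with restarts is a local search.
On rare tiny instances the globally optimal partition is a Lloyd fixed
point whose basin no data-point seeding reaches; the test suite verifies
the fit against exhaustive partition enumeration and, for such instances,
against the best value reachable by Lloyd iteration from any point
seeding.

## Classification

The unit of classification is one image's mean preprocessed spectrum
(8–18 per synthetic cohort, 33 channels). PCA centers columns and applies
no variance scaling; principal directions come from the SVD of the
centered matrix, with each loading's largest-magnitude entry made
positive. The two-class Fisher discriminant is
`w = (S_w + λI)⁻¹(μ_KO − μ_WT)` with `S_w` the pooled within-class
covariance (n−2 denominator) and ridge `λ = 1e-8·trace(S_w)/p` for
stability in small folds; a point goes to the class whose projected mean
is nearer (equal priors, midpoint threshold — the cohorts under study are
deliberately class-balanced in design, and sensitivity is reported per
class anyway). If the class means coincide exactly the model predicts the
larger training class (ties → WT).

**Cross-validation.** LOMO-CV holds out one mouse at a time: the training
set excludes every image of that mouse, PCA and LDA are refit per fold on
training images only (refitting inside the fold avoids the information
leak a single global PCA would introduce), and each held-out image is
predicted once. Mean sensitivity is the unweighted average of the two
per-genotype recalls (balanced accuracy), so class imbalance does not
bias it. Its uncertainty is the standard deviation over 200 seeded
bootstrap resamples of mice — stratified by genotype so both classes stay
represented — recomputed from the stored per-image predictions; the
bootstrap definition is a package choice among several reasonable ones.
`pc_sweep` runs LOMO-CV for 1..15 PCs (capped by per-fold feasibility,
`n_pc ≤ min(n_train−1, C)`) and selects the smallest PC count attaining
the maximal mean sensitivity. An image-level (non-grouped) CV mode exists
solely to demonstrate the sensitivity inflation subject leakage causes;
it should never be used for reporting.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the physics of CARS image formation. Pixel spectra are sums of
Gaussian bands — CH₂ symmetric 2850 cm⁻¹ (σ 16), CH₂ asymmetric
2889 cm⁻¹ (σ 14, amplitude 0.55), CH₃ asymmetric 2940 cm⁻¹ (σ 18) — over
a linear non-resonant background (level 0.3, slope −5e-4 per cm⁻¹),
clipped at zero and at the ceiling. Wild-type lipid and protein bands
have equal amplitude 1.0 (a double peak of similar height); the knockout
lipid amplitude is 1.6× — the configured genotype effect. Hierarchical
variability:

- **Mouse effect:** a log-normal multiplier on the lipid amplitude,
  log-SD `mouse_sd = 0.10`. This is the one calibrated parameter: it sets
  the between-animal overlap and therefore the ceiling of genotype
  discrimination, and its default is chosen so the one-image-per-mouse
  cohort's LOMO-CV mean sensitivity at 2 PCs (~95% averaged over seeds)
  matches the performance reported for real cohorts of this design.
- **Spatial field:** per image, white noise low-pass filtered at
  correlation length `field_scale = 16 px`, standardized and
  exponentiated with log-SD `field_sd = 0.3`, multiplies the lipid
  amplitude per pixel — lipid-rich vs. protein-rich tissue regions with
  realistic patch structure.
- **Noise and saturation:** additive Gaussian noise (SD 0.05) per
  channel, clipping to [0, 4.0], and a 0.2% fraction of pixels forced to
  the ceiling in one random channel.

Randomness is split hierarchically (cohort → mouse → image) via
`SeedSequence` spawn keys, so adding a mouse or image leaves earlier data
bit-identical. The default cohort mirrors the one-image-per-mouse design:
8 WT vs. 10 KO mice, 128² px images (1024² accepted); a matched null
config sets the KO band set equal to WT. `leakage_demo_config` is a
separate demonstration cohort — zero genotype effect, strong mouse effect
(log-SD 0.5), 2 mice per genotype with 8 images each — built to show the
naive-CV inflation clearly.

What the generator does *not* emulate: CARS lineshapes (Lorentzian
resonances interfering with the non-resonant field), spectral dispersion
of the background, fibrosis or other morphology, vignetting, or
correlated detector noise. Passing tests therefore validate the analysis
machinery and its statistical behaviour under the assumed structure, not
instrument fidelity on real tissue.

## Numerical choices and edge cases

- On-disk cubes are float32 multi-page TIFFs (one page per channel, axis
  order) with a JSON sidecar holding the axis, metadata and the
  run-length-encoded saturation mask; writes are byte-stable. In memory,
  float64 is preserved where it arises (e.g., after down-sampling).
- Degenerate pixels (zero-norm spectra) and fully masked blocks are
  dropped and recorded via the cluster-map sentinel 255.
- k-means determinism: one RNG seeded per fit drives all restarts;
  `assign` breaks distance ties toward the lowest canonical index.
- Problem sizes in tests and the acceptance script (128² images, 10–20
  seed replicates, capped fit subsamples) are chosen as desk-scale
  defaults that leave the statistical conclusions unchanged; the full
  1024² path is exercised where dimensions themselves are the claim.

## Known limitations

- The linear two-anchor baseline under-corrects curved non-resonant
  backgrounds; `anchor_m` is configurable but the model family is fixed.
- Equal-prior LDA is inappropriate for strongly imbalanced cohorts if a
  single accuracy number is wanted; here per-class recalls are always
  reported.
- The bootstrap SD underestimates uncertainty for very few mice per
  genotype (resampling 2 mice with replacement has only 3 distinct
  outcomes).
- k-means with restarts can miss the global SSE optimum on adversarial
  instances (see above); with the default 10 restarts on real-size pooled
  data this is immaterial for the reported percentages.
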