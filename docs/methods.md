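# Methods

## Pipeline

Segmentation proceeds green channel → enhancement → Gabor maximum
response → percentile hysteresis → small-component removal → FOV
restriction.  Enhancement is applied *before* the Gabor bank: the
filter is linear, so flattening illumination and stretching vessel
contrast first is what makes the filter's fixed thresholds portable
across images.  (Applying enhancement to the response instead would be
almost a no-op here: monotone intensity remappings do not move
percentile-based thresholds.)

## Gabor bank

The DC-compensated complex kernel (see README for the formula) uses the
printed parameter set k_max = π/2 rad/px, λ = √2, σ = π/3, 60×60
kernels, eight orientations φ_u = πu/8, one scale.  Notes on numerics:

- The prefactor divides by σ rather than the conventional σ²; we keep
  it as specified since the global min–max rescale makes any constant
  prefactor immaterial.
- With σ = π/3 the Gaussian envelope has standard deviation
  σ/k_max ≈ 0.67 px.  At that sampling density the continuum identity
  "kernel sum = 0" picks up an aliasing residue: the discrete kernel
  sums are 2–5% of the kernel peak depending on orientation (the
  plane-wave alias at 2π − k_max is only ~2 envelope standard
  deviations out in frequency).  This is a property of the printed
  parameters, not of the implementation; it bounds the additive-offset
  invariance of the response at the same few-percent level.
- Orientation labelling: the wave vector of kernel u points along φ_u,
  so kernel u responds maximally to curvilinear structures *running
  along* φ_u + π/2.  Orientation-recovery tests therefore build lines
  whose normal is φ_u.  Test lines use a smooth Gaussian cross-profile:
  hard-edged rasterized lines at diagonal angles carry staircase
  harmonics that the very narrow envelope picks up, which says nothing
  about the bank itself.
- Convolution runs via FFT on a reflect-padded array and is checked
  against direct spatial convolution to 1e-6.  Reflect padding avoids
  spurious rim responses at image borders.

## Enhancement operators

**GCADW.**  Intensities are binned to 256 levels; the pdf is reweighted
as `pdf_max · ((pdf − pdf_min)/(pdf_max − pdf_min))^a` with a = 0.5
(the customary value in the adaptive-gamma-correction family; the
method itself does not pin one) and pdf_min/pdf_max taken over all
bins.  Level l maps to `l_max (l/l_max)^(1 − cdf_w(l))`, a monotone
curve lifting dark levels.  A perfectly flat histogram makes the
weighting 0/0; we fall back to the unweighted cdf, its no-weighting
limit.

**Homomorphic.**  `log(img + ε)` is filtered in the frequency domain by
`H = (γ_h − γ_l)(1 − exp(−k P²/P0²)) + γ_l` with γ_h = 0.8, γ_l = 0.6,
k = 1, and P0 defaulting to 0.05·min(H, W) frequency-index units, then
exponentiated and rescaled.  The exponent's sign/square are chosen so H
rises monotonically from the low-frequency gain to the high-frequency
gain, matching the stated roles of the two gains.  ε = 1/255 keeps the
log finite on black pixels.  The cutoff and steepness are free
parameters of the method; the defaults here are our choices.

**JEH.**  Each pixel is keyed by the pair (own 8-bit level, 8-bit level
of its 3×3 neighborhood mean, replicate padding).  The 2-D CDF of pair
counts maps a pair to `trunc((L−1)(CDF − CDF_min)/(MN−1))`, CDF_min
being the minimum CDF over pairs that occur.  Integer conversion
truncates toward zero — the convention that reproduces the published
worked value 72 for (CDF = 11, CDF_min = 1, MN = 36) exactly, where
round-half-up would give 73.

**Unsharp masking.**  `out = clip(img + k (img − G_σ img))` with
k ∈ [0.2, 0.7] (default 0.5) and Gaussian σ = 2 px.  The smoothing
kernel is unspecified in the method's source; Gaussian is the standard
choice and is configurable.

**Adaptive unsharp masking.**  Per-pixel gain
λ = λ_g(I)·λ_d(d), with λ_g = 0.5(1 + tanh(3 − 12(g − 0.5))) on the
intensity plane and λ_d = 0.5(1 + tanh(3 − 6(d − 0.5))) on the
max-normalized unsharp residual magnitude d.  The reading of the tanh
argument anchors the maximum slope at g = 0.5 (so λ_g(0.75) = 0.5
exactly).  The reconstruction `I' = clip(I + λ·residual)` with
channel-ratio recombination (each of R, G, B scaled by I'/I) preserves
hue without an HSI round trip; I = 0 pixels pass through.  Quality
measures: mean forward-difference gradient magnitude (zero differences
on the last row/column so N is the full pixel count), opponent-channel
colourfulness `sqrt(σ_RG² + σ_YB²) + 0.3·sqrt(μ_RG² + μ_YB²)` on the
[0, 1] scale, and 8-bit Shannon entropy.

**PSO unsharp masking.**  The search space is a symmetric 3×3 kernel
(centre, edge, corner weights, each in [−2, 2]) plus a gain in [0, 2]:
4 dimensions.  Fitness is the entropy (bits) of the clipped enhancement
minus β = 10 times the over-range ratio (fraction of pixels pushed
outside [0, 1] before clipping).  The optimizer is canonical
global-best PSO (w = 0.729, c1 = c2 = 1.49445, 30 particles, 100
iterations, positions clamped to bounds) — the method's published
description gives steps but no update equations, so the
constriction-equivalent standard is used.  One initial particle is
pinned at the identity spec (centre 1, gain 0), which turns "the tuned
result is at least as fit as no enhancement" from a heuristic
expectation into an invariant.  Everything is driven by one explicit
seed; identical seeds give bit-identical traces.  For colour input a
standalone HSV entry point enhances the V channel; the segmentation
pipeline applies the operator to the green channel directly, and for
uniformity every enhancement method in the pipeline runs on that single
channel (the adaptive variant treats the channel itself as intensity).

## Segmentation

Hysteresis thresholds are *percentiles of the in-FOV response* (defaults
92 and 75) rather than absolute values, so one default spans
differently scaled responses.  A pixel survives if it is ≥ the low
threshold and 8-connected through such pixels to one ≥ the high
threshold.  Cleaning removes components under 30 px (components of
exactly 30 px are kept).  Both operations are exactly reproduced by
breadth-first-search oracles in the tests.

## Phantoms — what they do and do not establish

The generator draws `n_trees` random-walk vessel trees (headings
perturbed by N(0, 0.12 rad) per 2-px step, two children per branch
point, widths decaying by 0.8 per level from 4 px roots), darkens the
red and green channels by `vessel_contrast` = 0.25 on vessel pixels,
multiplies all channels by a radial vignette of amplitude 0.3, and adds
per-channel Gaussian noise with σ = 0.02 before clipping.  Branch
length (40 steps at the root, shrinking 0.85× per level) is the one
free parameter not pinned elsewhere; it was fixed once so that default
phantoms carry a realistic 4–9% vessel load within the FOV.  The
vessel mask is the exact pre-noise rasterization; the FOV is the
centred disc of radius 0.48·min(H, W).

The phantoms exercise orientation selectivity, illumination falloff and
noise robustness.  They do **not** emulate the optic disc, fovea,
lesions, the central vessel reflex, camera PSFs, or — importantly — the
*low* vessel contrast-to-noise ratio of real fundus photographs: at the
defaults, vessel contrast (0.25) is 12× the noise σ.  A green pipeline
test on phantoms therefore establishes correctness and determinism, not
clinical-grade ranking of enhancement methods.  In particular, on these
high-SNR phantoms the plain Gabor baseline is near-optimal and
entropy-maximizing or equalization-based enhancement mostly amplifies
background noise, so the enhanced variants do not reproduce here the
accuracy ordering they show on real low-contrast data; percentile
thresholds are rank-based, so an enhancement can only change the
segmentation through the *selectivity* of the response, not its scale.

## Evaluation conventions

Counts are restricted to the FOV when a mask is supplied (full frame
otherwise).  Zero-denominator metrics are returned as NaN, excluded
from table averages rather than raising.  Table averages are unweighted
arithmetic means over images.  The under-/over-segmentation taxonomy
takes its high/low cuts as user parameters; the classification is
qualitative.

## Determinism

Every stochastic component (phantoms, PSO) takes an explicit seed.  The
experiment driver derives per-(method, image) sub-seeds by CRC-32 of
`"seed:method:index"`, so all methods see identical phantoms and each
cell is reproducible in isolation.
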