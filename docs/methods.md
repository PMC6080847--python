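# Methods

## The measurement

`fibralign` quantifies how well fibrillar structures in a 2D fluorescence
image (typically a maximum-intensity confocal projection of sub-epidermal
collagen) are aligned. Orientations are *axial*: a fibril at angle θ and
θ + 180° are the same object, so every angle lives in [0, 180) and all
circular arithmetic doubles the angles (period 360°) first.

The per-image pipeline is:

1. **Power spectrum.** The image is mean-subtracted (removing the DC
   spike), apodized with a separable Hann window (suppressing the
   cross-shaped artifact that the periodised image edges would otherwise
   inject along the axes), zero-padded to a square, Fourier transformed,
   and squared. The spectrum is scaled by 1/N<sub>pix</sub> so its sum
   equals the energy of the windowed image (Parseval), which the tests
   assert to 1e−6 relative.
2. **Angular histogram.** Spectral energy inside an annular band is
   accumulated into angular bins by the orientation of each frequency
   pixel. A fibril field at orientation θ concentrates energy along the
   *perpendicular* direction in frequency space, so a 90° rotation is
   applied here; the returned histogram is already in real-space fibril
   coordinates. Opposite half-planes are folded together (axial
   symmetry). Defaults: 90 bins of 2°, radial band 0.02–0.9 of Nyquist
   (the lower cut removes the low-frequency background blob, the upper
   cut removes corner anisotropy — diagonal frequencies above the axial
   Nyquist), each frequency pixel contributing its full energy to a
   single bin (bin width dominates the error; no interpolation).
3. **Background subtraction.** The minimum bin value is subtracted from
   every bin (clamped at ≥ 0). This removes the orientation-independent
   noise floor that would otherwise dilute the alignment index toward
   the uniform value. A percentile rule is available as an option; the
   minimum is the default because it is the simplest monotone floor
   estimate and never removes signal mass from the modal bin. A flat
   histogram becomes all-zero and is flagged degenerate.
4. **Range split.** The histogram is partitioned at 90°. Mature
   sub-epidermal collagen consists of two orthogonal fibril families;
   a single global AI would let them cancel (cos 2Δ at Δ = 90° is −1).
   Splitting lets each family be assessed by its own half-range. Bin
   edges must align with 90°, which any even bin count guarantees.
5. **Alignment index.** Per range, the mean orientation θ<sub>th</sub>
   is the doubled-angle circular mean ½·atan2(Σw sin 2θ, Σw cos 2θ),
   and

   AI = | Σ w<sub>i</sub> cos(2(θ<sub>i</sub> − θ<sub>th</sub>)) | / Σ w<sub>i</sub>

   using 2cos²x − 1 = cos 2x; bin centers are the θ<sub>i</sub> and bin
   values the weights. AI = 1 for zero angular dispersion, AI = 0 for a
   uniform full-range distribution (a 2D nematic order parameter). The
   per-image summary `ai_combined` is the mass-weighted mean of the two
   range AIs, which reduces to the single-family AI when one range is
   empty; `ai_dominant` (the heavier range's AI) is the single-family
   readout used in the concentration-sweep tests.

### The range pedestal

Restricting axial data to a 90°-wide range maps the doubled angles onto
a half-circle, whose mean resultant length is bounded below: *uniform*
orientations give a per-range AI of 2/π ≈ 0.637, not 0. The AI = 0 limit
holds only for the full-range statistic (and is tested there). All
range-split comparisons in this package are therefore relative — what
matters, and what the acceptance tests assert, is that the per-range AI
increases monotonically with the true orientation concentration and
tracks the same statistic computed on the ground-truth angles. Absolute
per-range AI values should not be compared against full-range values.

### θ<sub>th</sub> and degenerate inputs

θ<sub>th</sub> is computed within each range independently (each
orthogonal family assessed on its own). Zero total weight yields AI 0
with a degenerate flag and θ<sub>th</sub> = NaN — never a division
error. A numerically vanishing resultant (e.g. exactly balanced
orthogonal masses) returns the smaller-angle root flagged ambiguous.

## Synthetic fibril images

The generator draws straight segments whose centers are uniform in the
image and whose orientations come from an axial von Mises mixture:
doubled angles are drawn from VM(2μ, κ) and halved, so μ and μ + 180°
are identical and κ = 0 reduces exactly to the uniform distribution.
Rendering is additive anti-aliased capsules (length 60–140 px, thickness
2 px, amplitude 40–80 AU by default), a Gaussian PSF (σ = 1.2 px), a
flat background (8 AU), Gaussian read noise (σ = 3 AU) and optional
Poisson shot noise. The noise field is seeded independently of the
segment content, so scenes differing only inside a sub-region have
identical noise elsewhere — this is what makes the wound series
pixel-identical outside the wound across timepoints. Identical
parameters and seed reproduce every image bit-for-bit; there is no
hidden global random state.

**Developmental preset** (one image per stage, independent draws — no
time-evolution model): sparse isotropic wisps (60 fibrils, κ = 0), a
loose orthogonal cross-hatch (150 fibrils, two families κ = 3), a tight
one (260 fibrils, κ = 20). Fibril counts rise with stage because
deposition accumulates; the κ ladder sweeps the alignment knob. The
lattice families default to 45° and 135° — the centers of the two
half-ranges — so each family is assessed whole by its own range.
Families at 0°/90° would sit exactly on the split boundaries, be cut in
half, and self-cancel; μ is exposed for callers who want that stress
case.

**Wound preset**: an orthogonal lattice with a central disk denuded of
fibrils (radius 0.35 × image size by default). Per timepoint the disk
refills at a density fraction of the outside lattice with its own
orientation mixture: absent (1 dpi-like), half-density isotropic wisps
(5 dpi-like), denser loosely orthogonal (9 dpi-like), full-density tight
lattice (16 dpi-like, statistically indistinguishable from unwounded).
Analysis is restricted to the wound domain by cropping the inscribed
axis-aligned square of the disk — cropping rather than zero-masking, so
no mask-edge energy enters the spectrum. Unwounded controls are
same-size central crops of intact lattices drawn independently per
replicate.

What the generator does **not** emulate: curved or branching fibrils,
depth attenuation and scattering, multi-channel bleed-through, myosepta
and other anatomical structures, spatially correlated noise, and any
mechanistic deposition/remodelling dynamics. Passing tests therefore
demonstrate that the measurement chain recovers known orientation
structure under fluorescence-like rendering — not that real wounds
behave like the presets.

## Group statistics

Per-image AI values are compared between groups exactly as the
experimental designs require: mean ± sample SD (n−1) summaries; a
one-way ANOVA with Tukey's HSD family-wise comparisons across
developmental stages (scipy's `f_oneway` and `tukey_hsd`); two-sided
two-sample t-tests per timepoint for wounded vs unwounded. Welch's
unequal-variance t-test is the default (no variance-homogeneity
assumption), with the pooled form behind a flag. Significance stars
follow the ns / * / ** / *** / **** ladder at 0.05, 0.01, 0.001,
0.0001. The test suite checks calibration rather than trusting labels:
simulated type-I error of the t-test is 0.05 ± 0.02 over 2000 null
replicates, and Tukey's adjusted p never undercuts the raw pairwise p
of the same statistic.

## Problem sizes and determinism

Emulation checks run at sizes chosen to make the statistics decisive
while keeping a full suite run short: the concentration sweep uses
512-px images over κ ∈ {0, 1, 3, 10, 50} × 10 seeds; the developmental
emulation 20 replicate cohorts of 3 × 12 images at 384 px; the wound
emulation 20 runs of 8 wounds + 8 controls at two timepoints at 448 px.
Batch runs record a config hash and seed in their manifest and
re-running any configuration reproduces byte-identical CSV outputs.

## Known limitations

- The per-range AI pedestal (2/π for uniform content) means range-split
  values are not comparable to full-range values; comparisons are valid
  within a fixed analysis convention only.
- Histogram-based AI treats bin centers as measurements; with 2° bins
  the discretisation error is well below the biological effect sizes of
  interest but is not zero.
- Energy-weighted Fourier histograms weight thick/bright fibrils by
  their squared contrast, not one-fibril-one-vote; the ground-truth
  oracle path (`histogram_from_angles`) is the unweighted reference.
- No local (structure-tensor) orientation analysis; one histogram per
  image or crop.
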