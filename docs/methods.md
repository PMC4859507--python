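# Methods

This note records the models, conventions and open design choices behind
`fiberquant`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic benchmark does and
does not establish about real data.

## Myofiber segmentation

Laminin outlines every myofiber, so a transverse muscle section is a
tessellation whose cell boundaries fluoresce. The pipeline is:

optional Gaussian smoothing (`smoothing_sigma`, px; default 0) →
threshold (Otsu by default; a fixed value can be supplied, which is the
convention used for collagen) → boundary mask → **gap repair** →
inversion → 4-connected component labeling → area filter → removal of
border-touching components → consecutive relabeling.

Gap repair implements the shrink-then-expand idea: each enclosed area is
shrunk into a closed object and re-expanded to its original size, which
is exactly morphological closing of the *boundary* mask with a disk
(equivalently, opening of the interiors). A disk of radius *r* seals
boundary interruptions narrower than about 2*r* and leaves intact
interiors untouched except within ~*r* of sharp concavities. The default
radius is 4 px, matched to the ~5 px staining interruptions the
synthetic generator produces; real sections with wider tears need a
larger radius, at the cost of eroding acute fiber corners.

Design points:

- **4-connectivity for interiors** so fibers cannot leak into each other
  diagonally through a one-pixel boundary break.
- **Area filter** defaults 200–8000 µm², bracketing the usual TA fiber
  CSA range; it also disposes of junction slivers created by closing.
- **Border censoring**: fibers cut by the field of view have biased area
  and MFI and are removed outright rather than estimated.
- **Degenerate thresholds** (uniform image, all-foreground /
  all-background mask) raise an error naming the threshold instead of
  returning an empty map.
- Increasing the closing radius is *not* monotone in fiber count on
  gapped input: sealing a gap splits a merged interior in two, so counts
  rise toward the true count as the radius grows past the gap width. On
  gap-free input closing can only merge or erase regions, and counts are
  non-increasing; the property test covers that regime.

Nucleus segmentation (DAPI) is deliberately simple: Otsu → fill holes →
minimum-area filter → label. Touching nuclei count as one object; no
watershed splitting. Collagen is quantified as percent of field pixels
at or above one fixed threshold applied to all images.

## MFI normalization

Stage order is fixed: background → fluorophore → fiber sum. The order
matters; sum-normalizing before equalizing the channels would weight the
composition by arbitrary conjugate brightness.

- **Background** defaults to the per-channel median of non-fiber
  (label 0) pixels — robust to bright ECM speckle. Note that label 0 of a
  *segmentation-derived* map also contains the fibers the size/border
  filters rejected, which drags the median upward in densely packed
  fields; a fixed per-channel override is provided, and exactness tests
  use ground-truth maps whose label 0 is pure ECM. Corrected values are
  clamped at 0 (intensities are physical).
- **Fluorophore normalization** divides each MyHC channel by its mean
  over the section's fibers, making each channel's fiber mean 1. This is
  scale-free: multiplying any raster by any positive constant leaves all
  downstream fractions unchanged (tested as a property). Whether the
  original procedure used conjugate-specific calibration factors instead
  is unknowable; the section-mean convention is this package's main
  interpretive choice. A consequence worth knowing: because each
  muscle's channel means are forced to 1, *between-section* level shifts
  are absorbed, and rank tests comparing fractions across sections
  become conservative under the null (we observe ≈0 rejections instead
  of 5% when the null is run through this stage). Condition effects
  expressed as distribution-shape changes survive it.
- **Sum normalization** yields per-fiber compositional fractions that
  sum to 1 (within 1e-9). Fibers whose scaled channels sum to zero are
  flagged `zero_sum` and excluded from fraction analyses — fabricating a
  composition of NaNs-as-zeros would invent fiber types.
- **GFP positivity** is raw GFP MFI > k × GFP background, k = 2 by
  default; the threshold criterion is a package choice.

## Statistics

Two-group distribution comparisons use Kruskal–Wallis (equivalent to a
Wilcoxon rank-sum for k = 2 up to the chi-square approximation), with
average ranks for ties and the standard tie correction. Besides the
asymptotic p, an exhaustive-permutation p (feasible for pooled n ≲ 10)
and a Monte-Carlo permutation p (with add-one correction) are
implemented; the unit suite checks them against from-scratch
enumeration. All values identical gives H = 0, p = 1 by convention.

Co-expression uses Spearman ρ for all six unordered MyHC pairs per
muscle; a constant channel yields a *missing* ρ, never 0 — zero would
fabricate evidence of no association. Condition-level changes are paired
t-tests on per-mouse ρ differences (knockdown − control), requiring at
least two usable pairs. No multiple-testing correction is applied across
the six pairs, mirroring per-pair reporting; callers can apply Holm
externally. Degenerate t-tests are explicit: all differences zero →
t = 0, p = 1; constant nonzero differences → an "exact-difference
report" (infinite t, note attached) rather than a silent NaN.

Fiber-level analyses pool fibers per condition across mice (with >400
fibers per muscle, per-mouse floors are comfortably met); per-mouse
analysis remains possible since the fiber table carries mouse ids.

## qPCR model

Exact doubling per cycle (100% amplification efficiency) is assumed
throughout; no efficiency calibration from dilution series is attempted.
Replicate Cts are averaged before any ΔCt. Relative expression uses one
housekeeping reference or the mean of several (e.g. Gapdh + Hprt). Fold
change is computed per contralateral pair; the cohort summary is the
**geometric mean** of per-mouse folds — folds are multiplicative, the
paired test runs on log2 folds, and the geometric mean is
median-unbiased on the log scale, whereas the arithmetic mean (also
reported) carries a Jensen bias of ~1–2% at 0.2-cycle Ct noise.

Distal-PAS utilization is `2^−(Ct_distal − Ct_proximal)`; since the
proximal set amplifies all isoforms this is the distal/total fraction.
Under noise the estimate can exceed 1 and is reported as-is — clipping
at 1 would bias paired deltas toward zero. Genes without an identified
proximal PAS (e.g. Murf1) carry only a gene-level primer set and no
utilization. Mice with milder knockdown are never auto-excluded;
subsetting is an explicit caller decision.

## Synthetic data

The generator emulates the data regime, not the optics (no PSF,
vignetting or 3D structure — listed non-goals):

- **Geometry**: seeds placed by dart throwing with minimum spacing one
  mean fiber radius, two Lloyd relaxation iterations, Voronoi
  assignment — convex, size-regular cells resembling TA cross-sections.
  Default 200 fibers in a 512 px field (~1300 µm² per cell at 1 µm/px).
  An impossible request (n·πr² exceeding the field) raises a placement
  error. Each truth fiber is pruned to its largest 4-connected piece so
  the truth map obeys the same connectivity as the segmentation output.
- **Boundaries**: ~3 px laminin ridges; gaps are punched out in
  contiguous runs (default 5 px) with a guard zone preventing adjacent
  runs from coalescing into wider tears, since run length is exactly the
  quantity the closing radius is calibrated against. A small Gaussian
  blur (0.5 px) softens the ridge; exactness tests switch it off along
  with noise.
- **Intensities**: each fiber draws a type (IIb/IIx/IIa/I) from mixing
  fractions and a 4-channel composition = type mean + correlated
  Gaussian jitter clipped at 0; channel rasters are background +
  amplitude × gain × composition + Gaussian noise, with distinct
  per-channel gains so the fluorophore stage has real work to do. The
  control profile is a fast TA (≈56/36/6/2% IIb/IIx/IIa/I) with strong
  negative 2b–2x jitter correlation; the knockdown profile shifts mixing
  toward IIx (≈33/51/11/5), flattens type means toward co-expression and
  decorrelates the jitter — producing the fast-to-slow transition
  (2b fractions down, 2x up) and weakened co-expression correlations at
  the cohort sizes used (3 mice/arm, ≥1000 fibers/arm).
- **Other channels**: one nucleus per fiber (peripheral, or central for
  a configurable fraction), a binary GFP transduction channel, a probe
  channel multiplied by `probe_effect` in GFP-positive fibers, and a
  collagen ridge along the ECM.
- **qPCR**: Ct = base Ct (20 targets / 18 housekeeping) − log2(expression)
  + per-sample input effect + replicate noise. The input effect is shared
  by all genes of a sample, so housekeeping normalization cancels it
  exactly — which also makes the recovered fold ratio invariant to the
  reference-gene choice (tested).

Everything is driven by one `numpy` Generator per spec seed with a fixed
channel order, so identical spec + seed reproduces byte-identical
rasters and tables.

**What passing tests show — and don't.** Exact recovery on noiseless,
gap-free mosaics validates the bookkeeping (thresholding, labeling,
means, normalization algebra), and the gapped benchmark validates the
repair step against its intended failure mode. Real cryosections add
uneven illumination, antibody penetration gradients, genuinely
non-convex and split fibers, freezing artifacts and out-of-focus light;
none of these are modeled, so the synthetic match rates are an upper
bound on real-world performance, not an estimate of it.

## Problem sizes

Defaults keep the full suite and the acceptance script within minutes on
a single CPU: 512–640 px fields with 200–450 fibers, 10 sections for the
recovery benchmark, 3 mice × 2 conditions for the transition cohort,
1000 draws of 200-fiber arms for null calibration, and 200 simulated
plates (5 mice × 3 replicates) for fold-change recovery. All are
package choices and scale linearly if increased.
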