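# fiberquant

Quantitative muscle immunohistology and qPCR analytics for paired
knockdown experiments in mouse skeletal muscle.

When PABPN1 — a regulator of 3'-UTR polyadenylation-site (PAS) choice —
is knocked down in one tibialis anterior while the contralateral muscle
receives a scramble control, the readouts are histological (myofiber
cross-sectional area, extracellular-matrix collagen, MyHC fiber-type
composition, nuclear proteasome-probe intensity) and molecular (ΔΔCt
fold changes and distal-PAS utilization from paired qPCR plates). This
package implements that entire quantification chain, plus a synthetic
generator of muscle sections and qPCR plates with known ground truth so
every stage is testable without any microscope or cycler.

## What it computes

**Segmentation.** The laminin immunofluorescence image is thresholded to
a fiber-boundary mask; broken contours are repaired by a shrink/expand
step (morphological closing of the boundary with a disk of radius *r*,
which seals gaps narrower than ≈ 2*r* while leaving intact objects at
their original size); the mask is inverted and connected interior
regions become myofibers, size-filtered and censored at the image
border. CSA is pixel count × pixel size².

**Fiber typing.** Per-fiber mean fluorescence intensity (MFI) of the
four MyHC isotype channels (2b, 2x, 2a, 1) passes through three stages:

1. background correction: `corrected = max(raw − bg, 0)` with `bg` the
   median intensity of non-fiber pixels;
2. fluorophore normalization: `scaled_c = corrected_c / mean_fibers(corrected_c)`,
   removing conjugate-brightness differences between antibodies;
3. per-fiber sum normalization: `frac_c = scaled_c / Σ_c' scaled_c'`,
   a compositional fraction per isotype (Σ frac = 1).

**Statistics.** Fiber-type distributions are compared between arms with
the Kruskal–Wallis rank test (tie-corrected H, chi-square p; exact and
Monte-Carlo permutation nulls available); co-expression between isotypes
with Spearman rank correlations per muscle, and condition-level changes
with paired t-tests on per-mouse ρ differences. Sorted MFI profiles
(2b descending, 2x ascending) and ECDFs reproduce the standard
distribution plots.

**qPCR.** Exact-doubling ΔΔCt throughout: relative expression
`2^−(Ct_gene − Ct_ref)` against one or several housekeeping genes, per-mouse
fold changes summarized by their geometric mean with a paired t-test on
log2 folds, and distal-PAS utilization `2^−(Ct_distal − Ct_proximal)` —
the proximal primer set amplifies all transcript isoforms, so the ratio
is the distal/total fraction.

## Worked example

```python
import fiberquant as fq
from fiberquant import stats, qpcr, synth
from fiberquant.design import generate_cohort

spec = fq.SectionSpec(n_fibers=200, field_size=512, gap_fraction=0.1, seed=42)
section, truth = fq.generate_section(spec)
labels = fq.segment_fibers(section[fq.LAMININ], fq.SegmentationParams(closing_radius=4))
print(f"segmented {labels.n_fibers} fibers (truth: {truth.true_label_map.n_fibers})")

table = fq.fiber_table_pipeline(section, labels, gfp_channel=fq.GFP)
print(f"median CSA: {table['csa_um2'].median():.0f} um^2, "
      f"GFP+ fibers: {int(table['gfp_positive'].sum())}/{len(table)}")
cm = stats.spearman_matrix(table)
print(f"Spearman rho(2b, 2x) = {cm.value('myhc_2b', 'myhc_2x'):+.3f} over {cm.n_fibers} fibers")

design = generate_cohort(5)
plate = synth.generate_qpcr(
    synth.QpcrSpec(genes=synth.default_qpcr_genes(), ct_noise_sd=0.2, seed=42), design)
fc = qpcr.fold_change(qpcr.relative_expression(plate, "Atrogin1", ["Hprt"]), design)
shift = qpcr.pas_change(qpcr.pas_utilization_table(plate, "Atrogin1"), design, "Atrogin1")
print(f"Atrogin1 fold change (shPab/Scram): {fc.mean_fold:.2f}, p = {fc.test.p_value:.4f}")
print(f"distal PAS utilization delta: {shift.mean_delta:+.3f}, p = {shift.test.p_value:.2e}")
```

prints

```
segmented 147 fibers (truth: 200)
median CSA: 1019 um^2, GFP+ fibers: 103/147
Spearman rho(2b, 2x) = -0.638 over 147 fibers
Atrogin1 fold change (shPab/Scram): 1.42, p = 0.0062
distal PAS utilization delta: -0.337, p = 8.81e-04
```

147 of 200 fibers survive because border-touching fibers are censored
(their area and MFI would be biased) and the size filter removes
fragments. The strong negative ρ(2b, 2x) is the co-expression signature
of a control fast muscle: the more 2b a fiber expresses, the less 2x.
The qPCR plate was generated with a true Atrogin-1 fold change of 1.6
and a utilization drop of 0.7 → 0.4; at Ct noise 0.2 cycles and five
mice the estimates land near those truths with significant paired tests.

A CLI wraps the same pipeline (`fiberquant simulate | segment | quantify |
stats | qpcr | run-histology | run-qpcr`), driven by a YAML config;
each output bundle carries a manifest (config hash, seed, versions) and
reruns with the same config and seed are byte-identical.

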