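# Methods notes

This note records the models, parameter choices and numerical conventions
behind `mitopla`, and what the synthetic benchmarks do and do not establish
about behaviour on real data.

## 1. Synthetic acquisition model

The generator emulates an automated widefield acquisition: a pre-defined xy
grid of fields (default 60; a typical single well grid is 15), each field a
10-plane z-stack in three wavelengths (DAPI, FITC, TRITC), rendered at
256×256 px with 0.34 µm pixels and written as 16-bit with saturation
clipping. Absolute intensity scales in fluorescence microscopy are
arbitrary; the generator therefore fixes plausible camera-unit scales once
and the analysis relies only on the *contrasts* between classes:

| structure | channel | shape model | peak intensity (a.u.) |
|---|---|---|---|
| interphase nucleus | DAPI | ellipse, axis ratio 0.85–1.0, r 14–20 px | 2500–3500 |
| mitotic chromosomes | DAPI | union of 3–5 ellipses, ratio 0.35–0.55, offset 0.5–0.9·r | 6500–9500 |
| spindle | FITC | ellipse, a 16–22 px, ratio 0.45–0.65 | 5000–7000 |
| cytoplasm (interphase) | FITC | 1.9× nucleus ellipse | 400 |
| PLA punctum | TRITC | Gaussian spot, σ 1.2 px | lognormal, mean 4000, σ_log 0.4 |

The mitotic/interphase contrast (brighter, less round chromosome masses) is
the premise of the classifier; over 1000 simulated cells the two DAPI
classes are separable by a single intensity/circularity threshold pair with
zero overlap under the defaults (the test requires ≤ 5%).

**Puncta statistics.** Mitotic cells carry Poisson(20) puncta in the control
condition, placed 60% on the spindle, 25% on the chromosome periphery and
15% in the cytoplasm; interphase cells carry Poisson(1.5) puncta
(nucleus/cytoplasm). The importazole (IPZ) condition divides the mitotic
Poisson mean by `ipz_puncta_fold_reduction` (default 5, i.e. ≥ 4-fold) and
leaves placement unchanged — the treatment disrupts the interaction, not the
cell geometry.

**Optics and noise.** Extended structures are drawn at peak intensity with a
1.5 px soft edge, then propagated along z with a Gaussian axial profile
(σ = 2.2 planes) and defocus blur growing linearly with distance from the
field's focal plane (0.6 px + 0.45 px/plane). Each punctum carries its full
integrated intensity at a single in-focus plane as a discretely normalised
Gaussian, plus faint blurred ghosts on adjacent planes; plane weights are
normalised so total rendered flux equals the punctum's integrated intensity
exactly, and ≥ 99.5% of it survives the maximum-intensity projection. Noise
is signal-dependent Poisson plus Gaussian read noise (sd 10). There is no
optics-accurate PSF, no chromatic aberration and no 3-D deconvolution ground
truth; the stack is only ever consumed through its projection, so a
MIP-adequate rendering is sufficient and deliberate.

**What the generator does not emulate:** spatial illumination gradients,
field-to-field focus drift beyond ±0.5 plane, touching/overlapping cells
(placement enforces a 50 px centre distance), debris and staining artefacts,
and cell-cycle stages other than a binary interphase/mitotic state. Passing
benchmarks therefore demonstrates the pipeline's correctness and its
behaviour under the stated noise model, not robustness to every failure mode
of real slides; the thresholds are exposed in the config for recalibration
on real data.

## 2. Imaging pipeline choices

* **Order:** projection → background subtraction → segmentation →
  classification → measurement.
* **Background:** default is percentile subtraction at q = 85 per channel.
  With a dark-dominated PLA channel the 85th percentile sits ~1 noise-sd
  above the true background, and the subsequent zero-clip removes most of
  the residual-noise floor that otherwise inflates small per-cell sums (the
  floor drops from ~6% to ~1% of a typical control-cell signal). Constant
  and rolling-ball backgrounds are available; q = 50 behaves classically
  when unbiased levels matter more than small-sum fidelity.
* **Thresholds:** default intensity thresholds are fixed values stored in
  the config (DAPI 1200 a.u., FITC 2200 a.u. after subtraction), mirroring
  the save-and-reload threshold workflow of interactive acquisition
  software; Otsu and upper-multi-Otsu auto-thresholds are available as
  overrides. Per-field Otsu is *not* the default because in asynchronous
  fields the FITC channel contains no spindle and Otsu then splits
  background from cytoplasm, producing spurious round "spindles".
* **Connectivity and shape:** 8-connected components; circularity
  4πA/P² with scikit-image's contour-length perimeter (diagonal-corrected),
  clamped at 1. Rasterised disks of r ≥ 10 px measure ≥ 0.9; 5:1 bars < 0.6.
* **Classification:** mitotic iff mean DAPI intensity ≥ 4000 a.u. AND
  circularity ≤ 0.95, or pH3 overlap ≥ 25% of the object. The two cut-offs
  were calibrated once on the generator defaults (measured interphase means
  2200–3100 vs mitotic 4900–6900; interphase circularity ≥ 0.89 vs mitotic
  mostly ≤ 0.87) and sit in the gaps. Spindle linking: nearest unassigned
  spindle centroid within 1.5× mean spindle major axis; exact distance ties
  break to the lowest label and are logged.
* **Measurement:** sum intensity over the selected mask of the
  background-subtracted PLA channel (raw-pixel measurement is available via
  `measure_on_subtracted=False`); default selection for mitotic cells is
  chromosomes ∪ linked spindle, for interphase cells the nucleus. Sum
  intensity over a non-negative image is monotone under mask inclusion and
  additive over disjoint masks by construction.
* **Evaluation:** "coverage" is matched detections over true objects and
  "precision" is matched detections over all detections (one-to-one greedy
  centroid-distance assignment among centroid-in-truth-shape candidates,
  class- and field-aware). We interpret the companion figure-of-merit of
  segmentation quality ("confidence") as precision, i.e. 100 minus the
  false-positive fraction among detections; a per-object classifier score
  would be an alternative reading.

## 3. Condition comparison

`compare_conditions` is a two-sided Mann-Whitney U test with three regimes:
full enumeration of all C(n1+n2, n1) rank assignments (tie-safe via
midranks) whenever that count is ≤ 20 000 — this regime *is* the exact
definition, and doubles as the reference the other paths are tested
against; scipy's exact recurrence when min(n) ≤ 8 without ties; and the
tie-corrected normal approximation otherwise. p-values are clipped into
(0, 1]. Significance stars follow the 0.05/0.01/0.001/0.0001 convention
(**** below 1e-4).

## 4. Interactome post-processing

* **Filter ledger:** rules run in the fixed order contaminant, reverse,
  unique peptides ≤ 0, peptides ≤ 1, only-by-site, MS/MS < 3, multi-gene;
  a row is charged to the first rule it violates, so sequential counts sum
  exactly to input − survivors. Because the order is a convention, marginal
  (independent) counts are reported alongside. "Multi-gene" is any
  ";"-separated gene-name field. The unique ≤ 0 and peptides ≤ 1 rules
  overlap by design; both are kept and applied in that order.
* **Enrichment:** Welch's two-sample t-test on log2 intensities — the
  standard workflow of label-free interactome software — with zeros treated
  as missing and, by default, imputed from a down-shifted normal
  (shift 1.8·sd, width 0.3·sd of the observed global log2 distribution,
  seeded generator, imputation recorded per row). With no missing data and
  equal variances the statistic reduces to the classical two-sample t. The
  hit rule is raw p < 0.05 AND positive log2 fold change, matching the
  original workflow's raw-p convention; Benjamini–Hochberg q-values are
  computed for users who prefer FDR control. A complete-case mode skips
  (with a warning) groups having fewer than two valid values per side.
* **Annotation:** percentages are over the annotated subset; an empty hit
  list yields an empty summary rather than a division error; conflicting
  duplicate annotations raise an error naming the genes.
* **Fixture realism:** planted true interactors are log2-enriched in bait
  (N(4, 0.5) by default) and *depleted* ~3 log2 units in IgG, where they
  also go missing at rate 0.3 — missing-not-at-random, as in real co-IP
  data, and the regime the down-shifted imputation is designed for. Each
  violator class in the fixture breaks exactly one filter rule so planted
  counts reconcile with the sequential report.

## 5. Degenerate inputs and tie-breaks

Empty images segment to zero objects; empty hit lists and all-disabled
pipeline stages are valid; cells that cannot be placed raise an explicit
`PlacementError` rather than silently truncating; requesting a spindle
measurement on an interphase cell raises `SelectionError`; a zero-variance
enrichment comparison reports p = 1 (non-hit) instead of NaN. All
randomness flows from explicit integer seeds; identical parameters and
seeds reproduce scenes, stacks and tables byte-for-byte.

## 6. Benchmark problem sizes

The shipped benchmarks run 15-field scenes (the size of one acquisition-grid
well) at 3 seeds per condition for segmentation scoring, 64/52-field scenes
for the 190-vs-150-cell condition comparison, and 15-field scene pairs at
3 seeds for fold-reduction recovery; protein-group fixtures use 200–300
background groups with 40–50 planted interactors at 3 vs 3 replicates.
These sizes give stable statistics (medians over ≥ 60 cells, sensitivity
over ≥ 40 planted rows) while keeping a full run around a minute on one CPU.
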