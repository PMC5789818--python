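# mitopla

Automated quantification of **in-situ proximity ligation assays (is-PLA)** in
mitotic cells, plus post-processing of **bait-vs-IgG co-immunoprecipitation
(AP-MS) interactomes** — the two computational legs of a three-step workflow
for profiling the mitotic interactors of a nuclear-transport receptor such as
importin beta-1.

## Who this is for

Labs that image PLA reactions on automated microscopes (multi-field,
multi-channel z-stacks: DAPI for DNA, FITC for tubulin or phospho-H3, TRITC
for the PLA product) and want a scriptable, testable replacement for
interactive segment-and-measure software; and labs that receive MaxQuant-style
`proteinGroups` tables from bait vs IgG pull-downs and need a reproducible
confidence-filtering and enrichment ledger.

Because raw acquisitions of this kind are rarely deposited, the package ships
a first-class **synthetic-data module** that generates ground-truthed
acquisitions (interphase nuclei, mitotic chromosome masses, spindles, PLA
puncta, an importazole-treated condition) and fixture protein-group tables
with planted truth, so every stage of the pipeline is benchmarked end to end
without any download.

## The method

**Imaging leg.** Each field's z-stack is reduced to a maximum-intensity
projection (per pixel, per channel: max over z), background-subtracted, and
segmented per category by intensity threshold plus size and circularity
windows, with circularity

    C = 4πA / P²   (clamped to 1; P from the contour-length estimator
                    with diagonal correction)

A DAPI object is called **mitotic** iff its mean intensity exceeds a floor
*and* its circularity is below a ceiling (condensed chromosomes are brighter
and less round than interphase nuclei), or it overlaps a pH3-positive mask;
each mitotic object is linked to the nearest spindle mask within 1.5× the
mean spindle major axis. The per-cell PLA readout is the **sum intensity** of
the TRITC channel inside the selected mask (default: chromosomes ∪ linked
spindle). Segmentation is scored against ground truth as coverage
(100·matched/true objects) and precision (100·matched/detections) with
centroid-in-mask matching. Control vs importazole conditions are compared
with a two-sided **Mann-Whitney U test** (exact null distribution whenever
affordable, tie-corrected normal approximation otherwise).

**Interactome leg.** `proteinGroups` rows are filtered sequentially:
potential contaminants → reverse-decoy hits → unique peptides ≤ 0 →
peptides ≤ 1 → only-identified-by-site → MS/MS count < 3 → multi-gene
association; the report reconciles exactly (input = Σ removals + survivors)
and also lists marginal per-rule counts. Survivors are tested for bait
enrichment with **Welch's t-test on log2 intensities** (zeros = missing;
missing values imputed from a down-shifted normal, shift 1.8·sd and width
0.3·sd of the observed log2 intensities, seeded); a hit requires p < 0.05
and positive log2 fold change (Benjamini–Hochberg q-values are reported as
well). Hits are finally cross-tabulated against a Mitocheck-like
gene → phenotype table, with percentages over the annotated subset.

## Worked example

```python
import dataclasses
from mitopla import (SceneParams, ImagingParams, generate_scene, analyze_stack,
                     evaluate_segmentation, compare_conditions, significance_stars)

ctr = SceneParams(field_grid_count=10, mitotic_fraction=0.5, condition="CTR", rng_seed=1)
ipz = dataclasses.replace(ctr, condition="IPZ", rng_seed=2)

scene, stack = generate_scene(ctr)            # ground truth + rendered z-stacks
analysis = analyze_stack(stack, ImagingParams())
ev = evaluate_segmentation(analysis.detections, scene)
print(f"coverage {ev.coverage_pct:.1f}%  precision {ev.precision_pct:.1f}%")

_, ipz_stack = generate_scene(ipz)
ipz_analysis = analyze_stack(ipz_stack, ImagingParams())
res = compare_conditions(analysis.mitotic_sums(), ipz_analysis.mitotic_sums())
print(f"CTR median {res.median_ctr:.0f} a.u. vs IPZ median {res.median_ipz:.0f} a.u. "
      f"(n={res.n_ctr}/{res.n_ipz}); Mann-Whitney p={res.p_value:.2g} "
      f"{significance_stars(res.p_value)}")
```

prints

```
coverage 95.0%  precision 94.3%
CTR median 34207 a.u. vs IPZ median 6424 a.u. (n=43/32); Mann-Whitney p=8.6e-12 ****
```

i.e. 95% of the true structures (nuclei, chromosome masses, spindles) were
detected with 94% precision, and the importazole treatment collapses the
per-cell PLA sum intensity of mitotic cells ~5-fold, a difference the
Mann-Whitney test calls at four-star significance.

The same pipeline is available from the shell:

```bash
mitopla init-config            # emit mitopla.yaml with all defaults
mitopla run -c mitopla.yaml -o out --seed 1
mitopla report -d out
```

plus per-step commands (`simulate`, `project`, `segment`, `classify`,
`quantify`, `evaluate`, `compare`, `filter-pg`, `enrich`, `annotate`) that
exchange TIFF masks and TSV/JSON tables.

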