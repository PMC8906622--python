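# Methods

This note records the models implemented in `omivec`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Design and data model

All analyses operate on `FeatureTable` objects: samples × features matrices
of finite non-negative reals (counts for the OTU layer, concentrations or
expression levels otherwise), with each sample assigned to one *condition*
— a (strain, day, arm) cell of the 2-strain × {0, 7, 15}-day ×
{control, treated} design. Conditions are the unit of every statistic in
the package: centroids, distances, evenness values and correlations are all
computed per condition (n = 3 replicates by default). Replicates are
treated as independent samples; cage or animal structure is not modeled.

## Discriminant ordination

Samples are projected onto the top-2 axes of the multi-class Fisher
criterion: maximize `wᵀ S_b w / wᵀ S_w w`, with `S_b` the between-class and
`S_w` the pooled within-class covariance, solved as the generalized
eigenproblem `S_b w = λ (S_w)_reg w`. With 3 replicates per condition
against hundreds of features `S_w` is always singular, so it is shrunk
toward a scaled identity:

    (S_w)_reg = (1 − γ) S_w + γ (tr S_w / p) I

with γ estimated by Ledoit–Wolf on the within-class-centered data by
default (`shrinkage="auto"`), or set explicitly in [0, 1]. Features are
centered and unit-variance scaled first (metabolite concentrations span
orders of magnitude); constant features are left centered only.

Conventions that pin down an otherwise arbitrary solution:

- eigenvectors are normalized to `wᵀ (S_w)_reg w = 1` (the scale returned
  by the generalized symmetric eigensolver);
- each axis is flipped so its largest-magnitude loading is positive, making
  trajectories reproducible across runs and platforms;
- the explained discriminant ratio is each axis's share of the positive
  eigenvalue mass.

Ordination is fit per strain by default (each strain's six conditions),
matching the per-strain cluster plots the statistics were designed for; a
joint fit is just a different `groups` argument. Fewer than 3 groups cannot
define a 2D plane and are rejected, as is data with zero between-class
scatter. LDA is used purely as ordination; no classification accuracy is
computed.

A caveat found while testing: duplicating a feature column doubles that
feature's weight in both scatter matrices, so the projection is *not*
invariant to duplication even under shrinkage — the centroid distance
structure moves by a few percent. The test suite asserts boundedness of
this perturbation, not exact invariance.

## Vector statistics on the plane

- **Dissimilarity Coefficient** `r(p₁, p₂) = √((x₂−x₁)² + (y₂−y₁)²)`
  between condition centroids (centroids, not medoids, consistent with the
  mean geometry of LDA). Ratios of such distances compare progression
  between condition pairs and use unsigned distances.
- **Trajectory**: the centroid polyline over an ordered condition list;
  segment lengths are Dissimilarity Coefficients of consecutive centroids.
- **Disease Severity Index** `D = Σ ρₓ ρᵧ r_xy`. The sum runs over *all*
  cross-condition sample pairs (x in condition A, y in condition B); this
  reading makes D symmetric in A and B and reduces to the single-pair
  product ρₓ·ρᵧ·r_xy when each condition has one sample. ρ is the distance
  from "the center", which defaults to the grand mean of all embedded
  samples (a parameter, since other centers — e.g. the day-0 control
  centroid — are defensible). D is reported descriptively; no significance
  test is attached. Under uniform scaling of the plane by s about the
  center, D scales as s³; it is invariant to rotations about the center.
  Both properties, and equality with a brute-force double loop, are
  property-tested.

## Differential shortlisting

Per feature: Welch two-sample t-test on natural-log values, with zeros
replaced by half the smallest positive value in the table before logging;
Benjamini–Hochberg adjustment per contrast per layer; a feature is
*selected* iff adjusted p ≤ α (default 0.05) and the raw-scale fold change
passes the cutoff in either direction (FC ≥ 1.5 or ≤ 1/1.5, default 1.5).
Zero-variance features get p = 1. The log scale matches fold-change
semantics; the two-sided cutoff reflects that both up- and down-regulated
features are shortlisted. No moderated-variance (empirical-Bayes) testing
and no count-model differential abundance: metabolite concentrations and
normalized expression are the intended inputs.

## Microbiome and diversity

- **OTU filter**: keep an OTU iff its count is ≥ `min_count` (default 2)
  in at least ⌈prevalence × n_samples⌉ samples (default prevalence 0.20) —
  the MicrobiomeAnalyst-style reading of "minimum count + prevalence", with
  a ceiling on the sample threshold.
- **Total-sum scaling**: divide each sample by its total; all-zero samples
  are an error naming the sample.
- **Aggregation**: proportions summed within phylum/genus groups; features
  absent from the taxonomy aggregate into an explicit `unclassified`
  bucket; per-sample mass is conserved at 1 through the whole
  filter → scale → aggregate pipeline.
- **Evenness Index**: `E = −Σ_{p>0} p ln p`, i.e. unnormalized Shannon
  entropy, exactly as defined for this analysis; bounded by ln k. E is
  computed on the *pooled* (condition-mean) composition by default, giving
  one E per condition as plotted in such studies; a per-sample-then-average
  mode is available. Treated/control E ratios are reported per
  (strain, day). A Pielou-normalized variant (E / ln k) is deliberately not
  the default and not part of any reported statistic.

## Annotation analytics

Pro/anti ratio = n_pro / n_anti over a shortlist; when n_anti = 0 the ratio
is serialized as the explicit string `"undefined"` rather than infinity so
downstream consumers fail loudly. Overlap counts are exact set
cardinalities. The clinical disease-activity score sums three 0–4 grades:
weight-loss bands (< 1% → 0, 1–5 → 1, 5–10 → 2, 10–15 → 3, > 15 → 4,
applied to loss = max(0, −weight_change)), stool consistency and rectal
bleeding passed through; the rubric is a YAML config
(`omivec/data/default_rubric.yaml`), following the standard DSS
disease-activity-index convention, and is a convention rather than a
transcribed table. Block correlations (inflammation markers × phylum
abundances / metabolic-category scores) are computed at condition level
(12 conditions), Spearman by default given the tiny n, with BH adjustment
across all cells; constant inputs are reported as missing with a reason.
Category scores are per-category means of condition-mean log fold changes
against the same strain's day-0 control.

## Synthetic-data generator

The generator is the package's test bed and demo data source; its defaults
(in `omivec/data/default_calibration.yaml`) encode the study conditions.

**OTU counts** are Dirichlet-multinomial: per sample,
`p ~ Dirichlet(c · π_cond)`, `counts ~ Multinomial(depth, p)`, with
concentration c = 200 (moderate overdispersion, typical of 16S replicates;
`c = None` gives the exact-multinomial limit), depth 50,000, and each genus
split into 3 OTUs at fixed 0.6/0.3/0.1 within-genus ratios. The genus-level
composition profiles π encode the published kinetics: Proteobacteria
(Helicobacter) at 32% of total abundance in treated C57BL/6 at day 15 and
29% in treated BALB/c at day 7; Bacteroidetes/Firmicutes depressed under
treatment; Verrucomicrobia (Akkermansia) appearing only in the BALB/c
recovery phase. The taxon set also carries three minor phyla
(Actinobacteria, Tenericutes, Deferribacteres) whose collapse under
dysbiosis produces the evenness decline: with only the two dominant phyla
plus the bloom, raising Proteobacteria would *increase* phylum entropy, so
the minor-phylum collapse is what makes treated communities less even than
controls, as observed.

**Feature layers** (transcript, serum metabolite, cecal metabolite) are
log-normal: `value = exp(baseline + shift(label, condition) + N(0, σ))`,
with per-feature baselines drawn once per study and σ = 0.1 (≈ 10%
replicate CV — appropriate for inbred animals and quantified marker
panels, and required for the designed effects to be detectable at n = 3
with BH correction, as in the original study where substantial shortlists
were obtained at this group size). Shifts follow each strain's severity
trajectory (C57BL/6: 0 → 0.6 → 1.0 over days; BALB/c: 0 → 0.7 → 0.3):
pro-labeled features move up by `pro_max_log_fc × severity` (ln 4 for
transcripts, ln 3 for metabolites), anti-labeled down by
`anti_max_log_fc × severity` (ln 3 transcripts, ln 2 metabolites), neutral
features never move. BALB/c day-15 shifts are therefore deliberately small:
the strain recovers, and its late shortlists are expected to be sparse.

**Clinical records** tie stool/blood grades (round(4 × severity)) and
percent weight change (−18% at severity 1) to the same trajectory, with ±1
integer grade jitter clamped to 0–4 and gaussian weight noise (σ = 1%).

Randomness is one global seed split deterministically per layer and
condition (hash-derived child streams), so regenerating one layer never
perturbs another, and every simulator is bit-reproducible under a fixed
seed.

What the generator does *not* emulate: read-level 16S artifacts (chimeras,
primer bias, variable depth), compositional correlation between taxa beyond
the Dirichlet, feature–feature correlation within a layer, batch effects,
cage effects, or missing data. Passing tests therefore demonstrate that the
analysis recovers known structure under the stated generative assumptions —
not that it is robust to every artifact of real multi-omics data.

## Pipeline and reproducibility

`omivec run` executes simulate → shortlist → project → vector stats →
microbiome → annotation as file-based stages (plain TSV only), with
per-stage contrasts of each treated day against the strain's day-0 control.
A content-addressed stage state (`stage_state.json`) records config, input
and output checksums; a stage re-runs only when any of these changed, so
deleting one stage's outputs regenerates just that stage (and dependents
whose inputs actually change — with a fixed seed, regenerated outputs are
identical, so dependents are reused). `manifest.json` echoes the config,
seed, software version and per-stage checksums; it intentionally contains
no wall-clock timestamps, so identical config + seed yields byte-identical
manifests. Timing goes to the log.

Default problem sizes — 120 transcripts, 2 × 40 metabolites, 24 OTUs,
36 samples per layer, depth 50,000, and 50 replicate datasets in the
composition-recovery script — were chosen so the full pipeline and every
recovery analysis complete in seconds while keeping Monte-Carlo standard
errors well below the effects being recovered.

## Known limitations

- The Disease Severity Index's pair set and center are conventions (see
  above); both are recorded in outputs so alternative readings can be
  compared, but only the implemented reading is computed.
- Shrinkage LDA coordinates depend on γ; comparisons across runs should
  hold γ fixed (or use the deterministic "auto" estimate on the same data).
- Evenness on pooled compositions hides replicate variance; the per-sample
  mode exists but treated/control ratios of pooled E are the reported
  statistic.
- The clinical rubric's stool/blood grade semantics are conventions of the
  DSS disease-activity literature, configurable via YAML.
- Correlation analytics at 12 conditions have little power; they are
  descriptive, mirroring the scale of the study they serve.
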