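# Methods

This note documents the models and procedures implemented in `nichepart`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Ecological distribution metrics

Inputs are condensed taxonomic profiles: one row per (metagenomic dataset,
taxon lineage) carrying a relative-abundance percentage, plus a map from
dataset accession to one of seven habitat categories (soil, engineered,
freshwater, host-associated, marine, non-marine saline and alkaline,
terrestrial non-soil). Lineages are GTDB-style rank-prefixed strings from
domain to genus; ranks must be resolved left-to-right.

**Detection** is any strictly positive relative abundance; zeros and
missing rows are equivalent, and zero rows are dropped at load time. For a
taxon and habitat with `n` datasets of which `d` contain the taxon:

- **ubiquity** = 100 · d / n (undefined, not zero, when the habitat has no
  datasets);
- **preference ratio** = soil ubiquity / pooled non-soil ubiquity, where
  the non-soil pool sums detections and datasets over the five non-host
  non-soil habitats — never an average of per-habitat percentages.
  Host-associated datasets are excluded from all soil-vs-non-soil
  comparative fields because of their extreme overrepresentation in public
  archives (but are counted in habitat-breadth analyses);
- **mean relative abundance** is averaged over the datasets in which the
  taxon is *detected*. Whether reported abundance should be
  detection-conditional or averaged over all datasets is genuinely
  ambiguous for this kind of corpus summary; the detection-conditional
  reading is the default and `compute_metrics(...,
  detection_conditional_abundance=False)` switches to the
  absences-as-zero alternative.

Abundances are percentages and are never renormalised per dataset: a
profile queries only some taxa, so rows need not sum to 100.

### Soil-preference classification

Strict (`>`, not `≥`) cutoffs, all configurable:

| criterion | call | cutoff |
|---|---|---|
| soil ubiquity | ubiquitous | > 75 % |
| soil / non-soil ubiquity ratio | soil-preferring | > 4 |
| soil / non-soil mean-abundance ratio | soil-enriched | > 1 |

A lineage passing all three is summarised **SPL** (soil-preferring
lineage); failing all three, **NSPL**; any mixture is *intermediate*. The
narrative definitions blend the three criteria, so all component calls are
always reported alongside the summary. A separate `abundant_in_soil` flag
records whether soil mean abundance exceeds 1 % (the "abundant" cutoff);
it does not enter the summary. Taxa detected in fewer than 250 studies are
summarised *rare* regardless of component calls. A zero non-soil
denominator with a positive soil signal yields ratio +inf with a
`denominator-zero` flag rather than a dropped taxon.

### Habitat breadth

Profile-based: a taxon is a **generalist** when detected in all seven
habitat categories (host-associated included), otherwise a specialist;
taxa with fewer than 250 total detections are reported `rare-excluded`,
with the unfiltered call alongside, since rarely seen taxa are easily
mis-called specialists. Genome-based: a taxon is a generalist when its
genome representatives originate from ≥ 2 habitat categories; taxa with
fewer than 5 genomes are `rare-excluded`. The two routes use different
thresholds by construction, so cross-checks compare the per-taxon habitat
counts, not the calls.

## Genome feature table

One row per genome: accession, taxonomic class, habitat of origin and 14
analysis features — 5 general (genome size, GC %, coding density, mean
gene length, protein count), 2 phage-related (CRISPR count, viral-contig
count), 3 secretory (CAZyme, peptidase, BGC counts), 3 physiological
predictions (optimal growth temperature °C, pH, oxygen preference) and the
life-history strategy. All upstream annotation and prediction tools are
out of scope; their outputs are consumed as tables. The comparison filter
keeps classes with ≥ 100 genomes originating from ≥ 5 of the 7 habitats
and emits a per-class audit with both reasons, because how exclusions
split between the two criteria is worth inspecting per dataset. Missing
feature values are retained as markers and excluded pairwise (per feature)
downstream, maximising per-feature n as per-feature tests imply; the
binary metabolic-trait matrix (0/1 pathway presence) rides alongside.

## Variance partition

### Continuous features: two-factor type III ANOVA

The model is `y ~ class + habitat + class:habitat` under **sum-to-zero
contrasts** (required for interpretable type III tests with an
interaction; mirrors the R `car::Anova` convention). Aliased columns are
dropped in term order — intercept, main effects, interaction — exactly as
`lm` drops aliased coefficients, so designs with empty class × habitat
cells fit cleanly; the lost interaction degrees of freedom are reported,
never silently imputed. Each term's SS is then the increase in residual SS
when that term's surviving columns are removed from the full model;
F = (SS/df)/(SS_res/df_res) with p from the F distribution.

**Percentage contribution** of a term defaults to
100 · SS_term / (Σ term SS + residual SS); the denominator is declared in
the result and switchable to explained-SS-only. Significance tiers follow
fixed cutoffs — *strong*: p < 1e-5; *weak*: 1e-5 ≤ p < 0.05 — with no
multiplicity correction by design; an informational Benjamini–Hochberg
column is provided in batch output. A feature is *lineage-specific* when
its class term is strong, *habitat-specific* when its habitat term is
strong, *both* or *neither* otherwise.

The two categorical analysis features run through the same machinery:
oxygen preference is 0/1-encoded; the 3-level life-history strategy is
analysed as one-vs-rest indicators with the maximum-class-SS indicator
reported. A chi-square/multinomial treatment would be an equally
defensible reading; the 0/1 route keeps the 14-feature batch homogeneous
and is the one implemented.

**A caution for severely unbalanced designs.** With the interaction in the
model, the type III main-effect hypothesis concerns *unweighted* cell
means. On the default design — whose smallest non-empty cells hold a
single genome — those hypotheses have almost no information, and variance
genuinely attributable to a factor is attributed to no term. The
parameter-recovery study therefore uses a two-model protocol: the
**factorial** fit supplies significance tiers (main effects assessed in
the presence of interaction), and the **additive** fit supplies the
percentage contributions (the generating truth is additive, and the
additive partition is consistent for the planted shares). Both fits are
plain calls to `fit_type3_anova` with `include_interaction` toggled.

### Post hoc comparisons

`tukey_hsd` implements Tukey–Kramer adjusted pairwise mean comparisons
from the studentized-range distribution with pooled within-group variance;
with two groups it reduces exactly to the pooled two-sided t-test. Pairs
are computed for any factor whose ANOVA p is below 0.05.

### Binary traits: logistic partition

Each 0/1 trait is fit by maximum-likelihood logistic regression on class +
habitat (+ interaction where estimable; collinear columns are dropped by
pivoted QR). Model fit is summarised by **McFadden pseudo-R²**
= 1 − logL_full / logL_null, and the contribution of a variable is the
pseudo-R² drop when its main-effect and interaction columns are removed.
Term p-values are likelihood-ratio chi-square tests. Non-convergence or
divergent coefficients (|β| > 20, the symptom of complete separation) flag
the result as unreliable rather than reporting a silent number; no
penalisation is applied by default since the reference procedure is a
plain GLM. Whether the full model for the drops includes the interaction
is not prescribed; the default includes it when estimable, with a
main-effects-only switch (used by the recovery studies, whose planted
truth has no interaction).

## Life-history classification

Two investment indices summarise a genome's strategy:

- regulatory index = transcription factors / total genes;
- acquisition index = (secreted CAZymes + secreted proteases + secreted
  lipases/hydrolases + BGCs) / membrane transporters.

Zero denominators yield flagged, unassignable profiles. Secreted-enzyme
counts are inputs; signal-peptide prediction is upstream. A three-centroid
model (ruderal / competitor / scarcity) is trained by k-means (k = 3, ten
seeded restarts) on a labelled training table after per-axis z-scoring
fitted on the training set — the two indices differ by orders of
magnitude, so unscaled Euclidean distance would be dominated by the
acquisition axis; scaling is recorded in the model and switchable off.
Training rows are canonically sorted before fitting so the model is
invariant to input row order. Each centroid takes the majority label of
its members (ties broken by the nearest labelled point); the three labels
must come out distinct or training fails with a request for a cleaner
training set. New genomes are assigned to the nearest *fixed* trained
centroid (the predict semantics of centroid-based classifiers) rather than
re-clustered jointly, so assignments are stable as cohorts grow.
Equidistant points break ties in the fixed order competitor, ruderal,
scarcity and carry a tie flag.

The labelled 27-genome training table published alongside the original
life-history method is not shipped; `make_synthetic_training` generates a
synthetic stand-in with nine genomes per strategy drawn around planted
cluster centres (regulatory ≈ 0.010–0.055, acquisition ≈ 0.25–1.8), and
the real table is accepted in the same layout.

## Synthetic data

Generators are pure functions of (config, seed); one seed fans out into
per-component substreams.

- **Profiles**: per dataset and taxon, detection is
  Bernoulli(detection probability for the habitat); detected abundance is
  log-normal with configured mean and log-scale dispersion (right-skewed,
  as relative abundances are), truncated to (0, 100]. Datasets whose
  independent draws total above 100 % are rescaled to 100, since relative
  abundances cannot exceed the dataset. The default panel is 10 datasets
  per habitat × 5 taxa with planted soil-preferring, non-soil-preferring,
  generalist, single-habitat-specialist and rare structure.
- **Genomes**: continuous features are grand mean + class effect + habitat
  effect + interaction + Gaussian noise; binary features and traits are
  Bernoulli(inverse-logit of planted terms); life-history labels come from
  a planted mixture. The default design reproduces the unbalanced
  six-class × seven-habitat cell counts of the real comparative cohort
  (1930 genomes, nine empty cells), so empty-cell handling is exercised by
  default. A ground-truth record (effects, realised variance shares,
  labels) is emitted for recovery tests.
- **Planted variance shares**: `make_variance_recovery_config` scales a
  class-effect direction and a habitat-effect direction so their
  per-genome variances hit requested percentages of total variance
  (default 40 % class, 1 % habitat, residual SD √59 on a total of 100).
  The class direction is the least habitat-confounded direction on the
  design (smallest generalized eigenvalue of between-habitat vs total
  variance): on an unbalanced design an arbitrary class effect leaks into
  the habitat margin and partial-SS attribution credits the shared part to
  neither factor, which would make any planted share unrecoverable by
  construction. The habitat direction is the natural soil-vs-non-soil
  contrast.

What the generator does **not** emulate: taxon co-occurrence and
compositional coupling between taxa; overdispersion beyond log-normal;
spatial or project-level structure among datasets (datasets are
exchangeable within a habitat); phylogenetic correlation of genome
features within classes; and any sequence-level signal. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated generating model, not robustness to real-data pathologies such as
compositionality or uneven sequencing depth.

## Numerical choices

- Least squares via SVD (`lstsq`, cutoff 1e-12); aliased-column pruning by
  incremental Gram–Schmidt at relative tolerance 1e-8.
- Logistic fits by IRLS, at most 100 iterations, relative log-likelihood
  tolerance 1e-10.
- Percentages reported to 2 decimal places internally and 1 in reports,
  rounded half-up (the convention behind printed percentages; bankers'
  rounding would disagree on ties).
- Studentized-range tail probabilities from `scipy.stats
  .studentized_range`, clipped to [0, 1]; a zero pooled variance returns
  p = 1 for equal means and p = 0 otherwise.

## Problem sizes

The test suite and the acceptance script run the full 1930-genome design
for the ANOVA studies, a ~600-genome down-scaled design for the logistic
recovery, 100 random small designs for the type III oracle comparison,
10 000 simulated datasets for the ubiquity-convergence study and a
300-genome cohort for life-history recovery. These sizes were chosen to
make every statistical check decisive (binomial and F-noncentrality
margins of at least ~3 sigma) while keeping a full run in seconds.

## Known limitations

- The variance partition treats class as a plain factor; no phylogenetic
  comparative correction (independent contrasts, phylogenetic regression)
  is applied, matching the reference procedure.
- Normality diagnostics are out of scope; the ANOVA relies on large-sample
  robustness.
- The percentage-contribution denominator is a declared convention, not an
  estimand; alternatives ("explained-only") change the numbers and the
  choice is recorded in every result.
- On severely unbalanced designs the factorial type III contributions
  understate a factor's variance share (see the caution above); the
  additive-model contributions should be preferred when an additive
  summary is the goal.
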