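# Methods

## Scope and data model

`coiscan` analyses a dated series of ClinVar-style VCF releases restricted
to a user-supplied whitelist of clinically relevant genes. Each release is
reduced to one `ClassificationRecord` per (contig, position, ref, alt)
after multi-allelic splitting; the `chr` prefix is stripped so GRCh38
ClinVar files and simple fixtures share one key space. ALLELEID is
retained as an auxiliary identifier but coordinates are the cross-release
join key: ClinVar positions for a given allele are stable within an
assembly, and a coordinate key keeps the pipeline usable on inputs that
lack allele identifiers. A variant annotated to several whitelisted genes
(GENEINFO `SYM1:ID1|SYM2:ID2`) counts once *per gene assignment* in every
gene-level quantity, because the per-gene burden is the analysis unit; the
alternative (unique-variant counting) would under-count genes in
overlapping loci.

### CLNSIG vocabulary

`CLNSIG` terms map to {P, LP, VUS, LB, B, COI, OTHER}. Slash dialects
(`Pathogenic/Likely_pathogenic`, `Benign/Likely_benign`) resolve to the
stronger / plain term; both `Conflicting_interpretations_of_pathogenicity`
and the 2024 renaming `Conflicting_classifications_of_pathogenicity` map
to COI, so a release series spanning the terminology change parses
uniformly. Comma-joined multi-values resolve to COI if any component is a
conflict term, otherwise to the first five-tier component. This
multi-value rule is a package choice: public archives do not document a
canonical resolution, and preferring COI guarantees that no conflicted
record is missed by the retrieval step. Everything else (drug response,
risk factor, ...) is OTHER. The mapping is total over non-blank strings;
blank values raise a malformed-record error rather than silently becoming
OTHER.

## Timelines

A timeline is the date-ordered sequence of states a variant takes across
releases; absence from a release is a gap, not a state. Derived fields:

* **first COI date** — earliest release with the COI status;
* **initial interpretation** — the class at the latest release strictly
  before the first COI date (gaps skipped), pooled into B/LB vs VUS vs
  P/LP for reporting while the five-tier class is retained. Variants
  whose first observed state is already COI form an explicit
  "no prior interpretation" category instead of being dropped, so the
  initial-class tally always partitions the conflicted set;
* **conflict combination** — which pooled groups have positive submission
  counts in the CLNSIGCONF breakdown of the first COI release: B/VUS,
  P/VUS, B/P, or B/P/VUS. OTHER submissions are ignored here (post-2018
  conflicts are defined only among the three pooled groups) but retained
  in the stored breakdown;
* **resolution** — the earliest post-COI state that is a five-tier class;
  an OTHER state does not resolve a conflict.

Headline counts include every variant that was ever conflicted, whether or
not it appears in the final release; presence in the final release is
recoverable from the timeline itself.

## Gene-burden test

Universe totals N (gene-assigned records) and K (ever-COI among them)
span the whole whitelist; the test statistic for a gene with n records
and k ever-COI records is the upper tail P(X ≥ k) of
Hypergeometric(N, K, n), evaluated through the survival function so deep
tails (q-values near 1e-200 arise in practice) remain finite; results are
clamped to (0, 1]. The one-sided upper tail is the only direction
consistent with asking which genes have a *higher* conflict frequency
than average. BH adjustment runs across exactly the genes with k ≥ 1 —
genes with no conflicted variant carry no evidence and would only dilute
the FDR denominator — and a gene is enriched at q ≤ α, default 0.05.

The power surface evaluates p at k = round(n·pct/100) (banker's rounding)
over n = 1..1000 and pct = 0..50 by default, treating the point value as
the "expected" outcome for a gene of that size and conflict share. At the
published ClinVar universe (N = 2,296,245, K = 131,092, baseline 5.7%),
a 15.2% share in a 250-record gene gives p ≈ 4e-8 and a 10% share in a
1000-record gene p ≈ 6e-8, both far below α — the test is limited by gene
size, not by effect size, once n reaches a few hundred.

Over-representation analysis reuses the same tail test on a query gene
list against GMT collections, with sets intersected with the universe and
BH across all tested sets.

## Group comparisons

Continuous gene properties (transcript length, exon count, disease count,
LOEUF, LOEUF decile, expressed-isoform count) are compared between COI
groups with the unpaired two-sided Wilcoxon rank-sum test. Below a
combined sample of 20 the p-value is computed by exhaustive enumeration of
all C(n_a+n_b, n_a) group assignments of the pooled average ranks — exact
in the presence of ties, and the reference the large-sample path is tested
against; at or above 20 the tie-corrected normal approximation with
continuity correction is used (the asymptotic regime in which p-values
like 2.2e-16 are meaningful). Identical multisets give p = 1 on both
paths. Direction is the sign of the median difference, falling back to the
mean-rank difference when medians tie.

Both the LOEUF score and its rank-based decile (0 = most constrained) are
compared, since either can serve as the constraint measure; deciles are
assigned from average ranks, making them invariant under monotone
transformations and balanced up to ties.

Inheritance modes use a chi-squared test (no continuity correction) on the
group × mode table; a gene linked to several modes contributes one count
per mode by default, with a `dominant_if_any` switch collapsing AD-linked
genes to AD. All-zero mode columns are dropped so the degrees of freedom
match the realised table.

An isoform counts as expressed when its median TPM strictly exceeds 5 in
at least one tissue.

Variant-level comparisons group variants as P/LP, VUS, B/LB (latest
non-conflict pooled class) or COI (ever conflicted). Missing allele
frequencies are excluded pairwise by default — absence from gnomAD is
censoring, not zero — with zero-imputation available as a switch. AF
ordering violations (popmin > global etc.) are flagged on the ingested
records, never silently reordered. Impact distributions can be stratified
by the pre-conflict pooled class within the COI group.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen to mirror public-archive behaviour in clinically
relevant genes:

| parameter | default | meaning |
|---|---|---|
| `baseline_coi_rate` | 0.057 | ever-COI probability per background variant |
| `n_enriched_genes` / `injected_coi_rate` | 10 / 0.20 | planted high-conflict genes |
| `class_mix` | P .02, LP .04, VUS .55, LB .27, B .12 | pre-conflict / stable class |
| `conflict_combo_mix` | B_VUS .55, P_VUS .30, B_P .05, B_P_VUS .10 | collision structure |
| `prior_interpretation_frac` | 0.9 | conflicted variants with an observed pre-conflict state |
| `resolution_rate` | 0.003 per release | ≈10% of conflicts resolve over 36 releases |
| `resolution_class_mix` | B .30, LB .45, VUS .15, LP .06, P .04 | resolutions skew benign |
| releases | 36 monthly from 2018-04 | series length |
| `n_genes` × `variants_per_gene_mean` | 300 × Poisson(30) | cohort size |

Variants are present from the first release by default (`entry_span`
staggers entry when cohort growth is wanted). A conflicted variant with a
prior interpretation shows that class in the first release and the COI
status from the second onwards; its CLNSIGCONF counts are drawn so the
parsed combination equals the drawn one (each present pooled group gets a
positive total). Allele frequencies are log-normal per class with median
ordering VUS < COI < B/LB and popmin ≤ global ≤ popmax by construction;
impact mixes make conflicted variants resemble the class they came from,
with a programmed excess of high/moderate impacts in B/LB-initial
conflicts. Enriched genes receive ×1.5 transcript length and exon count,
extra associated diseases, ×0.7 LOEUF (more constrained), an
autosomal-dominant excess (AD weight .60 vs .35) and roughly two extra
isoform candidates.

What the generator does **not** emulate: submitter-level records and
review status, duplicated alleles across assemblies, archive-wide
record-count anomalies (such as the transient mid-2022 drop in the real
archive), correlated conflict emergence within a gene, and LD or
mutational-spectrum structure in variant coordinates. Passing recovery
tests therefore demonstrates correctness of the pipeline's bookkeeping
and the calibration of its statistics under the stated model, not
robustness to every artefact of the real archive.

Because conflicts pre-date the series for no-prior variants only, the
first release shows a depressed COI share (≈0.1 × baseline); the series
mean remains within Monte-Carlo error of the configured rate and release
dynamics are stable from the second release on.

## Problem sizes used in validation

Statistical checks run at sizes chosen to give the relevant tests real
power while staying desk-scale: planted-gene recovery uses 2,000 genes ×
Poisson(300) variants (~600k records, 4 releases; expected per-gene COI
count under the alternative ≈ 60 vs ≈ 17 under the null), null
calibration uses 20 seeds of 500 genes × Poisson(60) over 2 releases, and
the exhaustive hypergeometric sweep covers every (N ≤ 60, K, n, k)
configuration (>1M tail values) against direct binomial-coefficient
enumeration.

## Numerical and degenerate-input choices

* Hypergeometric tails: scipy survival function; values clamped into
  (0, 1] (k = 0 returns exactly 1).
* BH: statsmodels step-up implementation, validated against the textbook
  sort / m-over-rank / cumulative-minimum construction.
* Duplicate variant keys within one release: last record wins, with a
  logged warning.
* An empty whitelist intersection yields an empty snapshot, not an error;
  a whitelist file with no entries is an error.
* Zero conflicted variants in a universe: the burden test returns an
  empty result with a warning rather than failing.
* Contrasts whose groups have fewer than two members are skipped in the
  property report; inside a comparison, missing values are excluded
  pairwise and fewer than two remaining values is an error.
* A single-release series is valid: timeline-dependent fields (initial
  class, resolution) are simply undefined.

## Known limitations

* The coordinate join key cannot follow a variant across assembly
  remappings; ALLELEID is stored but not used as a fallback join.
* The power surface's "expected p-value" is the p-value at the expected
  count, not the expectation of the p-value under the alternative; the
  two agree closely at the gene sizes of interest.
* ORA is plain hypergeometric over-representation: no ontology topology,
  no ranked (GSEA-style) statistics.
* The Wilcoxon exact path enumerates combinations and is quadratic-ish in
  practice; it is capped at combined n < 20 by design.
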