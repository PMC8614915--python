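# Methods

## Design and data model

The package analyses a 2×2 factorial bulk RNA-seq design: two near-isogenic
genotypes (`HI`, the high nitrogen-use-efficiency line, and `LO`, its low-NUE
sibling) under two nitrogen levels (`N1` normal, `N0` deficient), with ≥ 2
(by default 3) biological replicates per cell. Input is a gene × sample
matrix of integer fragment counts plus a sample sheet; gene identifiers are
opaque strings and no genome coordinates are used anywhere.

Four standard contrasts drive everything downstream: the two within-genotype
nitrogen responses (N0 vs N1 in each genotype, numerator first) and the two
between-genotype comparisons within each nitrogen level (HI vs LO). Contrast
orientation is fixed by these definitions and echoed in every serialized
name (`N0_HI_vs_N1_HI` style), so numerator/denominator never drift silently.

## Normalization and differential expression

Counts are normalized by median-of-ratios size factors: factor_j = median
over genes of count_gj / geometric-mean_g, computed over genes with strictly
positive counts in every sample; the median of an even number of ratios is
the midpoint of the two central order statistics. If no gene is positive
everywhere (tiny or pathological matrices), factors fall back to column sums
scaled to mean one, with a logged warning. FPKM
(count × 10⁹ / (length_bp × library_size)) is provided for reporting;
library size defaults to the column sum, with an explicit mapped-fragment
total accepted to mimic alignment-report semantics.

Per-gene significance uses a two-sided moderated *t* on
log2(normalized count + 1). Per-gene pooled within-group variances s²_g
(residual df d) are shrunk toward a prior s₀² with prior df d₀ estimated
across genes by the standard empirical-Bayes moment fit on log variances
(digamma/trigamma moments of the scaled inverse-χ² model; the trigamma
inverse is solved by Newton iteration). The posterior variance
(d₀s₀² + d s²_g)/(d₀ + d) enters an ordinary t statistic with d₀ + d degrees
of freedom. The motivation is power at three replicates: a plain per-gene
Welch *t* at n = 3 has so noisy a variance estimate that genes with a 16-fold
planted response are missed ~40% of the time on the package's own benchmark,
while variance moderation — the field's standard remedy — recovers ≥ 90% of
them with no measurable false-positive cost (the realized fraction of null
genes at adjusted p < 0.05 stays ~10⁻⁵ on all-null data). A plain Welch
engine remains available (`engine="welch"`), and externally computed DE
tables (e.g. a DESeq2 negative-binomial Wald fit) can be ingested per
contrast and flow through the rest of the pipeline; only `gene_id`, `log2fc`
and `p` are required, adjusted p being recomputed by Benjamini–Hochberg when
absent and DEG flags always being recomputed from the thresholds.

Fold changes are effect estimates separate from the test:
log2FC = log2((mean_num + ε)/(mean_den + ε)) on normalized group means, with
pseudocount ε = 1 so the quantity exists at zero counts. A gene is a DEG when
adjusted p < α (default 0.05, Benjamini–Hochberg step-up via statsmodels) and
|log2FC| ≥ 1; the fold-change cut is inclusive by default with a strict
(`>`) flag. Genes whose groups both have zero variance get p = 1 when the
group means agree and p = 0 otherwise.

## Set algebra

Per-contrast DEG sets are split by direction. Pairwise Venn summaries report
common and unique counts plus the "inconsistent" subset — genes significant
in both contrasts with opposite directions. By default inconsistent genes
stay inside the common count and are reported separately (parenthetical
bookkeeping); a flag excludes them from common instead, since published
common counts do not always state which convention they use. Counts,
explicit gene-id lists (TSV) and a JSON summary are all emitted; a simple
two-circle figure is drawn with plain matplotlib. The unique-count ratio
between two contrasts is (|A| − common)/(|B| − common).

## Classification

For focal genotype F (other O), the pipeline is:

1. **genotype-specific response** — DEGs of O's N0-vs-N1 contrast minus
   DEGs of F's, each tagged with its direction in O;
2. **expression filter** — drop genes with mean normalized count below the
   floor (default 1) in both treatments of F ("not expressed");
3. **trend filter** — drop genes whose between-genotype DE-table log2FC sign
   contradicts the sign of the raw normalized-mean difference in either
   nitrogen level, plus genes whose O-side mean is zero in both treatments
   (raw ratio undefined without a pseudocount). Direction-ambiguity has no
   single established operational definition; this sign-agreement rule is
   the package's documented default and the filter can be disabled;
4. split the classifiable set by O-direction: up → frontload candidates,
   down → relative-up candidates;
5. keep candidates that are DEGs in **both** between-genotype contrasts;
6. fold-change ratios r_N1, r_N0 = (F mean + ε)/(O mean + ε) per treatment,
   computed from size-factor-normalized group means — deliberately not from
   the DE engine's log2FC, since the ratio must exist for non-DE genes too
   (a flag switches to 2^log2FC of the between-genotype tables). Strict
   inequalities: frontloaded iff r_N1 > 2 and r_N0 < 0.5; relatively
   upregulated iff r_N1 < 0.5 and r_N0 > 2. Candidates failing only the
   ratio rules are labeled `candidate_unclassified` rather than dropped, so
   the candidate→classified funnel stays visible.

Labels are mutually exclusive
(`frontloaded`, `relatively_upregulated`, `candidate_unclassified`,
`not_candidate`, `excluded_trend`, `excluded_not_expressed`) and the
bookkeeping invariants
(classifiable = specific − not-expressed − trend-inconsistent = up + down;
classified ⊆ candidates ⊆ direction split) are enforced at construction.
The summary ratio is the frontloaded-count quotient between the two focal
genotypes. The whole classification is symmetric: relabeling HI↔LO in the
sample sheet exchanges the two focal results exactly, which the tests assert.

## Synthetic benchmark

The simulator draws negative-binomial counts with variance μ + φμ²
(dispersion φ = 0.05 by default, shared across genes; per-gene values
accepted), mean μ_cell × depth factor. Depth factors default to 1 with an
optional log-normal (σ = 0.2) mode. Archetype mean constructions at baseline
m with between-genotype fold g = 4 and response fold r = 16, ordered
(HI_N1, HI_N0, LO_N1, LO_N0):

| archetype | means |
|---|---|
| frontloaded_in_HI | (g·m, g·m, m, r·m) |
| relatively_up_in_HI | (m/g, m/g, m, m/r) |
| frontloaded_in_LO / relatively_up_in_LO | genotype mirrors |
| shared_response | (m, r·m, m, r·m) |
| constitutive_difference | (g·m, g·m, m, m) |
| null | (m, m, m, m) |

These folds place planted genes a factor of two beyond the classification
thresholds (ratio 4 vs cut 2; response log2FC 4 vs cut 1) so recovery is
testable at 3 replicates; they are configurable to probe sensitivity. The
default benchmark plants, among 2000 genes: 120 frontloaded and 80
relatively-upregulated genes per focal genotype, 300 shared responders, 300
constitutive differences, and 1000 nulls. Gene ids embed the archetype name
so fixtures are self-describing, and a truth table with the four planted
cell means accompanies every matrix. All randomness flows through one seeded
`numpy` generator; identical config + seed reproduces byte-identical output.

What the simulator does **not** emulate: read-level effects (GC/length
bias), batch effects, isoform switching, correlated genes, realistic
mean–dispersion trends, or outlier samples. Passing the recovery benchmark
therefore shows the pipeline's logic and thresholds behave as designed under
clean overdispersed counts — not that real tissue libraries would yield the
same sensitivity.

## Enrichment and qPCR utilities

Term enrichment is the upper-tail hypergeometric P(X ≥ k) for each term of a
user-supplied gene→term map against an explicit population; note P(X ≥ 0) is
identically 1, so a study set hitting a term zero times is never "enriched".
The primary flag uses raw p < 0.05 (many published enrichment lists are
reported this way); BH-adjusted values are emitted alongside, clearly
labeled. qPCR relative expression is 2^−ΔΔCt with technical-replicate Ct
values averaged first and exactly one calibrator sample required per gene —
which condition serves as calibrator is the user's choice (a natural default
is the focal genotype under normal nitrogen). Concordance between qPCR and
RNA-seq log2 fold changes is the squared Pearson correlation, undefined for
constant series.

## Numerical and reporting choices

- QC percentages (clean/raw, mapped/clean, unique/mapped) are rounded half
  up to two decimals, matching how alignment reports print them; zero
  denominators raise rather than yield NaN.
- Benchmarks in tests and the acceptance script use 2000-gene matrices with
  3 replicates and 20 null seeds — large enough for stable recovery and
  false-positive estimates while the full suite runs in seconds.
- `run` outputs record the config hash and seed in `run_meta.json`; the run
  is a pure function of (config, seed).

## Known limitations

- The moderated t on log2 counts is not a count-likelihood model: no
  dispersion shrinkage toward a mean trend, independent filtering, or LFC
  shrinkage. For publication-grade DE on real data, inject DESeq2/edgeR
  tables via `read_contrast_table`; the classifier consumes only
  (log2FC, adjusted p, flags).
- The trend filter and the "not expressed" floor are pragmatic defaults, not
  community standards; both are configurable and the filter can be disabled.
- Enrichment takes flat gene→term maps only: no ontology DAG propagation or
  pathway-database access.
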