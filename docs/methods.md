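# Methods

## Model and procedure

The package identifies lncRNA–PCG pairs acting as competing endogenous
RNAs from a matched normal/tumor cohort in two stages.

**Candidate construction.** From a miRNA–target interaction table the
candidate set is every lncRNA × PCG pair whose miRNA target sets
intersect. Enumeration iterates over miRNAs (cost proportional to
co-targeting events, not |lncRNA|·|PCG|). The sharing itself can be
scored by an upper-tail hypergeometric test: with `k` shared miRNAs,
`K` miRNAs targeting the lncRNA, `nq` targeting the PCG and universe
`N`, `p = P(X ≥ k)` for `X ~ Hypergeom(N, K, nq)`. The universe defaults
to the number of distinct miRNAs in the interaction set — the natural
sampling frame — and is overridable. Benjamini–Hochberg q-values are
computed across all tested pairs.

**Scoring.** Per-patient relative expression is
`e = log2(tumor + c) − log2(normal + c)` with pseudocount `c = 0` by
default and a hard error on non-positive values: silently shifting
strictly positive (microarray-like) data would distort fold changes, so
a pseudocount (0.01 suggested) must be an explicit choice for
count-derived data. The local criterion counts patients whose two log2FC
values are concordantly beyond the fold-change threshold (±1 log2 unit,
strict); the global criterion is the Pearson correlation of the two
log2FC profiles with a two-sided t-test p-value. The functional call
requires `DEC > dec_cutoff` (default 5), `cor > 0` and `p < 0.05`, all
strict — `DEC > 5` means at least six consistent patients.

Relative (log2FC) rather than absolute expression feeds the correlation:
differencing within patients removes patient-level baseline effects.
Combining a two-sided p with `cor > 0` approximates a one-sided test at
0.025; `GloceRNAConfig(two_sided=False)` switches to one-sided. No
multiple-testing correction is applied to the correlation p in the
functional call (the raw-p criterion is part of the decision rule);
the baseline comparator applies BH where its rule says so.

**Numerical notes.** Correlations are computed by centred dot products;
the t transform uses `t = r·sqrt((n−2)/(1−r²))` with the `1−r²` factor
clipped at 0 so |r| = 1 maps to p = 0+. Pairs with a zero-variance
log2FC profile are excluded and counted, never scored `cor = 0`: an
undefined statistic must not silently pass or fail. Pairs whose genes
are absent from the matrix are skipped with a count. Output rows are
sorted by (lncrna_id, pcg_id) with a stable sort, so results are
deterministic and patient-order invariant. Cohorts with n < 3 are
rejected.

## Baseline comparator

The traditional identification scheme is provided for comparison: a pair
passes iff (i) `cor > 0` with BH FDR < 0.05 across tested pairs, (ii)
both genes differentially expressed by a paired two-sided t-test on
log2 expression at BH FDR < 0.01 or 0.05, and optionally (iii) the
shared-miRNA hypergeometric test at BH FDR < 0.05 (otherwise sharing one
miRNA suffices). The paired t-test is a documented stand-in for
SAM/Limma; the scheme treats the DE engine as interchangeable, and exact
reproduction of those tools is out of scope. The correlation uses
relative expression by default (`use_relative=False` correlates absolute
tumor expression), keeping the comparison on the same footing as the
main scorer.

## Network, enrichment, survival

The functional pairs form a strictly bipartite undirected graph.
Betweenness is reported unnormalized (each unordered node pair counted
once), matching the classical definition; degree-1 nodes in trees have
betweenness 0. lncRNA similarity reports both the raw shared-PCG count
and the Jaccard index, since either normalization is defensible.
Cross-cohort overlap significance is an upper-tail hypergeometric test
that requires the universe (candidates scoreable in both cohorts) to be
supplied explicitly — there is no sensible implicit default.

Hallmark enrichment tests the union of PCGs adjacent to ce-lncRNAs
(network-wide) or each lncRNA's own PCG neighborhood (per-lncRNA)
against GO-term proxy sets, upper-tail hypergeometric, query and set
first intersected with the universe (default: PCGs appearing in
candidate pairs). Significance is raw p < 0.05 with BH q-values reported
alongside; a hallmark counts as enriched when any of its GO sets is
significant. Ranking of lncRNAs by enriched-set count breaks ties by id.

The survival screen dichotomizes patients at the mean of each target's
absolute tumor expression (tie → low, deterministic; relative expression
is an option), then applies Kaplan–Meier estimation and the two-group
log-rank test (lifelines). Pair targets use the per-patient average of
the two genes' raw expression. Degenerate groupings, missing genes and
zero-event tables raise or skip per target with a log record. A pair is
flagged `pair_better` when it is significant while neither of its genes
is alone.

## Enhancers and THZ1

SE/TE regions (called upstream from H3K27ac data; region calling is out
of scope) are assigned to genes by three rules with precedence
overlap > proximal > closest: gene-body overlap (distance 0), TSS within
`proximal_window` of the region center (default 50 kb, the conventional
enhancer-mapping window), and the single closest TSS per region (ties by
gene id). TSS is strand-aware, coordinates are BED-style 0-based
half-open. A ce-lncRNA is SE-labelled if SE-assigned in any cell line,
else TE, else none.

THZ1 sensitivity is classified at a configurable evaluation timepoint
(default 12 h): genes with DMSO FPKM ≤ 1 are excluded as inactive, the
fold change is `(DMSO + ε)/(THZ1 + ε)` with ε = 0.01 guarding zero
denominators, and `fold_change > 1.5` (strict) marks a gene sensitive.
The subnetwork seeds are the sensitive SE/TE ce-lncRNAs, intersected
across cell lines by default (`require_shared=False` takes the union),
expanded to first neighbors.

## Synthetic data

The generator emulates all inputs with known truth. Study conditions
(defaults): 20 patients, 200 lncRNAs, 600 PCGs, 100 true pairs among 900
shared-miRNA decoys, effect mean μ = 2 log2 units, signal spread
σ_signal = 0.5, observation noise σ_noise = 0.5, null log2FC spread 0.5,
log-normal normal-tissue baseline (mean 5, sd 1 on the log2 scale).

For a true pair, each patient draws a direction `s_i = ±1` with equal
probability and a latent `z_i ~ N(s_i·μ, σ_signal)` shared by the two
genes; each gene observes `z_i` plus independent `N(0, σ_noise)`. The
per-patient direction models tumor heterogeneity — the very situation
the local DEC criterion is built to detect — and makes the planted
within-pair correlation `(μ² + σ²_signal)/(μ² + σ²_signal + σ²_noise)`
≈ 0.94. With `per_sample_signs=False` the direction is instead fixed per
pair (half up, half down), which adds the mean shift a paired DE test
needs but lowers the planted correlation to
`σ²_signal/(σ²_signal + σ²_noise)` = 0.5; the baseline-comparator tests
use that mode. Decoy pairs share a dedicated miRNA but have independent
expression, isolating the expression criteria from the pairing
criterion; each planted pair gets its own miRNA so the candidate set is
exactly the planted pairs.

Survival times are exponential with log-hazard `hazard_beta` (default
1.5) per standard deviation of the linked gene's tumor expression and
independent censoring (default rate 0.2). The toy genome has two
chromosomes with 1-kb genes spaced 200 kb; planted SE/TE regions overlap
their lncRNAs' bodies in every cell line. The THZ1 time course fixes
non-sensitive active genes at fold change exactly 1, sensitive genes at
the configured fold (default 2.0) at 12 h, and emits a few genes below
the FPKM > 1 activity floor.

What the generator does **not** emulate: array/sequencing noise
heteroscedasticity, batch effects, correlated miRNA co-targeting
structure, gene-length effects, non-exponential survival, or partial SE
overlap cases. Passing tests therefore demonstrate correctness of the
decision rules and statistics under the stated model, not performance on
real cohorts.

Test and example problem sizes (a few hundred to a thousand pairs,
10–60 patients, 20 simulation seeds) were chosen as the smallest scales
at which the planted effects are unambiguous while the whole suite runs
in seconds.

## Known limitations

* The method needs N/T matched samples; unmatched cohorts cannot supply
  per-patient fold changes.
* miRNA expression is not used: conditional approaches (partial or
  sensitivity correlation) are deliberately out of scope.
* The DEC cutoff is an absolute sample count; for cohorts much larger or
  smaller than a few dozen patients it should be re-examined (the
  configuration exposes it).
* Behaviour at log2FC exactly ±1 follows the strict inequalities; values
  on the boundary never count as consistent.
* The hypergeometric universes (miRNA sharing, enrichment, overlap) are
  explicit modelling choices; results can be sensitive to them.
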