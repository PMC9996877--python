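# Methods

## The circadian rhythm score

Genes of the mammalian clock fall into two classes: the core oscillator
(CLOCK/BMAL1, PERs, CRYs, their kinases and modifiers) and the
clock-control genes of the stabilizing and output loops (RORs, REV-ERBs,
DBP/TEF/HLF, NFIL3, …). The CRS summarizes, per sample, the balance between
the two classes' transcriptional activity.

For one sample with N genes, expression values are replaced by ranks
r_1..r_N (1 = lowest, average ranks on ties). Walking the genes in
decreasing rank order, the ssGSEA enrichment score of a gene set S is

    P_hit(k)  = Σ_{i∈S, pos(i)≤k} r_i^α / Σ_{i∈S} r_i^α
    P_miss(k) = |{i∉S : pos(i)≤k}| / (N − |S|)
    ES(S)     = Σ_{k=1..N} (P_hit(k) − P_miss(k))

with α = 0.25 (the canonical ssGSEA exponent). The two circadian sets are
always scored in a single call; when normalization is enabled (the
default), every ES of the call is divided by the max − min of the call's
full set × sample score matrix, so the two sets share one scale and

    CRS = ES_control − ES_core

is meaningful. The statistic is rank-based, hence invariant to any strictly
monotone per-sample transform of expression, and the walk's tie order is
fixed (stable sort by gene position) so repeat runs are bit-identical.

Sign convention: the definition above (control minus core) makes CRS *fall*
in tumors where core genes rise and control genes fall. Reported group
directions in this literature sometimes use the negated axis; a
`sign_convention` switch is exposed and every output records which
convention produced it. Genes of a set absent from the matrix are dropped
with a warning (never imputed as zero expression). Whether to normalize is
likewise exposed; the flag and constant are carried in the output metadata.

## Survival statistics

All four survival procedures are first-principles implementations
(cross-checked against lifelines in the test suite, never delegated to it):

- **Kaplan–Meier**: S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct event
  times; censored-only times shrink the risk set without moving S.
- **Log-rank**: χ² = (O₁ − E₁)²/V with the hypergeometric variance
  V = Σ_t d (n₁/n)(1 − n₁/n)(n − d)/(n − 1) summed over distinct event
  times; p from χ²(1).
- **Maximally selected cutpoint**: candidates are observed marker values
  whose `value > cut` split leaves ≥ minprop·n samples on each side
  (minprop = 0.1, the referenced cutpoint routine's convention); the
  returned cutpoint maximizes |(O₁ − E₁)/√V|, ties broken toward the
  smaller value. Samples above the cutpoint are "high". The p-value
  attached to the selected split uses the ordinary χ²(1) reference and is
  flagged `selection_biased, uncorrected`: scanning many splits inflates
  the maximal statistic, and no selection correction is applied here.
- **Univariate Cox**: Newton–Raphson on the Breslow partial likelihood,
  convergence |Δβ| < 1e−8 within 50 iterations, steps damped to |Δβ| ≤ 5
  near separation; SE from the observed information; Wald z/p and 95% CI.
  Breslow (not Efron) ties: simpler, exactly testable, and identical to
  Efron on tie-free data; the tie method is recorded on the result.
  Non-convergence and monotone likelihoods are flagged on the result, never
  silently returned. The score test at β = 0 on a binary covariate equals
  the log-rank χ² (without tied event times), which the tests exploit.

## Differential expression and genomics

- FPKM→TPM: TPM_ij = FPKM_ij / Σ_i FPKM_ij × 10⁶ (columns sum to 10⁶).
- Differential calls: Welch's t on log2 values (linear units get a +1
  pseudocount before log2; no pseudocount is stated upstream, +1 is the
  common convention for abundance units). "Up" requires fold change > 2
  *and* p < 0.05; "down" symmetric; BH q-values are reported alongside but
  the gate uses the raw p, matching the stated DEG definition. A moderated
  (empirical-Bayes) test is deliberately not used; the substitution is
  visible in the output metadata.
- Mutation frequency: distinct mutated samples / cohort size; a sample hit
  twice in one gene counts once and is classed `multi_hit`. A display
  filter at overall proportion > 10% is exposed as an option.
- CNV: focal scores in [−0.3, 0.3] (boundaries inclusive) are neutral,
  above 0.3 amplified, below −0.3 deleted. (The stated deletion threshold
  "less than 0.3" is read as −0.3; otherwise the neutral class would be
  empty.) CNV–expression coupling is Spearman on the *raw* focal scores
  over shared samples (≥ 5); genes with constant CNV get a missing record,
  not ρ = 0.

## Immune screens

Fractions (e.g. CIBERSORT output) are inputs — deconvolution is out of
scope. Group differences per cell type use the two-sided Wilcoxon rank-sum
test; CRS–feature screens use Spearman correlation with BH adjustment
(Pearson is exposed as an option; the default follows the rank-based
choice). The immune-checkpoint screen keeps genes with |ρ| > 0.7 and
p < 0.05. Stromal/immune signature scores are unnormalized ssGSEA ES from
one joint call, their sum is the combined score, and the cosine purity
transform (constants from the original ESTIMATE publication) is strictly
opt-in. The bundled stromal/immune signatures are synthetic stand-ins; real
signatures can be supplied as GMT.

## Connectivity scoring

The query signature is the n_top = 150 most positively and most negatively
CRS-correlated genes (Spearman; ρ ties broken lexicographically by gene id
for determinism). For a compound ranking of n genes and a tag set T with
sorted positions V(1..t):

    a = max_j (j/t − V(j)/n),  b = max_j (V(j)/n − (j−1)/t)
    ks(T) = a if a > b else −b      (a = b resolves to −b)

raw score s = ks(up) − ks(down), set to 0 when the two components share a
sign. Within each cancer, positive raw scores are scaled by the maximum
positive and negative scores by |minimum negative| onto [−100, 100]; this
deterministic extremal scaling is this package's convention (no
permutation-based tau normalization). A compound is a positive hit when its
scaled score exceeds 90 in at least 10 cancers; negative hits mirror this.
Exact negation of s under ranking reversal holds only away from discrete
tie boundaries (the shared-sign zero rule), so the tests verify reversal
against an enumeration oracle rather than asserting antisymmetry.

## Synthetic data

One master seed spawns a fixed substream per draw site
(`SeedSequence.spawn`), so outputs are bit-reproducible and adding a stream
never perturbs the others. Defaults encode the study conditions the
analysis assumes:

- **Cohort** (`simulate_cohort`): log2(x+1)-scale expression, gene
  baselines μ_g ~ N(7, 1), noise SD 0.5; 13 control + 35 core circadian
  genes among 1000 background genes; 200 tumor + 50 normal samples; in
  tumors, core genes shift +1 log2 unit and control genes −1. The latent
  score (mean control − mean core expression, standardized over tumors)
  drives exponential proportional-hazards survival with baseline hazard
  1/500 per day and log-hazard 0.8 per score unit; censoring is
  Uniform(0, τ) with τ solved numerically so the expected censoring
  fraction is 0.3. Effect sizes of one log2 unit sit exactly at the
  fold-change gate, so roughly half the circadian genes are called
  differential in a default cohort — the gate's strictness is visible by
  design.
- **Knockout** (`simulate_knockout`): normal-like samples; target genes
  are multiplied by the knockdown factor on the linear (2^x − 1) scale, so
  factor 0 sends them to the floor without −∞ and factor 1 is exactly the
  identity.
- **Time course** (`simulate_timecourse`): circadian genes oscillate as
  A·sin(2πt/period + φ_g). Phases are class-coherent — control genes
  ~N(0, 0.4 rad), core genes ~N(π, 0.4) — because clock output is
  phase-organized by regulatory element (E-box vs D-box/RRE), and with
  uniform random phases the class-level enrichment oscillations would
  cancel. The deregulated group differs only in amplitude.
- **Genomics** (`simulate_genomics`): Bernoulli mutations per gene ×
  sample at rate 0.01 (so ~38% of samples carry ≥ 1 hit across a 48-gene
  panel, and per-gene frequencies stay in the low percent range); focal
  CNV scores are U(−0.25, 0.25) noise with a 10% admixture of ±U(0.35,
  1.2) events; expression shifts by coupling × categorized CNV. Note the
  Spearman CNV–expression correlation on raw focal scores is structurally
  capped near 1 − f_neutral³ even under perfect coupling, because neutral
  samples contribute independent ranks.
- **Compound library** (`simulate_compound_library`): uniform random
  permutations of the universe; planted mimics put the query's up-genes at
  the very top and down-genes at the very bottom, reverts the opposite.
- **Fractions** (`simulate_fractions`): Dirichlet columns with
  concentration 5·exp(link_c · score_s) — a zero link gives exchangeable
  columns summing to 1.

What the generators do *not* emulate: count-level noise (negative
binomial), batch effects, tumor purity confounding, probe-level microarray
structure, correlated gene-gene networks, or non-proportional hazards.
Passing tests therefore demonstrate correctness of the statistics and the
pipeline's plumbing under the assumed generative structure, not robustness
to real-data pathologies.

## Numerical conventions and degenerate inputs

- TSV is the only tabular dialect (no comma autodetection); floats are
  written at 17 significant digits and parsed with round-trip precision, so
  write-then-read is exact.
- Gene ids match case-sensitively after whitespace stripping; rows with
  missing values are dropped and counted, never imputed; every drop or
  label remap appears in the load report.
- Ranks use average ties everywhere; all scan/sort tie-breaks are
  deterministic and documented at the operation.
- Correlations on constant vectors are reported missing, not zero.
- Degenerate requests (single-gene matrices, empty set intersections,
  single-level groups, constant Cox covariates, no admissible cutpoint,
  zero-event log-rank) raise typed errors rather than returning values.

## Problem sizes

The test suite and the acceptance script run on simulated cohorts of 200
tumor + 50 normal samples with ~1000 background genes (smaller for
replicate-heavy checks: Cox recovery uses 100 replicates at n = 300 with a
20-gene background, since survival recovery does not depend on the
expression dimension; the compound screen uses 18 synthetic cancers with
300–1000 compounds over a 300-gene universe). These sizes were chosen so
each property is measured with comfortable statistical resolution.

## Known limitations

- The selected-cutpoint log-rank p is reported uncorrected (flagged); a
  selection-bias correction is out of scope.
- Breslow ties make Cox estimates differ slightly from Efron-based fits on
  heavily tied data; synthetic survival times are continuous, so the
  difference is negligible here.
- The extremal ±100 scaling of connectivity scores is sensitive to the
  single strongest compound per cancer; a permutation-based normalization
  would be more robust but non-deterministic.
- The bundled circadian and checkpoint gene lists are curated stand-ins
  assembled from well-established members of each class; swap in your own
  GMT files for production analyses.
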