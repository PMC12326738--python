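# Methods

This note documents the statistical models behind `senescreen`, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions that affect results.

## 1. Screen count model and beta scores

For one selection condition (RSS or ISS), the count of sgRNA *i* of gene
*g* in sample *s* is modelled as negative binomial,

    k_is ~ NB(mean μ_is = S_s · exp(b_i + t_s·β_g),  variance μ + α_i μ²),

with `S_s` the per-sample size factor, `t_s ∈ {0,1}` the final-sample
indicator, `b_i` a free per-sgRNA abundance intercept, `β_g` the gene's
selection coefficient (the *beta score*), and `α_i` the sgRNA's NB
dispersion. A positive β means the gene's sgRNAs are enriched in the final
population. Each condition is fitted separately against its own initial
samples; a joint two-condition fit was considered but a per-condition
contrast keeps the two arms' results independent, which the downstream
RSS-vs-ISS classification relies on.

**Optimization.** Joint MLE over `{b_i}, β_g` by Fisher scoring with the
expected information. The information matrix has arrow structure (diagonal
in the `b_i` plus one dense column for β), so the Newton step is solved by
a Schur complement in closed form and the fit is vectorized across all
genes with the same sgRNA count. Steps are halved per gene whenever the
log-likelihood would decrease (up to 25 halvings), convergence is declared
at |Δlogℓ| < 1e-8 with a cap of 100 iterations, β is clipped to ±15
(degenerate all-zero final counts would otherwise diverge), and
non-converged genes are reported as NA and logged. Below α = 1e-6 the
likelihood switches to its Poisson limit, avoiding catastrophic
cancellation in the gamma functions; the fit then agrees with an
iteratively-reweighted Poisson GLM to < 1e-6 (tested against statsmodels).
Wald SE comes from the (β, β) entry of the inverse expected information;
p-values are two-sided normal.

**Size factors** are DESeq-style median-of-ratios over sgRNAs nonzero in
every sample, rescaled to geometric mean 1. All-zero sgRNAs are excluded
from the likelihood; no pseudo-counts are added (the NB handles zeros).

**Dispersions** are method-of-moments, `(s² − m̄)/m̄²`, on normalized counts
within each replicated (condition, timepoint) group, precision-weighted
across groups. Because screens typically have only two replicates, the raw
per-sgRNA estimate is extremely noisy and would break Wald calibration, so
it is shrunk toward the across-sgRNA mean with weight `df/(df + prior_df)`
(`prior_df = 20`) and floored at 0.01. With two replicates per group this
makes the estimate mostly global — which is what keeps the null
fraction of Wald p < 0.05 inside [0.03, 0.08] in the calibration tests —
while with ~20 replicates the per-sgRNA moment estimate dominates.

**Non-targeting controls** are grouped into pseudo-genes (default size 5,
names `NT_PSEUDO_*`) and fitted identically, giving an empirical null
inside every result table.

**Permutation FDR.** sgRNA→gene assignments are shuffled preserving gene
sizes (the gene-label vector is permuted over all sgRNA rows, non-targeting
included), the full estimator is re-run, and null p-values are pooled
across `n_perm` rounds (default 100; tests and the acceptance script use
20 to keep runtimes short — the estimator is unchanged, only the
null-resolution drops). Then

    FDR(g) = [(1 + #{null p ≤ p_g}) / (1 + #null)] / [#{obs p ≤ p_g} / #obs],

capped at 1 and made monotone non-decreasing in p by a running maximum.
Null counts are accumulated per permutation as rank counts, so memory does
not grow with `n_perm`. The add-one smoothing bounds the smallest
attainable FDR away from zero.

## 2. Screen QC

A logistic model of gold labels on (β, −log10 p) is fitted on the labelled
genes and its linear predictor scores all genes; AUC is the Mann–Whitney
pair statistic with midrank ties. The combiner is fitted and evaluated on
the same genes — deliberately reproducing the usual screen-QC practice —
so the AUC is optimistic; it is a data-quality readout, not an estimate of
out-of-sample classification accuracy. Significance comes from the same
label-permutation scheme as the FDR, with `p = (1 + #{null AUC ≥ obs}) /
(1 + n_perm)`.

## 3. Gene-set classification

Signature genes are those with Wald p < 0.05 in either arm. K-means
(Lloyd, best of 50 restarts) runs on the raw (β_RSS, β_ISS) matrix — no
column scaling, because both axes are beta scores on a shared scale.
`k = 4` by default: the two arms produce ISS-specific and concordant
groups, each with an enriched and a depleted pole. Cluster labels depend
only on centroids (hence are invariant to cluster indexing): with
per-column thresholds `thr = 0.5 · max_cluster |centroid|`, a cluster is
*inflammaging* if its ISS centroid is large and its RSS centroid small,
*common-aging* if both are large with the same sign, else unassigned. A
zero column threshold (axis carries no signal at all) counts as "small".
The 0.5 fraction and k are configuration; they were chosen once, before
the recovery experiments, as the natural reading of "specifically enriched
in one arm". Control sets are uniform draws from the universe minus the
named sets. Reference-set enrichment is the upper-tail hypergeometric
`P(X ≥ overlap)` with Benjamini–Hochberg correction across sets.

## 4. Synthetic data

The screen generator emulates a pooled CRISPRi library of ~5 sgRNAs/gene
plus non-targeting controls (the emulated genome-wide design: 18,905 genes,
~5 guides each, 1,895 non-targeting; the real library's guide count varies
per gene, this generator's does not). Baseline abundances are
log-normal(0, 1) — matching the right-skew of real pooled libraries —
renormalized to proportions; final proportions are `∝ p0 · exp(effect)`;
counts are NB with mean `depth` reads per sgRNA (default 500) and
dispersion α = 0.05, two replicates per arm. The per-sgRNA effect is
`β_g · e_i` with efficacy `e_i ~ N(1, 0.2)`: multiplicative, so null genes
are exactly null (additive guide noise would make every "null" gene a weak
true effect and destroy the type-I-error analysis) while unit effects get
the intended 0.2 spread. What this generator does **not** emulate: variable
guides per gene, guide-sequence-dependent efficacy, copy-number artifacts,
cell-cycle bottlenecks, or correlated replicate structure — so passing
recovery tests show the estimator works under its stated model, not that
real screens meet that model.

The GWAS generator draws, per LD block with AR(1) correlation R
(`R_ij = ρ^|i−j|`, exact and therefore with closed-form true LD scores),

    z = √N · R β + ε,   β_k ~ N(0, Σ_c τ_c A_kc),   ε ~ MVN(0, R),

so `E[χ²_j] = N Σ_c τ_c ℓ(j,c) + 1` holds exactly. Truth objects record
the expected-scale h² and per-annotation h². Real human LD (variable block
sizes, long-range LD, MAF-dependent architecture) is out of scope; AR(1)
blocks keep every downstream quantity checkable in closed form.

## 5. Stratified LD score regression

Annotations: SNP j belongs to a gene set's annotation iff it lies within
100 kb of a member gene's transcribed region, **boundary inclusive**
(100,000 bp beyond the ends is in; 100,001 is out — the inclusive reading
of "within"). The base annotation (all ones) is always the first column.
Windows are physical distance; LD-score windows default to 1 Mb.

The regression is `χ²_j = N Σ_c τ_c ℓ(j,c) + intercept` with a **free
intercept** (standard practice; absorbs confounding inflation).
Weights are two-pass: an unweighted pass gives a provisional ĥ², the
second pass weights `1/[max(ℓ_base, 1) · (1 + N ĥ² ℓ_base / p)²]`,
combining the over-counting and heteroskedasticity corrections. This is a
documented simplification of the reference tool's weighting (which also
conditions on the in-regression annotations); the two agree in the
settings tested here but are not identical. χ² values are capped at
`max(80, 0.001·N)` before regression (the conventional outlier guard;
configurable off — and worth disabling on toy data whose per-SNP signal
is orders of magnitude above GWAS scale). Heritabilities are
`h²_a = Σ_{k∈a} Σ_c τ̂_c A_kc`, enrichment is `(h²_a/h²)/(|a|/p)`, and the
base annotation's enrichment is identically 1 with SE 0.

Uncertainty is a delete-one-block jackknife over `n_blocks = 20`
contiguous SNP blocks (reference tools use 200; 20 matches the synthetic
scale of ~20k SNPs at ~1k SNPs per block). Coefficients are re-estimated
per deletion; h², enrichment and the per-SNP difference d are recomputed
from each delete-block coefficient vector over the full SNP set, and
`SE² = (B−1)/B Σ (θ_b − θ̄)²`. The one-sided enrichment test is the normal
upper tail of `d/SE(d)`; with 20 blocks this is mildly liberal relative to
a t reference but stays inside the binomial band at α = 0.05 in the
200-replicate calibration.

Identifiability note: with a free intercept, τ_base is identified by the
*variation* in ℓ_base. Weak LD (ρ ≲ 0.5 in short blocks) leaves ℓ_base
nearly constant and the fit unstable — the same degradation the real
method suffers when LD scores have little range. The shipped defaults use
ρ = 0.9. Datasets are gated on single-annotation h² Z ≥ 6 (and MAF ≥ 0.05,
boundary retained), which at synthetic scale requires ~20k SNPs of
well-measured signal.

## 6. Meta-analysis across traits

Per trait and gene set, the pooled quantity is the per-SNP inside-vs-
outside difference `d = h²_a/|a| − (h²−h²_a)/(p−|a|)` (zero exactly when
enrichment is 1; undefined when the annotation is empty or full), with its
jackknife SE. DerSimonian–Laird random effects:
`τ²_meta = max(0, (Q−(n−1))/(Σw − Σw²/Σw))` with `w = 1/se²`, pooled
estimate `Σw*·est/Σw*` with `w* = 1/(se²+τ²_meta)`, `SE = 1/√Σw*`; a
single study passes through unchanged. The group-level p is the one-sided
normal upper tail of pooled/SE. Gene sets are compared by
`z = (pooledA − pooledB)/√(SE_A²+SE_B²)` assuming independence — an
approximation, since both sets are evaluated on the same traits; a
trait-paired alternative (meta-analyzing per-trait d_A − d_B) is provided
and is the safer choice when the trait lists coincide. Trait selection
keeps traits with one-sided enrichment p < 0.05 for any set; retained
enrichment rows are Ward-clustered (cluster count defaulting to the number
of gene sets) and each trait is labelled by its argmax set. The
label-vs-aging association uses Fisher's exact test (two-sided) — the
association test in the emulated analysis is unnamed, and Fisher's exact
is the standard choice for small 2×2 tables.

## 7. Pipeline scale and reproducibility

Every random step draws from an explicitly seeded generator; per-stage
seeds are derived from the global seed by hashing the stage name, so
stages can be re-run independently. `run_pipeline` writes TSV/GMT/JSON
artifacts and a manifest of SHA-256 hashes; identical configs reproduce
identical hashes. Default problem sizes — 400 genes × 5 sgRNAs at depth
500 for the screen; 12,000 SNPs in 240 AR(1) blocks (ρ = 0.9) with 20
traits at N = 50,000 for the heritability chain; 20 permutations and 20
jackknife blocks — were chosen so the full chain runs in seconds on one
CPU while keeping every estimator in its asymptotically sensible regime.
The acceptance script uses 1,000 genes, 20,000 SNPs, 20 recovery seeds and
200 null replicates.

## 8. Known limitations

- The NB fit assumes known (plug-in) dispersions; their uncertainty is not
  propagated into the Wald SE, which the shrinkage mitigates but does not
  remove.
- The QC AUC is in-sample by design (Section 2).
- Beta-score MLE invariance to rescaling one sample's counts together with
  its size factor is exact only in the Poisson limit: the NB likelihood
  weighs a sample by its counts, so inflating one sample shifts the MLE
  slightly. Rescaling all samples together is exact in the Poisson limit.
- Enrichment invariance to rescaling all χ² and N by a common factor is
  exact under count-independent weights (single-pass); the two-pass
  weights introduce an O(weight-change) perturbation.
- The S-LDSC weighting scheme is a simplification of the reference tool's
  (Section 5); jackknife-based one-sided tests use a normal reference.
- The cross-gene-set comparison ignores between-set correlation unless the
  paired variant is used.
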