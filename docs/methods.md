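# Methods

This note documents the statistical models behind `pqtlkit`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Data model and numerics

Summary statistics are tab-separated tables with 1-based inclusive
coordinates on a single build label; BED input is converted on read. Effect
sizes are per effect-allele copy: inverse-rank-normalized trait SD units for
quantitative traits (protein, mRNA), log-odds for case-control outcomes.
All two-sided p-values use the normal approximation (meta-analysis z-tests),
never *t*.

Association strength is carried internally as −log₁₀ *p* computed from the
normal log-survival function, so values far beyond the float64 underflow
limit (*p* ~ 10⁻³⁰⁰ and smaller; |z| up to several hundred) remain exactly
comparable. The inverse (z from −log₁₀ *p*) switches to a Newton solve of
`logsf(z) = log p/2` past |z| ≈ 36.

Allele harmonization flips β → −β and f → 1−f for swapped alleles.
Strand-ambiguous (A/T, C/G) pairs are resolved by effect-allele frequency
only when the two candidate orientations differ by more than 0.1 in
frequency distance; otherwise the record is declared unmatchable. This is a
policy choice (upstream tools differ and are rarely explicit); the
conservative default trades a little power for immunity to sign errors.

For eQTL resources that publish only (z, f, N), effect sizes are
reconstructed as β = z/d, se = 1/d with d = √(2f(1−f)(z² + N)), which
preserves β/se = z exactly.

## Meta-analysis and filters

Fixed-effects inverse-variance weighting with w = 1/se²;
Q = Σw(b − β̂)², I² = max(0, (Q − (k−1))/Q)·100, defined as 0 for k = 1.
Verdict logic per variant:

* **excluded** — present in < 3 cohorts or < 3,500 participants (evaluated
  after cohort QC);
* **not_significant** — pooled *P* > 5×10⁻¹⁰ (5×10⁻⁸ Bonferroni-corrected
  for ~100 protein GWAS);
* **filtered_heterogeneous** — study-wide significant with I² > 30 % but
  fewer than three cohorts at *p* < 0.05 whose sign matches the pooled
  estimate (cohorts missing the variant count as "?" and never as support);
* **significant** — otherwise.

Boundary conventions: p-thresholds use ≤, the I² rule uses strict >, QC
boundaries are inclusive (info = 0.3 is kept, HWE *p* = 10⁻⁶ is dropped
since the rule is *p* > 10⁻⁶). The genomic-control λ is computed and
reported per protein but never used to rescale.

## Locus definition and conditional analysis

Significant variants are flanked ±1 Mb; closed intervals that overlap *or
touch* merge transitively (the exactly-2-Mb-apart case is a documented
choice — merging errs toward fewer, larger loci). Left bounds clip at 1; no
chromosome-length clipping (synthetic coordinates are unbounded). Sentinel
ties break by largest |z| then smallest position, making outputs
deterministic.

The approximate conditional analysis reconstructs the multiple-regression
solve from marginal statistics: X′X ≈ √D R √D and X′y ≈ D b with
D_j = 2f_j(1−f_j)N_j, R the LD-reference correlation submatrix, and the
phenotypic (residual) variance fixed at 1 — appropriate for an
inverse-rank-normalized trait whose individual signals explain little
variance, and the reason the orthogonal-LD limit reduces *exactly* to the
marginal tests. Selection starts at the sentinel and admits the candidate
with the smallest conditional p while it passes the entry threshold
(5×10⁻¹⁰) and stays below the collinearity cap (r² ≤ 0.9 with the selected
set). Variants with MAF < 1 % are ineligible unless they are the sentinel.
A numerically singular LD submatrix is ridge-stabilized (10⁻⁶ of the
diagonal) with a warning. Selected sets are finally pruned to pairwise
r² ≤ 0.1 by ascending p with sentinels forced in.

PVE per protein is Σ χ²ᵢ/(χ²ᵢ + Nᵢ − 2) over sentinels, flagged when the
total reaches 1 (non-independent inputs).

## Colocalization

Per-variant Wakefield log-ABFs with prior effect SD 0.15 (trait-SD scale)
for quantitative traits and 0.2 (log-odds) for case-control — the delegated
convention, recorded in output since only the hypothesis priors
(10⁻⁴, 10⁻⁴, 10⁻⁵) were fixed upstream. Hypothesis sums use log-sum-exp
throughout; H3 is computed as log(e^{s1+s2} − e^{s12}) via `expm1`, so
posteriors stay finite and sum to 1 for |z| up to at least 200. Variants
missing from either trait are dropped (intersection) with a count.

The conditional-then-pairwise mode runs stepwise selection per trait at
*P* ≤ 5×10⁻⁸, conditions each trait on its *other* signals
(b_cond,j = b_j − Σ_k r_jk (s_j/s_k) b_joint,k, SEs inflated by the
conditional-variance factor 1/√(1−h_j), conditioned variants set to zero),
and colocalizes every signal pair plus the unconditioned pair, reporting the
matrix and its maximum PP4. With a single signal per trait the matrix
reduces to the plain pairwise result. Upstream "very large cap" parameters
(top-variant count, LD window) are treated as unbounded at this scale.
Multi-trait colocalization is approximated by requiring pairwise PP4 ≥ 0.8
for all pairs.

## Mendelian randomization

Instrument selection: genome-wide significant (*P* ≤ 5×10⁻⁸) cis variants,
greedily clumped to r² ≤ 0.1 by ascending p, allele-frequency difference to
the reference capped at 0.4, minimum three instruments. The estimate is
generalized least squares over Wald ratios β_i = b_zy,i/b_zx,i with
v_i = (se_zy,i² + β_i² se_zx,i²)/b_zx,i² and covariance
V[i,j] = r_ij √(v_i v_j); with uncorrelated instruments this is exactly
inverse-variance weighting of the ratios. Exposure effects are per SD of
inverse-rank-normalized protein; outcomes are log-odds, so exp(β̂) is the
odds ratio per protein SD.

HEIDI outliers: the reference is the instrument with the smallest exposure p
(it cannot be removed); d_i = β_i − β_ref with delta-method variance
including the LD-induced covariance 2 r √(v_i v_ref); instruments with
two-sided p(d_i) < 0.05 are removed and the model re-estimated.

Calibration: the GSMR test itself holds its nominal size (type-I error
≈ 0.05 in the null simulations). The *sequential* procedure including HEIDI
is mildly anticonservative (≈ 0.06–0.07 at α = 0.05) because removing
ratio-discordant instruments under the null shrinks apparent heterogeneity;
this is a property of any consistency filter, is shared by the upstream
tool, and is reported separately by the acceptance script.

BH FDR (< 0.01) is applied jointly across all protein–disease models
tested. Significant pairs then need a convincing disease signal at the locus
(min *P* ≤ 10⁻⁴), high LD between the exposure sentinel and the best
disease variant (r² > 0.8), and conditional-colocalization support
(max PP4 ≥ 0.8) for the **robust** verdict; each failure is recorded as its
own elimination reason.

## Mediator prioritization at trans loci

Local genes are those with TSS within ±500 kb of the sentinel (boundary
inclusive), ordered by distance with gene-id tie-break. Evidence classes:
(1) among the 3 nearest genes; (2) the sentinel is the gene's cis-eQTL
sentinel, tags it at r² ≥ 0.8, or sits in a supplied credible set; (3) a
user-supplied interaction table links the gene to the trans-affected target
(no live database queries); (4) two-sided Fisher exact overlap between the
gene's and the target's annotation terms over the locus background (the
union of all local genes' terms), Bonferroni-corrected by the number of
local genes. The tier is the count of satisfied classes; ranking is tier,
then adjusted p, then distance. The two-sided Fisher convention (sum of
table probabilities ≤ the observed) matches `scipy.stats.fisher_exact` and
is verified against exhaustive hypergeometric enumeration.

## Synthetic-data generator

The fast path draws marginal standardized effects per LD block as
b̂_std ~ MVN(Rβ, R/N) — the exact sampling distribution of marginal OLS
estimates for a variance-1 trait in linkage equilibrium with the block —
then converts to per-allele scale (divide by √(2f(1−f))), giving
se = 1/√(2f(1−f)N) by construction. LD is block-diagonal AR(1)
(r_ij = ρ^|i−j|, default ρ = 0.8, blocks of 50 variants 2 kb apart, blocks
10 Mb apart so loci never merge across blocks). Between-cohort heterogeneity
adds N(0, τ²) to each cohort's causal effect. Disease outcomes use the
liability model: under vertical pleiotropy the disease log-odds effect at
each protein causal variant is θ·β_protein (so the MR estimand is exactly
θ); the `ld_confounded` mode instead plants an independent disease effect on
a variant in LD with the protein signal — the case HEIDI and conditional
colocalization must flag. Case-control standard errors use
se = 1/√(2f(1−f)·N·φ(1−φ)) with φ the case fraction.

A slow path simulates individual haplotypes with a Markov copying chain
(exact ρ^|i−j| dosage correlation at block-constant allele frequency) and
runs per-variant OLS; it cross-validates the fast path in the tests.

Default study conditions: 11 cohorts totalling 14,824 participants (the
per-cohort split is a realistic decreasing sequence 3,500…600 chosen once),
eQTL N = 30,000, disease GWAS 50,000 cases / 100,000 controls (typical of
current immune-disease meta-analyses, and large enough that the top disease
variant pins down the shared causal variant), planted standardized effects
0.09–0.18 (cis z ≈ 10–15 at study size), θ = 0.3.

What the generator does *not* emulate: realistic human LD maps, allele
frequency spectra, population structure or relatedness, imputation error
correlated across cohorts, assay batch effects, or case-control sampling
biases. Passing the recovery tests therefore demonstrates correctness of
the estimators under their own sampling assumptions, not robustness to
those real-data complications.

## Problem sizes in the test and acceptance runs

The suite is sized for a desk-scale machine: 10⁶ null cohort-tests (250k
variants × 4 cohorts) for meta calibration; 2,000 null replicates for MR
type-I error; 100–300 replicates for each recovery rate (at which the
binomial noise on a 95–99 % rate is well below the asserted margins);
200-variant regions for colocalization; the bundled pipeline uses 200
variants in 4 LD blocks. The full test suite runs in about a minute and the
acceptance script in about half a minute on one CPU.

## Known limitations

* Single-causal-variant assumption in each coloc pass (mitigated, not
  removed, by conditioning).
* The approximate conditional solve fixes residual variance at 1; for loci
  explaining a large trait fraction the joint SEs are slightly conservative.
* HEIDI's sequential use inflates the MR test size a little (see above).
* The GLS/GSMR equivalence is asserted against this package's own
  specification of the estimator, not against the external implementation.
* No support for overlapping samples between exposure and outcome GWAS, nor
  for binary exposures.
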