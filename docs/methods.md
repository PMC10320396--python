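# Methods

This note documents the models, estimators, numerical choices, and
simulation design behind xwaskit, and what the passing test suite does and
does not establish about behavior on real data.

## Per-probe causal inference (SMR + HEIDI)

The pipeline follows the two-sample summary-data Mendelian randomization
design: SNP–exposure effects (b_zx, the cis-xQTL effects on a molecular
level) come from one cohort, SNP–outcome effects (b_zy, the GWAS effects)
from another, and LD is estimated from a reference dosage panel. The two
cohorts are treated as non-overlapping, so cross-cohort covariance terms
are zero throughout. Case-control outcome effects must be supplied as (or
converted to) log odds ratios; the reader performs the conversion when the
effect column holds odds ratios.

Harmonization re-expresses all three sources on the xQTL effect allele:
swapped alleles flip the effect sign and reflect the frequency, panel
columns oriented to the other allele contribute sign-flipped LD rows,
strand-ambiguous (A/T, C/G) SNPs are dropped unconditionally (frequency
cannot resolve strand near MAF 0.5), and any SNP whose minor-allele
frequencies disagree by more than 0.15 between two sources is dropped.
Every rule increments a named counter that the run log reports, so filter
attrition is auditable.

Key analysis parameters (SmrConfig), with defaults chosen to match
standard SMR practice:

| parameter | default | meaning |
|---|---|---|
| cis_window_bp | 2,000,000 | max distance probe–SNP |
| instrument_p | 5e-8 | top-instrument xQTL p threshold |
| heidi_select_p | 1.57e-3 | xQTL p for admitting HEIDI instruments (χ²₁ > 10) |
| heidi_min / heidi_max | 3 / 20 | HEIDI instrument count bounds |
| prune_r2_high / low | 0.9 / 0.05 | LD pruning against the top SNP |
| freq_mismatch | 0.15 | max pairwise MAF disagreement |
| heidi_adjust_floor | 0.01 | HEIDI p above which no penalty applies |

The 1.57×10⁻³ threshold is interpreted as the instrument-admission
threshold for HEIDI (its conventional meaning); it is not a post-hoc filter
on HEIDI p-values.

HEIDI forms Wald ratios b_i at the top SNP and each selected instrument,
takes differences d_i = b_i − b_top, and standardizes them with the
delta-method covariance

    Cov(b_i, b_j) = r_ij (se_zy,i se_zy,j + b_i b_j se_zx,i se_zx,j) / (b_zx,i b_zx,j).

T_HEIDI = Σ (d_i / sd_i)² is distributed as Σ λ_k χ²₁ with λ_k the
eigenvalues of the correlation of d. A ridge of 1e-8 is added to the
diagonal of Cov(d) before standardizing; if the matrix is still not
positive semi-definite the probe is reported with p_HEIDI = NA rather than
a fabricated value. Note that the d_i are correlated through the shared
top-SNP ratio even when the instruments themselves are uncorrelated, so
the plain χ² tail is only the limit of a vanishingly precise top
instrument.

**Weighted-tail evaluation.** The default method is exact Imhof
characteristic-function inversion (a single deterministic quadrature),
which agrees with a 10⁶-draw Monte-Carlo oracle to within Monte-Carlo
noise (worst p-ratio ≈ 1.05 over random AR(1) spectra). The cheaper
Satterthwaite two-moment approximation is available via
`heidi_tail_method="satterthwaite"`; it was measured optimistic by up to a
factor ~2 at p ≈ 10⁻³ for concentrated spectra, which is why it is not the
default — HEIDI p-values near the 0.01 penalty floor deserve an accurate
tail. A fixed-seed Monte-Carlo mode exists for cross-checks. Equal
eigenvalue spectra short-circuit to the closed-form χ² tail in all
deterministic modes.

Tie-breaking for the top instrument is deterministic: smallest p_zx, then
largest |z_zx|, then smallest position. HEIDI candidates are pruned
greedily in that same order, so near-duplicate pairs (r² > 0.9) keep their
better-powered member.

## HEIDI-penalized p-values and gene-level combination

p′_SMR = min(1, p_SMR / min(p_HEIDI/0.01, 1)). The cap at 1 keeps the
output a probability; probes whose HEIDI was not run (fewer than 3 usable
instruments, or a numerical failure) are not penalized, and keep
nsnp_HEIDI = NA so downstream users can filter them if they prefer.

The Cauchy combination is evaluated as T = Σ wᵢ cot(π pᵢ), using the
identity tan((0.5 − p)π) = cot(πp), which preserves full relative
precision at both ends of (0,1) and reduces to the 1/(πp) tail expansion
automatically; inputs are clipped to [1e-300, 1 − 1e-15]. The far upper
tail of the combined statistic uses atan2(1, T)/π. Suggestive and
Bonferroni flags use strict inequalities; the gene-level table header
records both denominators (probes tested, genes mapped) because scans of
different granularities legitimately use either.

## Multi-study concordance

The p-value-based pattern-mixture model: t = −2 ln p is χ²₂ under the
null; each study's alternative is a scaled χ²₂ whose scale is estimated as
(mean of the top ⌈alt_props·G⌉ statistics)/2, floored at 1 + 1e-6. This
top-tail estimator is deliberately crude — it carries an upward selection
bias when the true alternative fraction differs from alt_props (measured
≈ +40% at scale 8 with a matched fraction) — but pattern-weight recovery
and posterior precision are insensitive to that bias at the scales tested
(π̂ within 0.002 of truth, PP>0.95 precision 0.997 at G = 2×10⁴, J = 3,
scale 10). EM runs over the K = 2^J pattern weights with the component
densities held fixed, entirely in log space (log-sum-exp), initialized at
0.9 mass on the all-null pattern; the observed-data log-likelihood is
non-decreasing by construction and asserted in tests. alt_props defaults
to 10⁻³ per study (the conventional choice for well-powered scans) and is
configurable per study; a sweep subcommand reports the sensitivity of the
PP > 0.95 call count to it. On the strongly-signalled synthetic bundle the
sweep saturates (identical counts across three decades); the
non-decreasing behavior is what the pipeline asserts. Between-study
correlation from sample overlap is **not** modeled — patterns are
conditionally independent across studies — a known limitation shared with
p-value-based mixture analyses generally.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) via scipy's exact survival
function, validated against a rational-arithmetic enumeration oracle for
all universe sizes ≤ 25. The universe is either an explicit gene list or
a bare size (default 54,619); with a list, query and sets are intersected
with it first. MHC exclusion removes genes annotated in
chr6:[25,000,000, 35,000,000) — half-open by convention so a gene at
exactly 35 Mb is kept; genes without coordinates are kept and logged.
BH-FDR comes from statsmodels.

## Synthetic data: what it emulates and what it does not

Each cis region is a Gaussian-copula haplotype model: latent AR(1)
normals (default ρ = 0.8) thresholded at the MAF quantile; two independent
haplotypes sum to a dosage. The implied dosage correlation is computed
analytically via Owen's-T bivariate normal orthant probabilities
(cross-checked against quadrature to 1e-12), so LD truth is exact.
Defaults: 30 SNPs at 2 kb spacing, MAF ~ U(0.1, 0.5), n_ref = 500.

Phenotypes are standardized, so effects are per-SD: x = b_zx g_c + e,
b_zx = 0.5 (a strong cis-xQTL, 25% of variance); causality y = b_xy x + e
with b_xy = 0.3; pleiotropy adds a direct effect of the same variant
(indistinguishable from causality by design — HEIDI should not reject);
linkage drives the trait from a second SNP with dosage correlation closest
to 0.6. The linkage trait effect is set to b_zx·b_xy so its GWAS signal
matches the causal scenario's. Cohort sizes default to n_xqtl = 30,000 and
n_gwas = 100,000.

The fast path draws marginal estimates from β̂ ~ N(R β_marg, D R D/n),
with D the per-SNP residual SDs — exactly the covariance a per-SNP
least-squares scan has, and exactly what HEIDI assumes, so calibration
statements are clean. The slow path simulates individuals and runs the
regressions; a two-sample KS test confirms the two paths agree in
distribution, making the slow path the oracle for the fast one. The
case-control study in the fixture bundle is emulated by exponentiating the
quantitative-trait effects into odds ratios with the same SE — an
approximation that exists to exercise the log-OR reading path, not a
liability-threshold simulation.

All randomness derives from one master seed via
`SeedSequence([master, *tags])` with documented integer tags per
region/study/purpose, giving byte-identical reruns.

Not emulated: realistic human LD maps (AR(1) has no long-range structure
or LD blocks), imputation noise, population stratification, allele-coding
errors, sample overlap between cohorts, or panel–cohort LD mismatch.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated assumptions, not robustness to those real-data
pathologies — the HEIDI penalty's behavior under panel mismatch, in
particular, is exactly the situation the smooth penalty (rather than a
hard p_HEIDI filter) is designed to soften, and is not stress-tested here.

## Fixture bundle and problem sizes

The default end-to-end bundle is 200 probes (100 causal, 50 linkage, 50
null; 25 SNPs each) × 3 studies sharing one xQTL dataset and LD panel with
independent GWAS draws, one designated planted shared gene, ten two-probe
genes, ten unmapped probes, a 10,000-gene universe, and one planted gene
set (20 of 30 members causal) among nine random sets. Calibration studies
use 200–2,000 replicate regions per scenario and G = 2×10⁴ genes for the
concordance model; these sizes give Monte-Carlo standard errors well below
the asserted margins while keeping the full suite fast on a single CPU.

## Degenerate inputs and edge policy

b_zx = 0 is an undefined instrument (error); b_zy = 0 yields b_xy = 0 with
se = se_zy/|b_zx|. SMR p-values are floored at 1e-300 (χ²₁ survival
underflows near z ≈ 38). T_HEIDI < 1e-12 returns p = 1 exactly. Probes
with zero xQTL SNPs are retained by the reader but flagged unusable.
Duplicate SNP ids within a table are an error (multi-allelic sites are
rejected, not guessed at); allele sets that disagree between sources
beyond a swap are dropped and counted. Monomorphic panel SNPs have
undefined r and are excluded during harmonization.
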