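# Methods

This note documents the models, assumptions, parameter choices, and known
limitations behind `sexbias`, stage by stage, and what the synthetic-data
studies do and do not demonstrate.

## Summary-statistics model

The atomic record is one variant's association in one stratum: effect-allele
frequency, log-odds effect `β`, standard error, p-value, sample size,
imputation quality, and a per-cohort sign string. Linear-mixed-model output
is rescaled to the logistic scale by dividing `β` and `se` by `μ(1−μ)` (`μ`
the case fraction), which leaves z-scores and p-values invariant; the
rescaling is exact only to first order, which is the standard convention for
mixed-model case-control GWAS. Effective sample size is `4·N·v(1−v)` with
`v` the case fraction; parental-proxy cohorts contribute `N_eff/4`,
reflecting the diluted phenotype.

Cohorts are combined by inverse-variance fixed effects. Admixed cohorts use
DerSimonian–Laird random effects:
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, weights `1/(se² + τ²)`; when
`Q ≤ k−1` this collapses to the fixed-effects result, and the
random-effects `se` can never undercut the fixed-effects one. Alleles are
harmonized by EA/OA swap then strand complement; strand-ambiguous variants
(A/T, C/G) with EAF in [0.4, 0.6] are unresolvable and dropped with a log
entry.

The sex-heterogeneity test is a z-test on the effect difference with an
optional cross-stratum overlap correlation `ρ` (default 0: female and male
strata are disjoint samples; the parameter exists because meta-analysis
tools support overlap correction). p-values are computed from z via
log-scale survival functions so that variants beyond `p ≈ 1e-300` neither
overflow nor collapse; `log10p_from_z` is exact arbitrarily far into the
tail.

Post-meta QC keeps variants present in a designated anchor cohort, with
≥ 90% cohort coverage, and with cross-cohort EAF deviation ≤ 0.2 among
designated cohorts; every drop records a machine-readable reason.

## Locus discovery

Qualifying variants (`p < 1e-5` in either sex) are merged by transitive
1 Mb chaining — two qualifying variants join a cluster when within 1 Mb, and
membership is transitive — because window anchoring is otherwise undefined.
Clusters are split into signals by greedy clumping on ascending p at
`r² < 0.01`, with p-ties broken by (chrom, pos) so output is independent of
row order. A configurable major-effect region (an APOE-like ±5 Mb span) is
masked before clustering.

Signals are retained when genome-wide significant in one sex with nominal
heterogeneity, or genome-wide in the heterogeneity test itself. A signal is
dropped when its lead tags (r² > 0.01) a common (MAF > 1%) catalog variant
that is more significant in the same sex but itself not sex-heterogeneous —
the catalog must supply its own heterogeneity p for this rule to fire
(a warning is emitted otherwise). One signal per locus survives. The
cross-sex effect-magnitude ratio ≥ 1.5 is checked as an assert-and-warn, not
a hard filter, because empirically it held for everything the other filters
retained; a hard-filter switch exists (`ratio_rule="drop"`). Opposite-sign
effects count as infinitely discordant. Novelty is classified against a
catalog by distance (1 Mb) then LD (r² 0.01), with a manual override list
for variants ruled to be novel independent signals. Cross-ancestry
consistency combines each sex across ancestries by fixed effects and asks
whether the heterogeneity p improves; variants absent from the second
ancestry are labeled `eur_only`. Locus spans are reported as lead ±1 Mb to
match the colocalization window convention.

## PWAS engine

Weight training residualizes abundance on covariates, screens heritability
by a permutation p-value of 5-fold cross-validated ridge predictive r²
(default 200 permutations; keep when `p < 0.01`; note the permutation p is
bounded below by `1/(n_perm+1)`, so at least 100 permutations are needed for
the screen to be passable), then compares top1, lasso, elastic net, and
ridge — ridge standing in as the dense BLUP-like model — by 5-fold CV r² and
refits the winner on all data. If the winner shrinks every weight to zero,
top1 is substituted so a valid model always has ≥ 1 nonzero weight. A CSF
convention gate trains weights for strata whose lead cis variant reaches
5×10⁻⁸, adding the opposite sex when exactly one sex qualifies.

The association statistic is `z = wᵀz_gwas / sqrt(wᵀRw)` over the variants
shared with the GWAS; `R` is shrunk toward the identity (λ = 0.1) and
eigenvalue-floored to positive definite. Genes retaining < 50% of absolute
weight mass are refused rather than silently reported. FDR is
Benjamini–Hochberg within each GWAS × weights × tissue combination (a
pooling flag exists). Sex-bias classification requires every available
opposite-sex combination to be direction-discordant or `p > 0.05`, then
demotes all proteins at a locus whose most significant protein is not
sex-biased. Cross-ancestry consistency uses sample-size-weighted z
combination; proxy-exclusion sensitivity requires concordant direction with
`p < 0.05` in the discovery sex and `p > 0.05` opposite.

## Colocalization, SMR, HEIDI-like

Wakefield log-ABFs (`sd_prior` 0.2 for quantitative traits, 0.15 log-odds
for case-control) are summed over single-causal-variant configurations in
log space (logsumexp; the H3 term uses a stable log-difference). Default
priors are `p1 = p2 = 1e-4`, `p12 = 1e-5`; the adjusted mode re-runs with
`p12 = 5e-5` — a choice this package fixes since only "increased
probability" is specified — and the best PP4 across modes is kept with its
mode recorded. PP4 ≥ 0.7 is strong, ≥ 0.4 suggestive. Multi-signal loci are
not decomposed (no SuSiE-style regression); per-window analyses around
alternative index variants are the supported workaround, as in the
multi-tag locus views.

SMR is the Wald ratio with `z²_smr = z²_g z²_q/(z²_g + z²_q)` against
χ²(1). The LD-bias check is deliberately named `heidi_like`: instruments
with QTL `p < 1.6e-3` (≤ 20, excluding the top variant) give ratio
differences `d_i = b_xy(i) − b_xy(top)` whose delta-method covariance uses
LD-derived covariances between effect estimates within each trait; the
statistic `Σ z²_d` is referred to a Satterthwaite-matched scaled χ²
(`c = tr(C²)/tr(C)`, `ν = tr(C)/c`) rather than the original saddlepoint
approximation. Near-collinear instruments (|r| > 0.995) are pruned before
the test; fewer than 3 survivors means no test. Protein validation combines
FDR-significant SMR with non-significant HEIDI-like, and suggestive-or-
better colocalization, into both/smr_only/coloc_only/none.

## Gene priority scoring

Scoring is a pure function of a per-gene evidence ledger. Gene-specific QTL
types are eQTL/sQTL/pQTL; mQTL/haQTL/caQTL never score but set a locus-level
"epigenetic feature prioritized" flag. "More than one colocalization across
tissues or datasets" counts distinct (qtl_type, dataset) pairs — two
datasets of the same tissue count separately. GWAS-locus branches: >1
strong (PP4 ≥ 0.7) gene-specific colocalization → 1; PWAS gene with strong
matching-tissue pQTL colocalization → 1; exactly one strong → 2; else 3.
PWAS-locus branches add: strong matching-tissue colocalization → 1; strong
in the non-matching pQTL tissue while unavailable in the matching one → 1;
suggestive matching-tissue colocalization → 2, upgraded to 1 by any other
strong gene-specific hit; exactly one strong → 2; else 3. Score-3 genes
with nominally significant differential abundance upgrade to 2. Every score
records exactly one rule id; literature/missense overrides force score 1
with provenance, and excluded loci are dropped at list assembly. Scores are
monotone: added strong evidence can never worsen a score (property-tested
on random ledgers).

Differential abundance fits, per protein, a sex main effect adjusting for
diagnosis and covariates on all subjects, and a case-control analysis on
biomarker-defined (A-T- vs A+T+) subjects. The case-control analysis
defaults to a sex × status interaction — the reading adopted for "sex-biased
differential abundance across cases and controls" — with a per-sex-contrast
mode also provided; any sex × status cell under 10 non-missing observations
skips the protein with a log entry.

## Structural-variant locus dissection

Two-locus LD from unphased genotypes: allele frequencies come from the
genotype margins, and the haplotype frequency `f(AB)` solves the cubic
EM-stationarity equation within `[max(0, p+q−1), min(p, q)]`. With multiple
valid roots the multinomial likelihood decides (the root count is
recorded); if numerics yield no in-interval root, EM iteration is the
fallback. When the table has no double heterozygotes the estimate equals
direct haplotype counting exactly, and the cubic root agrees with the EM
fixed point to ~1e-12 on random tables. r² is invariant to allele
relabeling at either locus. Missing genotypes are pairwise-complete for LD
and mean-imputed for classifier features.

SV imputation treats the SV as a biallelic dosage (0/1/2 copies). Tag SNVs
with cubex r² > 0.1 are retained, ordered by r² (position tie-break). The
imputer is an SVC with polynomial kernel of degree 3, evaluated over 100
repeated stratified 70/30 train/test splits (the accuracy distribution is
kept) and refit on all data; the contract is the accuracy-vs-LD
relationship, not a particular margin algorithm. The "100 permutations" of
the original protocol is read as 100 repeated splits; a label-permutation
null is available through shuffled labels in the tests.

Conditional analyses regress an outcome on a variant plus covariates and a
conditioning dosage (logistic for binary outcomes). Conditioning on a
single best-guess imputed genotype under-corrects whenever imputation is
imperfect — residual SV information leaks through the tags — so
`sv_condition_matrix` builds the imputed genotype's full representation
(posterior class probabilities plus called-class indicators), which is the
conditional-mean construct that orthogonalizes tag leakage. Near-collinear
variant/condition pairs (r² > 0.99) are reported non-estimable rather than
silently dropped. Stratified analysis runs the same model independently per
stratum, flagging strata under 10 cases as underpowered. The locus pheWAS
regresses every aptamer on each variant passing MAC ≥ 10 and missingness
≤ 0.1, with a Bonferroni threshold of 0.05 divided by the per-tissue
aptamer count.

## Synthetic data: what it emulates, and what it does not

LD is a block copula: a latent AR(1) Gaussian per block, thresholded to
binary haplotype alleles. The latent autocorrelation is calibrated by
inverting the bivariate-normal orthant probability so the *realized*
adjacent-variant correlation equals the requested `within_block_r`; this
calibration is exact because all variants in a block share one allele
frequency, drawn per block from a 0.01 grid on [0.1, 0.9]. Blocks are
independent. This reproduces the features downstream stages consume —
within-block tagging, cross-block independence — but not realistic human LD
decay, allele-frequency spectra, imputation error, or relatedness; nothing
here validates behavior under mixed-model confounding.

Case-control GWAS has two modes. The default draws summary statistics from
the asymptotic normal law around the LD-induced marginal effect with
`se = 1/sqrt(N v(1−v) 2f(1−f))`, making null z exactly standard normal
(hence exactly uniform p — calibration results on this mode test the
pipeline, not the asymptotics). The individual-level mode simulates
genotypes and logistic phenotypes (with two APOE-like dosage covariates)
and fits per-variant logistic regressions; the two modes agree at n = 5k in
the tests. Proxy cohorts halve planted effects (a one-parent transmission
heuristic, configurable — not an empirical claim) so the `N_eff/4`
down-weighting is exercised realistically. Proxy phenotypes follow the
parental-history rules: the analysis sex uses its same-sex parent's status,
subjects reporting the other parent affected are excluded, and parents
younger than 65 are phenotype-unknown.

QTL simulation plants cis effects on a standardized abundance trait within
±1 Mb windows; causal variants either coincide with a GWAS effect variant
(ground-truth colocalizing) or sit elsewhere in the same block, and the
truth label rides along in metadata. The SV generator draws tag alleles
conditionally on the SV haplotype to hit target r² exactly in expectation,
raising an infeasibility error naming the `[max(0, p+q−1), min(p, q)]`
bound when frequencies cannot support the target.

## Reference problem sizes (the study conditions)

- Heterogeneity calibration: 2000 variants, n = 20k per stratum, shared
  effects on 50 variants; the 95% binomial band at α = 0.05 is
  [0.040, 0.060].
- Locus recovery: 20 replicate genomes, 25 blocks × 12 variants, 10
  female-biased loci (lead z ≈ 11 in women, cross-sex ratio 2.0 — a strong
  genome-wide locus, as loci clearing 5×10⁻⁸ with margin in a ~100k-N_eff
  GWAS are), 10 unbiased genome-wide loci, 5 null blocks. Expected behavior:
  ≥ 9/10 biased retained and ≤ 1 unbiased admitted on average (the
  heterogeneity filter admits unbiased loci at its nominal 5% rate).
- PWAS oracle: 200 genes × 1000 samples × 8 cis variants; truth weights are
  used on both the summary and individual-level paths so the comparison
  isolates the burden statistic.
- Colocalization behavior: 50-SNP AR(0.9) loci, causal z = 8, n = 10k per
  trait, 100 shared- and 100 distinct-causal replicates (distinct variants
  8 SNPs apart, r ≈ 0.43).
- SMR/HEIDI-like: 2000 null SMR draws; 100 homogeneous and 100
  two-causal-variant loci (20 SNPs, AR(0.9), QTL z = 12, GWAS z = 7).
- SV dissection: 50 replicates; imputer trained on 431 samples (a
  long-read-cohort size) over a 20-SNV consensus-style tag panel spanning
  r² 0.97–0.12 (including the 0.97/0.75/0.27 index geometry), applied in a
  3000-sample proteogenomic cohort; protein effect 0.5 SD per SV allele.
  With near-perfect imputation, conditional removal of the tag association
  sits at the 95% ceiling imposed by uniform p > 0.05.

These sizes keep the full suite under a minute of simulation while leaving
every property comfortably measurable; all are overridable parameters.

## Known limitations

- No genomic-control/LDSC intercept correction or sample-overlap
  estimation; `ρ` must be supplied if strata overlap.
- No conditional/joint multi-signal dissection or fine-mapping; clumping is
  greedy and marginal.
- Colocalization assumes a single causal variant per trait per window.
- The HEIDI-like test is a Satterthwaite approximation, expected to be
  slightly conservative (homogeneous-locus retention runs above 90% at a
  5% level).
- Enrichment takes gene sets, PPI edges, literature and druggability tables
  as files; no ontology propagation or semantic clustering of terms.
- The gene-ratio denominator is the number of query genes mapped to the
  universe; fold filters depend on this convention. A fold definition that
  reports < 1 alongside significant overrepresentation (as some published
  tables do) is not reproduced here; fold is `(k/n)/(K/N)`.
- Aptamer QC, TMT normalization, and surrogate-variable estimation are out
  of scope; covariates arrive precomputed.
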