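# Methods

`fritassoc` implements the analysis chain of a multi-population candidate-gene
study of a butterfly metapopulation sampled from two landscape types
(northern fragmented vs. southern continuous). This note records the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic-data generator does and does not emulate.

## Study design assumed throughout

Five regional populations (AL, UP fragmented; GO, OL, SA continuous), each
sampled as ~50 full-sib larval families with one scored offspring per family
by default, genotyped at 49 bi-allelic SNPs and phenotyped for a 21-trait
life-history battery (9 development traits scored in both sexes, 6 male
adult traits, 6 female adult traits).

## Genotype quality control (`qc`)

Per population and locus we compute genotype counts, the folded minor-allele
frequency (minor designation is global and ties break alphabetically), and a
Hardy–Weinberg equilibrium p-value. The HWE test is the exact conditional
test: given the allele counts, the heterozygote count follows

P(n_Aa | n, n_A) ∝ n! 2^{n_Aa} / (n_AA! n_Aa! n_aa!),

and the p-value sums the probabilities of all heterozygote counts no more
probable than the observed one (mid-p off; a 1-df chi-square option is
exposed). The exact test was chosen because per-population sample sizes
(~35–60) make the asymptotic test unreliable at low MAF. HWE p-values are
Benjamini–Hochberg adjusted per population across loci — the smallest
defensible multiplicity family. A population fails a locus when the adjusted
HWE p < 0.05 or the MAF < 0.05 (all-missing and monomorphic columns count as
MAF failures: they carry no association information). The two-tier rule:
failure in ≥2 populations drops the locus; failure in exactly one masks that
population's calls to missing; otherwise the locus is untouched. The rule is
idempotent, and masking only ever sets calls to missing. Cluster-plot
criteria from the genotyping chemistry are not computable from calls and are
accepted only as a pre-filtered input.

## Trait reduction (`traits`)

Proportion-valued traits (flight probability, hatch rate, host-plant
preference) are arcsine-square-root transformed. Each battery is restricted
to complete cases and reduced by PCA on the Pearson correlation matrix —
the correlation (not covariance) matrix, because the eigenvalue-greater-
than-one retention rule (Kaiser criterion) presupposes unit-variance traits.
A component is retained iff its eigenvalue exceeds 1 AND its proportion of
variance exceeds 0.1, applied literally. Component signs are fixed by making
each component's largest-magnitude loading positive, so reruns and
downstream effect signs are reproducible. Retained component scores are
screened with Shapiro–Wilk tests at α = 0.01; failures are flagged, not
excluded (exclusion is left to configuration). No imputation is performed.

## Mixed-model association scan (`association`)

Every QC-retained locus × retained component × inheritance encoding is fit
with a linear mixed model: fixed effects sex (development components only),
environment type, genotype, and environment×genotype; random intercept for
population, which is nested in environment because environment is itself a
fixed effect. The pilot variant adds a family random intercept (families are
uniquely labelled, hence nested in population). Encodings from minor-allele
counts c: additive c, dominant 1{c≥1}, recessive 1{c=2}, over-dominant
1{c=1}. Models are fit by REML (statsmodels MixedLM); fixed-effect p-values
are Wald tests, with a likelihood-ratio option. Interaction terms with Wald
p ≥ 0.05 are removed and the model refit (minimal adequate model); the
decision is recorded per cell. Raw genotype p-values are BH-FDR adjusted
across the entire fitted grid; the family size equals the number of fits
that actually succeeded, and every skipped cell (constant encoding after
masking, singular fit) is logged with its reason.

Numerical care: with two environments and at most five populations, REML
variance estimates routinely hit the zero boundary. Boundary fits are
reported with a flag rather than discarded — at an exact boundary the fixed
effects coincide with OLS. The default L-BFGS optimizer can also report
convergence at a spurious optimum whose random-effect covariance is
collapsed (< 1e-12) with corrupt fixed effects; such fits are cross-checked
against derivative-free optimizers and the best restricted likelihood wins.
Variance-component (pilot) fits always compare two optimizers this way.

## Directed permutation test (`envdiff`)

Populations form two fragmented groups and two continuous groups (GO and OL
are pooled, matching the study's grouping; other layouts need an explicit
mapping). Group frequencies are ML allele-count proportions of the globally
designated minor allele — not refolded per group, so the 4-vector of
differences (f1−c1, f1−c2, f2−c1, f2−c2) is coherently signed. A locus is
tested only when all four differences strictly share a sign (zeros break
consistency). Sample labels are permuted jointly across the four groups,
preserving group sizes; missing calls travel with their sample and each
group's frequency uses its non-missing calls only. A permutation counts as
extreme when every element of its difference vector, signed in the observed
direction, reaches the corresponding observed element; the add-one rule
(count+1)/(n_perm+1) avoids zero p-values. A min-of-four scalar variant is
exposed for sensitivity analysis. Family-wise control is Bonferroni at the
1% level over all scanned loci (not only the consistent ones — the
conservative choice), with a strict-inequality threshold.

**Calibration caveat.** The nominal p of this procedure is a
direction-selected conjunction of four strongly correlated one-sided tail
probabilities. It is faithful to the published construction, but it is not a
uniformly distributed null p-value: over simulated null loci (all
populations sharing one MAF), about a third of loci are sign-consistent by
chance and the fraction that is consistent with nominal p < 0.05 is ~0.26
(~0.10 for the min-of-four variant, which still carries a factor ~2 from
direction selection). Verdicts at the Bonferroni-corrected 1% level are far
less affected, but nominal p-values near conventional thresholds should be
read as descriptive rankings, not calibrated error rates. The test suite
asserts the nominal-level calibration at face value and that assertion fails
by design; the enumeration check against the exact permutation distribution
passes, confirming the implementation computes exactly the intended
quantity.

## Pairwise FST (`fst`)

Weir–Cockerham variance-components theta, implemented for general
multi-allelic data: per locus and allele the among-population (a),
between-individual (b) and within-individual (c) components are computed
from sample sizes, allele frequencies and observed heterozygote-carrier
proportions; the multi-locus estimate is Σa / Σ(a+b+c) (ratio of averages).
Loci monomorphic across the pair contribute zero to both sums; negative
estimates are reported unclamped. Standardized FST divides theta by its
maximum given the observed within-population diversity, computed
operationally by recoding every population's alleles to private labels
(keeping genotype counts and missingness) and recomputing theta — so no
external program is needed. Significance is a permutation test shuffling
samples between the two populations (add-one p), with a vectorized
bi-allelic path that is verified against the general implementation.

## Power analysis (`power`)

The setting is indirect association: a genotyped marker in LD (D′ scale by
default; an r² flag exists) with an unobserved causal variant explaining a
fraction V of trait variance. With allele-frequency correlation
r = D′·Dmax/√(p_m q_m p_c q_c), the marker captures r²·V under an additive
causal architecture (1-df test). Under the dominant model the causal locus
acts with complete dominance; its variance splits into additive and
dominance parts (Falconer decomposition at increaser frequency p_c), the
marker captures r²·Va + r⁴·Vd — dominance attenuates twice as fast in LD —
and the marker test is the 2-df genotypic test. Power uses the
likelihood-ratio noncentrality λ = N·ln(1/(1−E)) and the noncentral
chi-square; required N is the smallest integer reaching the target power,
which brackets the continuous solution (two of the six standard settings
fall within one unit of an integer boundary, so the ceiling can differ from
a rounded value by 1). α defaults to 0.05. The analytic power was verified
against Monte-Carlo regression simulations (agreement within ~2 binomial SE
at 3,000–4,000 replicates across additive and dominant settings).

## Hierarchical clustering (`cluster`)

Genotypes are encoded as minor-allele counts, missing cells are mean-imputed
per locus (the minimal-assumption completion preserving locus means), and
samples are clustered agglomeratively with Euclidean distance and complete
linkage — the defaults of the R heatmap routine this mirrors; both are
exposed as flags. Samples are sorted by id before clustering so ties, and
hence the leaf order, are deterministic. Complete linkage is outlier-
sensitive: with strongly environment-divergent loci the two-cluster cut
separates environments with high purity in most but not all draws.

## Synthetic data (`simulate`)

The generator emulates the study design, not any particular dataset. Per
family, two parents are drawn at Hardy–Weinberg proportions for the
population's per-locus MAF and offspring inherit one uniformly chosen allele
from each parent, reproducing the full-sib genotype covariance the family
random effect absorbs (parents are unobserved). Per-population MAFs are a
shared base draw (U(0.1, 0.5)) plus small per-population jitter (±0.03);
environment-divergent loci are specified directly as (fragmented MAF,
continuous MAF) pairs, which is exactly the structure the directed test
detects, and a focal locus can be pinned to one frequency everywhere
(default fixtures pin causal loci at 0.3, the study's typical focal-SNP
frequency). Traits follow the generative mirror of the fitted model —
intercept + sex + environment + encoded-genotype effects (in residual-SD
units) + environment×genotype + shared latent factors (inducing the
within-battery correlation that makes PCA reduction meaningful) + family
and population deviates + Gaussian residual; proportion traits pass through
a logistic squash into [0, 1]; sex-specific traits are emitted as missing
for the other sex. Default noise scales: residual SD 1, family SD 0.5,
population SD 0.3, genotype missingness 2%.

Not emulated: inter-locus LD (the study reports LD extending over thousands
of base pairs, but gives no pairwise LD for its markers, so loci are drawn
independently and tests involving multi-locus structure should be read
accordingly); genotyping-intensity cluster artefacts; pedigree beyond
full-sib families; mitochondrial structure; real trait distributions (tails,
floors/ceilings of count traits). Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed generative model,
not robustness to real-data pathologies.

## Problem sizes used in the checks

The packaged fixture is 5 populations × 50 families × 1 offspring, 49 loci,
21 traits (250 samples) — the study's scale. Recovery of a planted dominant
causal SNP is scored over 50 fixture seeds with the dominant-scheme scan of
the development components; null calibration of the scan uses >1,000 fits
across 11 null fixtures; the directed test's null behaviour uses 500 null
loci at 2,000 permutations; end-to-end determinism runs the full pipeline
twice at 20,000 permutations and compares output checksums. The CLI default
for the directed test is 10⁶ permutations, matching the analysis the
pipeline reproduces.
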