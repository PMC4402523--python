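# Methods

## The base-composition phenotype

For a set of biallelic SNPs with reference base R_j and alternative base B_j,
an individual's phenotype is the base composition of the alleles it carries:

    frac_X = (number of carried alleles equal to X) / (2 * n_sites_used)

A homozygous-reference genotype contributes two R_j alleles (weight 1 toward
R_j), a heterozygote one of each (weight 0.5), a homozygous-alternative two
B_j alleles (weight 0). Sites with a missing genotype are excluded from that
sample's denominator — a choice the source procedure leaves open; it is the
only convention under which the four fractions sum to exactly 1 for every
sample regardless of missingness. [A] (frac_a) is used as the scanned trait;
by PR2 the choice among [A], [T], [C], [G] is immaterial.

Site filters run in the order biallelic-SNP → autosome → call rate
(default ≥ 0.8) → MAF (default ≥ 0.05, computed on the overall retained
sample set after the call-rate filter) → optional HWE. HWE deviation is
reported (1-df chi-square by default; a conditional exact test on the
heterozygote count is available for small samples) but does not remove sites
unless an alpha is configured, since deviation rates are informative output
rather than a default exclusion rule here. X/Y/mitochondrial records are
excluded by default: the analyses are autosomal, and heterozygote weighting
on sex chromosomes would need sex information the inputs do not carry.
Multiallelic records are dropped, not decomposed — the phenotype's
allele-pair bookkeeping assumes exactly two bases per site. Coordinates are
0-based half-open internally; VCF positions convert at the boundary.

## Parity metrics

PR2 is a qualitative rule; the scalar statistic reported is

    pr2_deviation = |[A] - [T]| + |[G] - [C]|,

zero iff the strand satisfies PR2 exactly, together with the standard skews
(A−T)/(A+T) and (G−C)/(G+C). N and all other non-ACGT IUPAC symbols are
excluded from denominators (uniform, conservative extension of excluding N);
soft-masked lowercase bases count as their base, since masking is annotation,
not composition. Composition is always reported on the strand as given.

## Genome scans

Both scans treat frac_a as a quantitative trait over n individuals and test
each SNP's dosage with a 1-df F statistic.

*Linear scan.* Per-SNP OLS, optionally with fixed covariates. F statistics
are the primary output; distribution-based p-values can be suppressed, as at
very large n with strong structure they stop being meaningful.

*Mixed-model scan (two-stage, EMMAX/P3D style).* Null model
y = Xb + u + e, u ~ N(0, σg² K), e ~ N(0, σe² I), with X = intercept +
PC2–PC6 of the column-standardized dosage matrix (PC1 is near-collinear with
the trait, so it is excluded from the covariates by default; the range is
configurable). The heritability ratio h² = σg²/(σg²+σe²) is estimated once
by REML: the kinship matrix is eigendecomposed, the profiled restricted
log-likelihood is evaluated on a 41-point grid in h² ∈ [0, 0.999] to bracket
the optimum (the surface can be multimodal), then refined by bounded scalar
minimization to xatol 1e-8. Every SNP is then tested by GLS with
V = h² K + (1−h²) I held fixed (whiten once, residualize, vectorized F).
Setting h² = 0 reproduces the covariate-adjusted linear scan exactly; an
identity kinship reduces GLS to OLS. Kinship is the VanRaden centered
cross-product ZZ'/(2Σp(1−p)) with per-variant mean imputation of missing
dosages (imputation is confined to kinship/PCA/scan design matrices; the
phenotype never imputes). An allele-sharing kinship is provided as a
cross-check. Eigenvalues are shifted by at most a numerical epsilon; a
kinship still indefinite after shifting is an error.

*Thresholds.* Bonferroni: alpha/m with its −log10 (0.05 over 7,003,981
tests gives 7e-9, −log10 = 8.1). Allele-switching simulation: start from a
pseudo-SNP perfectly fixed between the basal and derived groups (dosage 0
vs 2), flip the genotype in a uniformly chosen fraction p of samples, 1000
replicates per proportion p ∈ {0, 0.05, ..., 0.5}; proportions above 0.5
are rejected (mirror images). The source procedure does not state which
proportion/percentile defines the baseline, so the rule here is explicit
and configurable: the threshold is the 97.5th percentile of the F
distribution at the largest proportion at which the switched SNP remains
distinguishable from the fully randomized p = 0.5 distribution, and the
full per-proportion table is always returned so users can apply their own
rule. One statistical subtlety is asserted in the tests: at p = 0.5 the
flipped pseudo-SNP is marginally independent of the groups, but flipping a
without-replacement half couples its allele count to its residual group
alignment, so it is slightly more balanced than an unconstrained random SNP —
location, not exact distribution, is compared.

*Subsampling variance ratios.* For each site count k: resample k variants
without replacement, recompute frac_a, and decompose its variance into
between/(between+within) by one-way random-effects method of moments (MSB,
MSW, n0), clipped to [0, 1]; mean ± sd over replicates. The fraction grows
with k in structured data because the phenotype's site-sampling noise
(within groups) shrinks as 1/k while the group separation is fixed.

## The simulator

The generator provides the statistical structure the analyses assume, with
recorded ground truth; it is not a demographic inference tool.

*Spectrum.* 12 substitution rates constrained strand-symmetric,
r(X→Y) = r(comp(X)→comp(Y)) (6 free). `with_at_bias(b)` scales every rate
into {A, T} by b over a baseline of 1. Single draws choose the template
strand uniformly and report the substitution on the reference strand — the
generative content of the no-strand-bias explanation of PR2: under strand
symmetry the alt-base distribution is strand-independent, and tallies across
mutated sites satisfy [A] ≈ [T], [G] ≈ [C] on either strand.

*Population design.* Two groups: basal (n=50) and derived (n=100) by
default, at 10,000 biallelic SNPs. Site classes with the default
`private_fraction` of 0.4: 60% shared, 20% private to each group (before
MAF conditioning shifts the realized shares). Ancestral alt frequencies follow
a neutral-SFS-shaped law (density ∝ 1/x, truncated to [0.02, 0.98]); the
derived lineage's copy of shared variants and its private variants undergo
a bottleneck modeled as 40 generations of binomial (Wright–Fisher)
frequency drift at diploid size 100 — frequency-level drift, not
individual-based simulation, which is adequate for phenotype-level patterns
and fast. Genotypes are HWE draws within groups. Sites are accepted only if
the realized overall MAF is ≥ 0.05 and polymorphic, so the output passes
the default filters by construction. Reference bases follow a PR2-balanced
human-like composition (0.3, 0.2, 0.2, 0.3).

*The A&T-increase mechanism.* The shared spectrum has at_bias 2; the
derived lineage's private variants are drawn from that spectrum with the
AT rates boosted 3× (`derived_at_boost`). The boost is the package's design
choice: desk-scale prototyping showed that bottleneck drift alone with a
common AT-biased spectrum does not reproduce the derived > basal [A]
direction reliably — the bottleneck loses low-frequency (AT-enriched) alt
alleles at shared sites even as it fixes some private ones, and the two
effects nearly cancel at these sizes. Whether neutral demography alone can
generate the pattern is an open modeling question deliberately out of scope;
the boost encodes the alternative reading in which repair-efficiency
divergence shifts the derived lineage's effective spectrum. Under the
defaults the derived-minus-basal mean [A] difference is ≈ +0.008 with
across-seed sd ≈ 0.002 (z ≈ 4), so the direction is stable seed to seed.

*Null configuration.* `at_bias=1, bottleneck=None` is a panmictic
population: all variants shared, no drift, groups exchangeable, so the
Welch test on frac_a is calibrated. (A "no drift but group-private
variants" null would be anti-conservative for across-sample tests: the
realized between-group difference is then dominated by shared site-level
base-draw randomness, which the per-sample test does not see.)

*The bias-modifier locus and its power analysis.* The modifier is one SNP
with carrier frequency 0.3 in both groups. Carriers accrue extra
alternative alleles at a diffuse set of effect sites (fraction 0.85 of the
panel): per-allele alt probability 0.2 + 0.0065·d for modifier dosage d,
with alt bases drawn at the AT bias amplified by (1 + delta), delta = 11.
The diffuseness is forced by a real identifiability constraint worth
stating: the phenotype is an exact linear function of the scanned panel, so
a causal direction is scannable only while its excess genetic variance
(≈ 4.67 · effect_fraction · n_snps · slope²) stays below the
spiked-eigenvalue detectability edge of the panel (≈ sqrt(m/n) above the
eigenvalue bulk). Past that edge the modifier direction becomes PC2 and is
absorbed by the structure covariates and the kinship term. Since the
achievable squared signal-to-noise is proportional to the eigenvalue excess
times effect_fraction · ΔA² (ΔA = the AT excess of effect-site alt bases
over reference bases), recovery requires large panels and modest sample
counts. The defaults are calibrated for 90,000 SNPs × 100 samples:
eigenvalue excess ≈ 15 against a bulk edge ≈ 30, aggregate shift ≈ 0.9
within-group phenotype sd per modifier allele copy, giving mixed-scan F of
roughly 20–70 for the modifier against a maximum null F near 20; the
planted locus ranks in the top 5 in ≥ 90% of simulated datasets (observed:
40/40 across two independent 20-seed blocks, 38 of them rank 1). For other
panel sizes the slope should scale as sqrt(9e4 / n_snps). This constraint
is a genuine property of genome phenotypes computed from the panel being
scanned, and is the desk-scale analogue of why such scans want very dense
panels.

*Mutation accumulation.* One ancestor sequence (default 100 kb, uniform
composition — a ~50% GC, microbial-like genome, far from the AT-biased
stationary state so the A&T gain across mutation sites is well resolved),
10 lines × 200 substitutions at uniform unique positions via the spectrum.
Derived-line composition counts alt bases at each line's mutation sites;
the ancestor composition counts the reference bases at the same sites.

*Determinism.* Every generator consumes one integer seed through a single
numpy Generator; identical (config, seed) regenerate byte-identical VCF
output (asserted in the tests).

## Enrichment

Windows of size w are centered on each TAS position ([pos − w/2,
pos + w/2), clipped at chromosome bounds when supplied) and merged before
forming the in-window gene set, so clustered TASs do not multiply-count
genes; the per-SNP ≥ 2 (gene) / ≥ 3 (repair gene) tagging rules use
unmerged windows because they count tagging SNPs. A gene is in-window on
any overlap (full containment available) — any-overlap avoids excluding
long genes. The over-representation test is one-sided Fisher's exact on the
gene-level 2×2 table over the configured gene universe (default: all genes
in the annotation input); the hypergeometric tail identity is asserted in
the tests. Raw p-values are primary (no correction), with a
Benjamini–Hochberg column alongside. Annotation-term propagation up an
ontology graph is not performed; terms are used as annotated. Fixed 1 Mb
tiles with ≥ 5 TASs are tabulated separately for region-level reporting.

## Problem sizes

The repeated-seed analyses run at deliberately modest sizes chosen as the
package's own desk-scale study conditions: 100 seeds × 10,000 SNPs × 150
samples for the direction/null checks, 20 datasets × 90,000 SNPs × 100
samples for modifier recovery, 50,000 SNPs × 250 samples for the parity
summary. At these sizes the full test suite and the acceptance script each
complete in a few minutes on one CPU.

## Known limitations

- Frequency-level drift has no linkage, recombination, or selection; TAS
  positions are exchangeable, so region-level clustering arises only from
  signal strength, not LD structure.
- The derived-lineage AT-bias boost is a modeling commitment, not an
  inference; the package cannot distinguish it from purely demographic
  explanations and does not try to.
- The allele-switching baseline rule (percentile × proportion) is an
  explicit convention; published baseline F values derived from specific
  datasets are not reproduction targets.
- Mixed-model variance components are estimated once on the null model
  (two-stage approximation); per-SNP exact refits are not implemented.
- The phenotype-from-panel identifiability constraint above bounds what any
  scan can recover from aggregate composition phenotypes at small m/n; real
  data with millions of SNPs are far from the bound, small simulated panels
  are not.
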