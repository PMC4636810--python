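# Methods

## Study design and model

The package analyses a reciprocal cross between two inbred mouse
strains, the obese BFMI line and the lean B6N line. F1 animals of the
two cross directions (matBFMI: BFMI mother; patBFMI: BFMI father) are
autosomally identical heterozygotes, so three classes of signal
distinguish them: phenotype differences, total-expression differences,
and allele-specific expression (ASE) whose direction flips with the
cross. The last is the imprinting signature: a paternally expressed
gene transcribes the BFMI allele in patBFMI animals and the B6N allele
in matBFMI animals, so its BFMI-allele read fraction sits near 1 in one
group and near 0 in the other.

## ASE statistic

At an informative SNP (parental strains homozygous for different
alleles; the alternative allele re-anchored so that "alt" always means
the BFMI allele), each F1 individual with ref+alt = d high-quality
reads is scored

    s = sign(p̂ − 1/2) · sqrt(χ²),    χ² = (ref − d/2)² / (d/2) + (alt − d/2)² / (d/2)

which reduces to s = (alt − ref)/√d. The square root caps the leverage
of a single individual with an extreme deviation; the sign makes
opposite-direction imbalance in the two cross directions accumulate in
the group difference

    D = Σ_{matBFMI} s_i − Σ_{patBFMI} s_i

rather than cancel. Under balanced biallelic expression s is
asymptotically standard normal, so D has mean 0 and variance ≈ 6 with
three individuals per group; |D| grows like √d·|2p̂ − 1| per individual
under imbalance.

Assumptions: read counts at a site are exchangeable across individuals
within a group; no mapping bias toward the reference allele (the
statistic is symmetric, but input counts must be); sites are treated
independently (no haplotype phasing).

## Filter cascade

Stage order: informative-site selection → population coverage →
per-individual quality → within-group consistency → scoring/FDR. All
thresholds are exposed and default to the study values:

| parameter | default | meaning |
|---|---|---|
| min_pop_reads | 100 | total reads over all 10 samples (inclusive) |
| min_phred | 50 | per-sample call quality; `< 50` masks the sample |
| min_hq_reads | 5 | per-sample high-quality depth; `< 5` masks |
| max_group_sd | 0.20 | sample (n−1) SD of alt ratios within an F1 group, ratio scale |
| alpha | 0.05 | empirical FDR level |

A site enters scoring only when every F1 individual of both groups
passes the per-sample filters: group sums over unequal numbers of
individuals would not be comparable. Coverage for the population filter
is raw summed depth (the filter precedes per-individual quality
re-analysis). The per-stage in/out counts and reason tallies are
emitted as a FilterTrace and are non-increasing by construction.

## Permutation FDR

Null difference scores are generated per SNP by reassigning the six
per-individual signed scores to two pseudo-groups of three, pooling
across SNPs, and the threshold t* is the smallest observed |D| with

    FDR(t) = (mean per permutation of #{|null| ≥ t}) / #{|observed| ≥ t} ≤ α.

Sites with |D| ≥ t* are flagged (ties inclusive); when no threshold
achieves the bound, t* = +inf and nothing is flagged.

Design choice: of the C(6,3) = 20 partitions, the identity partition
and its label swap are excluded. D is antisymmetric under the group
swap, so those two partitions reproduce ±D_observed at every SNP and
would bound the achievable FDR below by 2/20 = 10%, making a 5%
threshold unattainable no matter how strong the signal; the remaining
18 partitions all mix individuals across groups and are the informative
null. With `n_perm > 0` a seeded random sample of the 18 is used
instead; an alternative null that shuffles the observed group scores
across SNPs with random sign flips is available
(`null_method="pool"`), since the choice of permutation scheme is a
genuinely open reading.

Per-gene classification of flagged SNPs uses mean BFMI-allele
percentages per group with mono-allelic cutoffs 0.90/0.10 —
paternal-allele-expressed when the patBFMI group is ≥90% BFMI allele
and the matBFMI group ≤10%, the mirror for maternal, and "partial
imbalance" otherwise. The cutoffs match the published mono-allelic
loci (Peg3, Zrsr1, H13 patterns) while leaving graded imbalance (the
Abca8b pattern, a ~24-percentage-point group difference) in the partial
class.

## Expression arm

Processing order: quantile-normalise raw counts across samples → RPKM
(count·10⁹ / (library·length), library = column sum of the normalised
layer) → ln(n+1). Quantile normalisation maps each column onto the
mean-of-sorted-columns reference; rank ties receive the mean of their
reference slots, which (intentionally) departs from the shared
reference distribution only at tied values. Genes without a positive
length are excluded with a warning.

DE testing is a per-gene two-sided t-test on the log layer, Welch by
default (robust at n = 3 per group; pooled-variance optional), with no
multiple-testing correction — at three animals per group a corrected
genome-wide test has essentially no power, and the downstream
overrepresentation test aggregates the uncorrected list. Degenerate
genes (zero variance in both groups) return p = 1 at equal means and
p = 0 flagged `degenerate` otherwise.

The reported fold change is the ratio of group means **on the
ln(RPKM+1) layer**, matBFMI/patBFMI — the definition consistent with
the published per-gene tables (3.98/3.01 = 1.32 etc.). The DE filter
keeps genes with p < 0.05, mean RPKM > 0.5 in at least one group, and
an expression difference of at least 20% **ratio-wise**:
max(Fch, 1/Fch) ≥ 1.20. The ratio-wise reading is the one the
published down-regulated genes satisfy (Fch 0.83 ⇒ 1/0.83 = 1.20); an
additive |Fch − 1| reading would exclude them.

Overrepresentation uses the upper-tail hypergeometric
P(X ≥ overlap) with population = universe, successes = set ∩ universe,
draws = DE genes, Benjamini–Hochberg-corrected across sets. Gene sets
come from user GMT files; no online pathway service is queried.

## TFBS arm

Promoter regions are 2000 bp upstream + 1000 bp downstream of the TSS,
strand-oriented; the TSS is the annotated start of the longest
transcript when several exist. PWMs are built from aligned site lists
or IUPAC consensus strings with probabilities
(count + pc)/(n + 4·pc), default pseudocount 0.1, and scored as
log₂-odds against a background (uniform 0.25 by default). A window is
a hit when its score reaches min + r·(max − min) with r = 0.90 — the
conventional relative-score reading of a "90% threshold"; a
matrix-similarity variant of that phrase would be an alternative
scoring function over the same matrix, and the threshold is exposed as
`--rel-threshold`. Both strands are scanned by default; windows
containing N are skipped; with a zero pseudocount (one-hot matrix) the
min score is −inf and only the exact consensus scores at any r.

The four androgen-element arrangements shipped with the package (ARE,
ARE2, ADR3, IR3) are IUPAC-consensus stand-ins built from the
hexameric AGAACA-type half-sites in direct or inverted repeat with a
3-bp spacer; users supply measured site lists or matrices for real
analyses.

Enrichment of a motif in a gene set compares the observed statistic
(genes with ≥1 hit by default; total hit count optionally) with the
same statistic over `n_perm = 1000` uniformly drawn size-matched
subsets of the universe, with the add-one estimator
p = (1 + r)/(n_perm + 1) so p is never 0; direction is "over" when the
observed value is at or above the null mean. The statistic is
integer-valued, so p is discrete and the test is conservative rather
than exactly nominal at small set sizes.

## Phenotype arm

Litter size confounds all growth traits, so traits are adjusted before
testing: adjusted = grand mean + residual of OLS(trait ~ litter size),
fitted on the full cohort (per-stratum adjustment optional). Blood
glucose and liver triglyceride/protein pass through unadjusted, as in
the study. The direction-of-cross contrast is a two-group one-way
ANOVA F-test per sex (and fostering) stratum — identical to the
two-sided pooled t-test — with group means ± SD and the
matBFMI/patBFMI fold ratio (reported to two decimals). Strata with
fewer than two animals in a group are flagged underpowered with p =
NaN. An iterated two-sided Grubbs test (α = 0.05) is available for
outlier screening but off by default, since the study's exact outlier
variant is not specified.

## Synthetic data

The generator reproduces the statistical structure the analyses
assume, not sequences or read-level artefacts:

* **Allele counts.** Per sample and site, total depth is negative
  binomial (mean 30, size 10 by default; an optional floor gives a
  shifted distribution for guaranteed-depth designs). The alt count is
  beta-binomial with mean equal to the group's true BFMI-allele
  fraction and intra-class correlation ρ (default 0.1), so the
  variance is n·μ(1−μ)(1+(n−1)ρ); ρ = 0 recovers the binomial. Counts
  are split between strands Binomial(1/2); parental strains are exactly
  homozygous; call qualities default to a passing constant.
* **Imprinting.** A planted site's expected BFMI-allele fractions in
  the two F1 groups are f and 1−f (default f = 0.95), paternal or
  maternal orientation; the two group means always sum to 1.
* **Expression.** Negative-binomial counts around log-normal gene base
  means; DE genes have the matBFMI group mean multiplied by the
  planted fold change on the count scale.
* **Promoters.** i.i.d. background at configurable composition with
  the motif consensus embedded at a recorded offset/strand in planted
  genes.
* **Phenotypes.** trait = group mean + slope·(litter − mean litter) +
  Gaussian noise, litter sizes uniform on the observed breeding range
  4–11.

All generators are pure functions of (parameters, seed); truth is
emitted as a sidecar table keyed by feature id, never inside the data
files. What the generator does **not** emulate: mapping bias, shared
depth structure along transcripts, correlated quality/coverage,
sequence-composition realism, sex-chromosome dosage. Passing tests
therefore demonstrate the statistical behaviour of the methods under
the modelled noise, not robustness to alignment artefacts in real
data.

## Verification sizes and numerical conventions

The test suite verifies the χ² score against an independent
goodness-of-fit computation on 1,000 random count pairs to 1e-9;
beta-binomial moments at 10⁵ draws (variance within 5%); FDR
calibration and recovery at 10,000 SNPs with 200 planted 0.9/0.1 flip
sites at depth ≥ 30 (the scale at which 200 planted sites make the
recovery fraction a stable statistic while the whole check runs in
seconds); enrichment calibration over 200 replicate null simulations
of a 40-gene universe with 99 permutations each. Quantile-normalised
columns agree to 1e-12 on tie-free input; litter adjustment preserves
trait grand means to 1e-9. Worked-example ratios from published
2-decimal group means are compared at the precision those inputs
support (±0.005 propagated through the ratio). FDR ties are flagged
inclusively; fold ratios/changes with a zero denominator are NaN and
flagged rather than raised.

## Known limitations

* The permutation null with 3+3 groups has only 18 informative
  partitions; the pooled null distribution is granular at very small
  SNP counts, and the achievable FDR estimates are coarse below ~100
  sites.
* The 20% consistency filter removes genuinely imbalanced sites whose
  within-group ratios are noisy (≈5–10% of planted 0.9/0.1 sites at
  ρ = 0.1, depth 30); recovery figures include these losses.
* No mapping-bias correction, phasing, or X/Y/MT dosage handling; the
  ASE arm analyses autosomes.
* Fold change on the log layer is compressive: a 2-fold count change
  at high expression can sit below the 20% DE rule. This mirrors the
  published convention and is intentional.
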