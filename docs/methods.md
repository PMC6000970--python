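# Methods

`pvpopgen` re-implements, as a tested library, the population-genetics
analysis chain used for candidate-gene amplicon panels in allotetraploid
switchgrass (*Panicum virgatum*): ~370 genotypes from ~36 accessions,
sequenced at ~21 amplicon contigs distributed over the two homoeologous
subgenomes (K and N) of ~12 biomass-related genes. This note describes the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic benchmark does and does not demonstrate.

## Zygosity calling and filtering

Allotetraploid amplicon reads pool two disomic subgenomes; once reads are
mapped subgenome-resolved, each contig behaves as a diploid locus and
genotypes are called from per-sample alternate-read fractions:

* fraction < 0.25 → homozygous reference; > 0.75 → homozygous alternate;
* fraction in [0.40, 0.60] → heterozygous;
* the uncovered bands [0.25, 0.40) and (0.60, 0.75] → *ambiguous*.

Ambiguous calls (typically homoeolog bleed-through or low coverage) are
treated as missing by every downstream frequency computation. The boundary
convention is strict `<`/`>` for the homozygous intervals and inclusive
bounds for the heterozygous interval.

Filters run in a fixed, logged order: INDEL removal → adjacent-SNP removal
(every member of a run of variants at immediately adjacent positions is
discarded as biologically unlikely) → per-call depth masking (depth < 3 →
missing) → site missingness (≥ 20% missing calls) → population
allele-frequency window (mean alternate dosage over called genotypes must
lie in [0.05, 0.95]) → sample missingness (> 30% missing). Frequencies are
computed *after* depth masking. Missingness ratios are computed as exact
integer ratios so boundary cases (exactly 20% or 30%) are not at the mercy
of floating-point rounding. Each removed variant is counted in exactly one
report category (the first rule that removes it).

## SNP classification

* **Coding effect**: reference and mutated codons are translated with the
  standard genetic code; a SNP is synonymous only if every observed
  alternate encodes the reference amino acid. Triallelic sites (about 6% of
  amplicon SNPs) report both mutant amino acids.
* **Conservation**: a non-synonymous change is *conservative* when the
  BLOSUM62 score of the wild-type/mutant pair is ≥ +1, otherwise
  *non-conservative* (score 0 pairs such as A/T, S/G, N/K, L/F are
  non-conservative). This operationalises "amino-acid property change" with
  a reproducible matrix rule; matrix and threshold are configurable. On the
  bundled 49-substitution worked-example panel this rule reproduces every
  published conservative/non-conservative label (32 non-conservative, 17
  conservative). Substitutions to or from a stop codon are classified
  non-conservative without consulting the matrix.
* **Wild-type allele**: the outgroup (*Setaria*-like) allele when it is
  observed among the site's alleles; otherwise the majority allele (an
  exact 50/50 tie falls back to the reference allele and is flagged). The
  triallelic row-level label uses the highest-frequency mutant.
* **Frequency class** of the wild-type allele: rare (≤ 0.25 or ≥ 0.75),
  balanced ([0.40, 0.60]), common (the remaining two bands). These three
  classes partition [0, 1] exactly.
* **Prevalence**: a mutant allele is *prevalent* in a subpopulation when it
  is present only there, or at frequency ≥ 0.75 there and < 0.25 in every
  other subpopulation; *diagnostic* when ≥ 0.50 there and < 0.05 elsewhere.
  A SNP meeting both definitions is reported as diagnostic.
* **Ecotype predominance**: no published test statistic exists for the
  upland/lowland contrast, so a two-proportion chi-square on mutant allele
  copies at α = 0.05 is used; non-significant sites are "shared".

## Diversity and neutrality statistics

Haplotypes over each contig's SNPs are reconstructed with an
Excoffier–Slatkin EM over haplotype frequencies (multiple restarts,
convergence at |ΔlnL| < 1e-6, deterministic given a seed). A full
coalescent-informed Gibbs phaser is deliberately not used: at amplicon SNP
counts (≤ ~40 per contig) the EM likelihood surface is essentially exact —
on a two-site benchmark the EM lands within 0.005 of an exhaustive
likelihood grid — and EM is deterministic. Individuals with more than 16
heterozygous sites on one contig (not reached at amplicon scale) would be
phased greedily with a warning.

On the phased sample of n = 2 × individuals sequences:

* π = (n/(n−1)) · Σ_sites 2p(1−p) / L (per site; pairwise deletion of
  missing data), which equals the mean pairwise difference;
* Watterson θ_W = S / (a₁ L), a₁ = Σ_{i<n} 1/i;
* standard deviations from the standard no-recombination neutral variances;
* haplotype diversity Hd = n/(n−1) (1 − Σ f_i²) with Nei's variance;
* Tajima's D with the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂);
  undefined (reported as not applicable) when S = 0;
* Fu & Li's F when outgroup orientation covers all segregating sites
  (derived singletons), otherwise F*, using the corrected (Simonsen-style)
  u/v constants. The variant used is recorded in the output.
* SNP density d = 100 · S / L (percent polymorphism).

π and Tajima's D were checked to machine precision against tskit's
implementations on neutral coalescent simulations; over 1000 msprime
replicates (n = 20, θ = 5) the mean D is within ±0.15 of zero and π and
θ_W agree in expectation to < 5%.

Statistics are computed on total analysed length L; the bundled gene
summary keeps the published coding lengths alongside.

## Differentiation and AMOVA

Nei's Gst uses Ht from pooled mean allele frequencies and Hs as the mean
within-group expected heterozygosity, averaged over loci as
(mean Ht − mean Hs)/mean Ht; significance by permuting individuals among
groups (999 permutations by default). Pairwise Fst is Gst restricted to the
pair (loci monomorphic for the same allele in both groups are skipped);
Weir–Cockerham is *not* implied — the pair-restricted Nei form is labelled
as such. Nei's standard distance D = −ln(Jxy/√(Jx·Jy)) is capped (default
10) when no alleles are shared. Gene flow Nm = 0.5(1−Gst)/Gst. Note that
the pair-restricted Nei Gst of two populations each drifted to
Balding–Nichols F converges to (F/2)/(1−F/2), not to F; the synthetic truth
therefore stores the Gst implied by the realized subpopulation frequencies.

The AMOVA is the three-level codominant partition (among groups / among
individuals within groups / within individuals). It is computed as a
nested ANOVA on the two 0/1 allele values per genotype — algebraically the
same as the squared-Euclidean AMOVA on allele-level distances — with
variance components from the unbalanced-design expected mean squares
(allele-count coefficient n₀), truncated at zero for reporting. Missing
dosages are mean-imputed per locus so the design degrees of freedom depend
only on sample counts (g−1, N−g, N; total 2N−1, matching the published df
layout). Permutation p-values use the *untruncated* component as the test
statistic (truncating the observed statistic at zero would bias p downward
under the null); individuals are permuted among groups for the among-group
level and alleles among individuals for the within-individual level.
Reported percentages are integer-rounded shares of the total component.

## Population structure

A minimal STRUCTURE-style Gibbs sampler: each allele copy carries a latent
cluster of origin; cluster allele frequencies have Beta(1,1) priors and
admixture vectors a symmetric Dirichlet(α) prior (α = 1 by default, fixed).
lnP(D) is estimated from the post-burn-in log-likelihood trace as
mean(lnL) − var(lnL)/2 and K is chosen as the smallest K whose mean lnP(D)
over runs is within one run-level standard deviation of the maximum
(plateau rule). The published protocol sizes (100k burn-in, 100k
iterations, 10 runs, K = 1..10) are the configuration defaults; the
desk-scale profile (`Config.reduced()`) uses 1k/2k, 2 runs, K ≤ 3.
Genotypes with maximum membership < 0.70 are "admixed"; an accession is
representative of a subpopulation when > 70% of its genotypes are assigned
there. The reporting run defaults to the highest-lnP(D) run
(`run_selection="lowest"` is available as a switch). PCoA is a
double-centred eigendecomposition of the squared-dosage genotype distance
(the same codominant metric as the AMOVA), with percent variance from the
positive eigenvalues; it matches scikit-bio's PCoA to 1e-6.

A note on the admixture prior: with ~250 loci at Fst ≈ 0.1, the flat α = 1
prior shrinks the posterior membership of genuinely pure individuals to
~0.85 — expected behavior of the model, not an implementation artifact.
The planted-truth recovery benchmark therefore fits with the generator's
own sparse α (0.2), where the posterior-mean Q reaches RMSE ≈ 0.06 against
the identifiability floor of ≈ 0.05 (computed by supervised EM with the
true frequencies known).

## Spatial genetics, trees and dating

* **Mantel**: Pearson correlation of off-diagonal entries with joint
  row/column permutation of one matrix, one-tailed on the positive side
  (the isolation-by-distance usage). Geographic distance is great-circle
  (haversine) kilometres from GPS coordinates; a log-distance option
  exists. Type-I error is calibrated (~5% at α = 0.05 under the null).
* **2D local spatial autocorrelation**: lr_i is the mean genetic similarity
  (1 − d/d_max over the panel) between individual i and its n nearest
  geographic neighbours; one-tailed p by permuting individual identities
  (9999 permutations by default); an individual is *consistently
  significant* when p ≤ 0.05 at every n in the 7..14 sweep. Duplicate
  coordinates (same collection site) are tie-broken by sample order and
  flagged.
* **UPGMA**: built on concatenated per-genotype sequences using IUPAC
  ambiguity codes at heterozygous sites; the default p-distance counts
  ambiguity matches fractionally (R vs A = 0.5 differences), with a
  composite Tamura–Nei option. Column bootstrap (500 replicates by
  default) annotates clade supports; trees are ultrametric by
  construction and exported as Newick.
* **Divergence dating**: t = 13 Mya × d(between groups)/d(ingroup,
  outgroup). When the "groups" are polymorphic populations the pipeline
  uses the *net* between-group distance, d_xy − (d_x + d_y)/2, so shared
  ancestral polymorphism does not inflate the split estimate; for single
  sequences the plain mean is the default. The estimate is invariant to
  rescaling all distances.

## Subgenome contrasts

SNP placement is profiled in non-overlapping 100-bp windows anchored at
position 1 of the analysed region. Homoeologous K/N gene copies are
compared on the percentage of polymorphic sites over *shared* windows
(windows with data in both copies, paired via the annotation's homoeolog
grouping — no sequence alignment between homoeologs is performed); windows
polymorphic in only one copy are reported as subgenome-specific divergence
candidates. Genes lacking mapping data in more than 20% of accessions in
either copy are excluded.

## Synthetic data generator

The generator emulates the study design so the whole chain is testable
without downloads: 36 accessions × 10 genotypes from K = 3 admixed
subpopulations; 12 genes of which 9 have both K and N homoeologs (21
contigs, ~2.4 kb each, 12 SNPs per contig ≈ 250 SNPs); accession
coordinates scattered around three regional centres (a northern/upland one
and two lowland ones) with ancestry weights decaying with distance to each
centre, which induces isolation by distance; ecotype and ploidy metadata
follow the centre assignment (upland mostly 8x).

Frequencies: ancestral p₀ ~ U(0.05, 0.95) per SNP; subpopulation
frequencies Balding–Nichols(F = 0.2) (calibrated: realized mean and
variance match F·p₀(1−p₀)). Each allele copy draws its cluster of origin
per locus from the individual's admixture vector — the admixture model
proper, so the drawn Q is the identifiable truth for recovery benchmarks —
and its allele from that cluster's frequency. Reads: Poisson depth (mean
60), binomial allele sampling with 1% error, 5% dropout, ~6% triallelic
sites carrying a low-frequency second alternate. The outgroup allele is
the ancestral state mutated at 8% of sites. Two classifier truths are
planted in the first gene's first exon (one non-conservative and one
synonymous substitution, codon-aligned, outgroup-anchored).

The mean depth deserves a note: it is set to 60×, a realistic per-amplicon
coverage. At a per-base average of ~8.6× the binomial resolution of allele
fractions is so coarse that most heterozygous calls land in the ambiguous
bands and the missingness filter then preferentially destroys polymorphic
sites — incompatible with the allele-fraction precision such panels report.

What the generator does **not** emulate: within-contig linkage
disequilibrium beyond admixture LD (allele copies are drawn independently
across loci given ancestry), inbreeding / departures from
Hardy–Weinberg within subpopulations (real accessions of this species show
strongly positive fixation indices; the synthetic panel is more
heterozygous, which shifts the AMOVA within-individual share upward),
octoploid dosage (ploidy is metadata only; inheritance is disomic
everywhere), sequencing-error structure beyond symmetric binomial noise,
and ascertainment of the site-frequency spectrum other than the uniform
common-SNP prior (which itself yields positive Tajima's D on average, as
real ascertained amplicon SNP panels do). Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to these real-data features.

## Problem sizes used in the test suite

The bundled validation suite runs the full pipeline once on the standard
fixture (360 samples × ~250 retained SNPs) with the reduced MCMC profile,
1000-replicate neutral-coalescent calibration for the diversity statistics,
200 null replicates for the Mantel calibration, and 12 × 50-individual
panels for the local-autocorrelation calibration. These sizes keep the
whole suite within a routine desktop run while leaving the statistical
assertions well inside their bands.

## Known limitations

* The conservation rule is a matrix operationalisation; borderline pairs
  (score exactly 0 vs +1) follow the matrix, not physicochemical intuition.
* Pairwise Fst is the pair-restricted Nei Gst, which is downward-scaled
  relative to the Balding–Nichols parameter (see above); comparisons across
  studies using Weir–Cockerham estimates need care.
* The AMOVA mean-imputes missing dosages; under extreme, structured
  missingness the within-individual component is mildly underestimated.
* lnP(D)-based K selection inherits the known fragility of the plateau
  criterion when runs are few; the run-level SD rule is deterministic but
  can prefer K ± 1 for nearly flat likelihood profiles.
* The 2D-LSA similarity (1 − d/d_max) reproduces the published algorithm at
  the contract level; the original tool's exact multivariate constants are
  unpublished.
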