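# Methods

This note documents the models and procedures implemented in `magicpanel`,
the defaults they use, and what the synthetic-data generator does and does
not emulate.

## Genotype model and site filters

Genotypes are diploid biallelic codes (hom-ref / het / hom-alt / missing)
in a sites × samples matrix; coordinates are 1-based inclusive throughout
(VCF convention). Per-site statistics are computed over non-missing calls:
the minor allele frequency is `min(p, 1-p)` with
`p = (2·hom_alt + het) / (2·non_missing)`. A site with zero non-missing
calls has undefined MAF (NaN sentinel, missing rate 1); a site with a
single non-missing call is treated as monomorphic (MAF 0) to avoid
division blow-ups — such sites can never pass a positive MAF threshold,
which matches the filter's intent.

Filtering uses strict inequalities in the inclusion form,
`missing_rate < max_missing` and `MAF > min_maf` (defaults 0.3 and 0.05,
the thresholds used to arrive at the 18,816 analysis SNPs of the S2
population), with an optional inclusive cap on the number of heterozygous
calls used during source-panel screening. Multi-allelic VCF records are
rejected by default; a `first_alt` policy keeps the first ALT and masks
calls carrying any other allele. The published source-panel pipeline also
marked alleles with fewer than five supporting reads as missing; that is a
read-depth operation upstream of the GT field and is documented here but
not performed — this package operates on genotype calls only.

## Diagnostic-site classification and panel selection

A site is *1:7* when exactly one of the eight founders is homozygous for
one allele and the other seven are homozygous for the other; *2:6*, *3:5*
and *4:4* generalize the minority count. Any founder heterozygote or
missing call disqualifies a site from panel candidacy (missing dominates
het in the labels): founder-of-origin inference presumes clean homozygous
founders. A 4:4 split has no strict minority; the hom-alt side is recorded
as carriers by convention.

Panel quotas per chromosome are proportional to physical length by
largest-remainder apportionment, capped at candidate availability with the
surplus re-apportioned until placed. Within a chromosome, the sequence is
partitioned into `quota` equal windows; each window picks its candidate by
priority 1:7 > 2:6, then nearest the window midpoint, then smallest
position; empty windows borrow the globally nearest unselected candidate.
This windowed greedy rule was chosen for determinism and testability — the
released 40K panel does not state its spacing algorithm, and its
30,082:9,918 1:7-to-2:6 split is an outcome, not a rule, so the target mix
(default 3:1) only thins 1:7 excess when candidates exceed a chromosome's
quota.

Probe flanks are `reference[pos-flank .. pos+flank]` (1-based inclusive,
target base centred) with the reverse probe as the exact reverse
complement. Effect annotation follows snpEff-style precedence —
coding (missense/synonymous by codon translation of the spliced CDS) >
5' UTR > 3' UTR > intron > non-coding exon > upstream > downstream >
intergenic — with a 5 kb strand-aware near-gene window (the annotation
tool's conventional default; the panel description does not state one).
Start/stop-codon changes fold into missense unless the optional `other`
class is enabled. Marker-density rates are `floor(length / variants)`;
floor (not round) reproduces every checked row of the released panel's
density table.

## Funnel combinatorics

The half-allele mating system forbids a founder appearing twice in a
cross, and reciprocal crosses are identified (no maternal/paternal
distinction is tracked). For 8 founders: C(8,2) = 28 two-way crosses, 210
founder-disjoint pairs of two-ways, and 315 founder-disjoint pairs of
four-ways. The 315 eight-way crosses partition into 35 classes keyed by
the unordered quartet split of the founders (C(8,4)/2), each class holding
the 3 × 3 internal pairings. The advance subset takes one representative
per class — lexicographically first by default, or seeded-random, since
the study does not state its choice rule — giving 35 crosses and, at 200
lines per cross, a 7,000-line target population. Slash notation binds
tighter with fewer slashes (`A/E//D/G///B/C//F/H`); the parser requires
separator depth to match subtree depth and round-trips canonical forms.

## Meiosis and funnel simulation

Meiosis uses the standard no-interference model: crossover count per
chromosome is Poisson with mean equal to the genetic length in Morgans,
crossover positions are uniform in genetic distance, the starting homolog
is fair, and there is no obligate chiasma. Two-locus recombination
fractions therefore follow Haldane's map function
r = ½(1 − e^(−2d/100)). The default genetic map is uniform 1 cM/Mb over
the panel's physical chromosome lengths (no genetic map is published for
this material). Non-uniform maps are supported through monotone (bp, cM)
anchors.

Founder descent is tracked as haplotype mosaics — ordered founder-labelled
segments tiling each chromosome — validated to tile exactly after every
operation. Each simulated line realizes its own intermediate cross
individuals (the field funnel used many plants per cross), then single
seed descent carries exactly one selfed offspring per line per generation;
the 8-way F1 is S0 and two selfing generations give S2. Genotypes are
projected from mosaics via the covering founders' alleles, with optional
symmetric genotyping error (a wrong call replaces the true one uniformly)
and missingness.

A consequence of the half-allele funnel worth stating explicitly: at a 1:7
site the carrier founder belongs to exactly one parental quartet, so the
8-way F1 is heterozygous with probability exactly 1/4 (not
2·(1/8)·(7/8) ≈ 0.219, which would hold only if the two homologs were
drawn independently with replacement from all eight founders). Two
selfing generations halve heterozygosity twice, so the expected S2
heterozygosity at 1:7 sites is 1/16 = 0.0625. The calibration suite tests
this exact value; an independent single-locus brute-force simulation
confirms it.

## Concordance

Chip-vs-truth comparison classifies each site with a fixed precedence so
the reported categories are mutually exclusive: chip-missing > indel
difference > heterozygous difference (either call het) > homozygous
difference > consistent. Truth-side-missing sites cannot be judged; they
are reported in a diagnostic column and are not any of the four printed
categories, but remain in the denominator (the full panel size). Accuracy
is 100·consistent/total with half-up rounding to two decimals, which
reproduces all eight published founder accuracies from their printed
consistent counts.

## Distance, clustering and covariates

The pairwise distance is 1 − IBS over sites non-missing in both samples:
allele sharing scores 1 (identical calls), 0.5 (hom vs het), 0 (opposite
homozygotes), equivalently `mean(|g_i − g_j|)/2` on dosage codes. Pairs
sharing no sites get NaN with a warning. UPGMA merges the closest pair
with arithmetic-average linkage, ties broken toward the lexicographically
smallest cluster label; merge heights are halved into branch lengths so
the tree is ultrametric. Trees are scikit-bio `TreeNode`s and export/parse
as Newick. The tree is not claimed to reproduce any published topology:
the upstream tool's exact IBS variant is not stated, so the definition
here is simply documented.

Structure covariates are either an externally produced Q matrix (TSV) or
the top-k principal components of the mean-imputed, centred genotype
matrix (ADMIXTURE is deliberately not re-implemented — it contributes no
algorithmic content to this stack, and PCA covariates serve the same role
in the mixed model).

## Mixed-model association scan

The model is y = 1μ + Qv + xβ + u + e with u ~ N(0, σ²_g K),
e ~ N(0, σ²_e I), where K is the VanRaden centred cross-product
relationship matrix K = WW'/c, c = Σ 2p(1−p). Variance components are
estimated once on the null (no-marker) model by REML — spectral
decomposition of K and a bounded 1-D search over log δ (δ = σ²_e/σ²_g,
bounds [1e-5, 1e5], tolerance 1e-8) — and reused for every marker test
(the P3D strategy, matching the upstream tool's default and keeping the
scan O(n²) per marker after one rotation). Each marker is then a
generalized least squares fit; the test is the Wald t with n − p − 1
degrees of freedom, reported as −log10 p. `add_effect` is the regression
coefficient on alt-allele dosage — the published table's +/− column names
no reference allele, so this sign convention is output metadata rather
than an attempt to match it. Markers collinear with the fixed effects
(scale-free criterion x'M₀x ≤ 1e-10·x'x) are skipped with a flag. With
identity kinship the scan reduces exactly to ordinary regression, which
the tests verify against statsmodels OLS.

The genome-wide threshold is Bonferroni, −log10(α/n) with α = 0.05 and n
the markers actually tested; no FDR alternative is offered, matching the
published analysis. (For n = 18,816 the formula gives 5.5756, and for
n = 18,186 it gives 5.5608.) Multi-trait hits are sites significant in at
least `min_traits` traits (default 2 of the four pod traits). Regions are
single-linkage chains of hits with gaps ≤ 1 Mb (default; this reproduces
the published chromosome-7 and chromosome-12 blocks as single regions of
0.93 and 2.61 Mb), and candidate genes are all gene features overlapping
the region span with no added flank. Genotype-class contrasts use Welch's
two-sample t-test between homozygote classes, optionally conditioned on a
genotype class at a second site, with heterozygous and missing calls
excluded.

## Synthetic data

The generator emulates the study's structure, not peanut biology: eight
homozygous founders on the 20 panel chromosomes (physical lengths scaled,
default 1/50), site patterns drawn with a 3:1 1:7-to-2:6 mix, a random
reference sequence consistent with the ref alleles, and single-exon toy
gene models tiling ~30% of each chromosome. Pod phenotypes build length
and width as latent traits — planted QTL effects on standardized dosage
plus a polygenic term and residual scaled to the target heritability
(default h² 0.5) — and derive area (∝ length × width) and perimeter
(∝ length + width), which induces the positive inter-trait correlations of
real pod measurements; the observed value is the mean of six noisy pod
measurements per plant, mirroring the study's phenotyping. Trait units
are labelled (mm, mm²) but arbitrary.

What passing tests therefore show: the pipeline's algorithms are correct
and calibrated under Mendelian descent with a uniform map and independent
Gaussian noise. What they do not show: performance under real peanut LD
structure, segregation distortion, genotyping-depth artifacts, or
image-based phenotype error.

## Problem sizes and numerical choices

The validation battery runs at a desk scale chosen to finish in minutes on
one CPU: 2,000 simulated S2 lines for heterozygosity/share calibration,
20,000 gametes for map-function checks, 300 lines × 5,000 markers for
mixed-model calibration, 50 replicates for QTL detection and 20 for
localization. Stochastic checks use 3 Monte-Carlo (or binomial) standard
errors. Type-I calibration uses unlinked markers so the binomial standard
error is the right yardstick; funnel-simulated markers are used for the
QTL power and localization checks, where linkage is the point.

Known limitations: no crossover interference; no selection or mortality in
the funnel; concordance is GT-based (no read-depth awareness); the UPGMA
implementation is O(n³) and intended for hundreds, not tens of thousands,
of samples; REML assumes a full-rank fixed-effects design after rotation.
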