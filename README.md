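# magicpanel

Computational toolkit for designing a targeted-genotyping ("liquid chip")
marker panel and analysing an 8-way MAGIC crop population with it. It was
built around the GenoBaits Peanut 40K panel and the peanut MAGIC population
genotyped with it, but every step is parameterized and runs end-to-end on
its own synthetic data.

A MAGIC (multi-parent advanced generation intercross) population mixes
eight founder lines through a *half-allele funnel*: 28 two-way crosses,
210 four-way crosses, 315 eight-way crosses (no founder used twice within
a cross), then selfing by single seed descent to S2. Genotyping uses a
panel of founder-diagnostic SNPs: *1:7* sites, where one founder is
homozygous for one allele and the other seven for the other, and *2:6*
sites, which split the founders two against six — these allow founder-of-
origin inference in the descendants.

The package covers, as importable modules behind one CLI:

- **genotype** — diploid genotype matrices, VCF/TSV I/O, missing-rate/MAF
  filters (`missing rate < 0.3`, `MAF > 0.05` defaults).
- **panel** — 1:7 / 2:6 classification, per-chromosome quotas by
  largest-remainder apportionment, even-spacing selection, probe flank
  extraction, marker-density reporting; **annotate** — snpEff-style effect
  categories from GFF3 gene models.
- **crosses** — exact funnel combinatorics: enumeration, the 35 quartet
  classes of 9 eight-way crosses, advance-subset selection, slash-notation
  parsing (`A/E//D/G///B/C//F/H`).
- **sim** — forward meiosis simulator (Poisson crossovers, Haldane map
  function, no interference) tracking founder haplotype mosaics through
  the funnel and projecting them onto panel sites.
- **concordance** — chip-vs-sequencing comparison with mutually exclusive
  difference categories and percent accuracy.
- **popstruct** — 1−IBS distance, UPGMA trees with Newick export, PCA
  structure covariates.
- **gwas** — VanRaden kinship and a mixed linear model scan,
  y = 1μ + Qv + xβ + u + e with u ~ N(0, σ²gK), e ~ N(0, σ²eI): REML
  variance components on the null model, P3D per-marker generalized least
  squares, Bonferroni threshold −log10(α/n), multi-trait hit selection
  (≥ 2 traits), 1 Mb single-linkage candidate regions, gene lookup and
  Welch genotype-class contrasts.
- **synth** — synthetic founders, reference FASTA, GFF3 and pod-size
  phenotypes (area, perimeter, length, width) with planted QTLs, so the
  whole pipeline is testable without external data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a demo fixture (8 founders, the 20 panel chromosomes at 1/50
length, 5,000 diagnostic sites, 300 S2 lines from the funnel cross
`A/E//D/G///B/C//F/H`, phenotypes with one planted QTL each for length and
width) and scan pod length:

```python
import pandas as pd
from magicpanel import filter_sites, kinship, pca_covariates, read_vcf
from magicpanel.gwas import MixedLMScan
from magicpanel.synth import make_demo

m = make_demo("demo", seed=42, n_sites=5000, n_lines=300)
geno = filter_sites(read_vcf(m["population_vcf"]))
pheno = pd.read_csv(m["phenotypes_tsv"], sep="\t", index_col=0)
res = MixedLMScan.from_dataframe(pheno, "length", geno,
                                 pca_covariates(geno, 3), kinship(geno)).fit()
print(res.summary())
```

prints

```
Mixed linear model scan — trait 'length'
  samples: 300   markers tested: 5000
  REML variance components: sigma2_g=2.929 sigma2_e=10.62 (h2=0.216)
  Bonferroni threshold (-log10): 5.0000 at alpha=0.05
  significant markers: 20
  top hits:
    Arahy.01_1138966 Arahy.01:1138966 -log10p=14.50 effect=+2.642
    Arahy.01_1163400 Arahy.01:1163400 -log10p=14.22 effect=+2.611
    ...
```

The planted length QTL in this run is `Arahy.01_1163400`
(`m["qtl_truth"]`): the scan places it second, 25 kb behind the top hit on
the same chromosome — the markers around a QTL share its founder descent,
so a tight cluster of hits is the expected signature. The Bonferroni
cutoff is −log10(0.05/5000) = 5.0; `effect` is the marker's additive
effect on pod length in mm per alt-allele dose.

The same workflow is available from the shell:

```sh
magicpanel plan-crosses                      # 28 / 210 / 315 / 35 / 7000
magicpanel demo-pipeline --seed 42 --out-dir run/
magicpanel gwas --vcf pop.vcf --phenotypes pheno.tsv --pca 3 \
    --gff3 genes.gff3 --out-dir out/
```

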