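"""Predicted effect of a panel SNP on overlapping gene models.

Categories follow the usual snpEff-style vocabulary: missense, synonymous,
five_prime_UTR, three_prime_UTR, intron, non_coding_transcript_exon,
upstream_gene (within 5 kb before the TSS, strand-aware), downstream_gene
(within 5 kb after the TES), intergenic, plus an optional ``other`` class
for start/stop-codon changes.  When a site is covered by several features
the highest-precedence category wins:

    coding > 5'UTR > 3'UTR > intron > non-coding exon > upstream >
    downstream > intergenic
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .genotype import VariantSite

UPSTREAM_WINDOW = 5_000  # bp before TSS / after TES, the annotator convention

CATEGORIES = (
    "missense", "synonymous", "five_prime_UTR", "three_prime_UTR", "intron",
    "non_coding_transcript_exon", "upstream_gene", "downstream_gene",
    "intergenic", "other",
)


class ReferenceMismatchError(ValueError):
    """The site's REF allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class EffectCategory:
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown effect category {self.category!r}")


def _coding_effect(db, cds_feats, site: VariantSite, reference,
                   classify_edge: bool) -> str:
    """Missense/synonymous via the spliced CDS of the transcript."""
    strand = cds_feats[0].strand
    cds_sorted = sorted(cds_feats, key=lambda f: f.start)
    seq_parts, offset = [], None
    running = 0
    for f in cds_sorted:
        part = str(reference[site.chrom][f.start - 1:f.end]).upper()
        if f.start <= site.pos <= f.end:
            offset = running + (site.pos - f.start)
        seq_parts.append(part)
        running += f.end - f.start + 1
    cds = "".join(seq_parts)
    assert offset is not None
    if cds[offset] != site.ref_allele.upper():
        raise ReferenceMismatchError(
            f"reference base {cds[offset]} != ref allele "
            f"{site.ref_allele} at {site.chrom}:{site.pos}"
        )
    alt_cds = cds[:offset] + site.alt_allele.upper() + cds[offset + 1:]
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
        offset = len(cds) - 1 - offset
    codon_i = offset // 3
    ref_codon = cds[3 * codon_i:3 * codon_i + 3]
    alt_codon = alt_cds[3 * codon_i:3 * codon_i + 3]
    if len(ref_codon) < 3:
        return "other" if classify_edge else "synonymous"
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if classify_edge:
        start_lost = codon_i == 0 and ref_aa == "M" and alt_aa != "M"
        stop_change = (ref_aa == "*") != (alt_aa == "*")
        if start_lost or stop_change:
            return "other"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def annotate_effect(site: VariantSite, gene_db, reference,
                    classify_edge: bool = False) -> EffectCategory:
    """Classify one site against a :mod:`gffutils` database and a reference.

    ``gene_db`` is a ``gffutils.FeatureDB``; ``reference`` maps chromosome
    name to sequence (``pyfaidx.Fasta`` works).  ``classify_edge`` enables
    the ``other`` class for start/stop-codon changes.
    """
    overlapping = list(gene_db.region(
        region=(site.chrom, site.pos - 1, site.pos), completely_within=False))
    by_type: dict[str, list] = {}
    for f in overlapping:
        if f.start <= site.pos <= f.end:
            by_type.setdefault(f.featuretype, []).append(f)

    if "CDS" in by_type:
        # evaluate the codon in the first covering transcript's spliced CDS
        cds_here = by_type["CDS"][0]
        parents = list(gene_db.parents(cds_here))
        if parents:
            tx_cds = list(gene_db.children(parents[0], featuretype="CDS"))
        else:
            tx_cds = [cds_here]
        return EffectCategory(
            _coding_effect(gene_db, tx_cds, site, reference, classify_edge))
    if "five_prime_UTR" in by_type:
        return EffectCategory("five_prime_UTR")
    if "three_prime_UTR" in by_type:
        return EffectCategory("three_prime_UTR")

    transcripts = [f for t in ("mRNA", "transcript", "ncRNA", "lnc_RNA")
                   for f in by_type.get(t, [])]
    genes = by_type.get("gene", [])
    if transcripts or genes:
        exons = by_type.get("exon", [])
        if exons:
            coding_tx = {
                p.id for e in exons for p in gene_db.parents(e)
                if any(True for _ in gene_db.children(p, featuretype="CDS"))
            }
            if coding_tx:
                return EffectCategory("intron")  # exonic but neither CDS nor UTR
            return EffectCategory("non_coding_transcript_exon")
        return EffectCategory("intron")

    # near-gene classification, strand-aware
    lo = max(1, site.pos - UPSTREAM_WINDOW)
    hi = site.pos + UPSTREAM_WINDOW
    upstream = downstream = False
    for g in gene_db.region(region=(site.chrom, lo - 1, hi),
                            completely_within=False):
        if g.featuretype != "gene":
            continue
        if g.strand == "-":
            before_tss = site.pos > g.end and site.pos - g.end <= UPSTREAM_WINDOW
            after_tes = site.pos < g.start and g.start - site.pos <= UPSTREAM_WINDOW
        else:
            before_tss = site.pos < g.start and g.start - site.pos <= UPSTREAM_WINDOW
            after_tes = site.pos > g.end and site.pos - g.end <= UPSTREAM_WINDOW
        upstream |= before_tss
        downstream |= after_tes
    if upstream:
        return EffectCategory("upstream_gene")
    if downstream:
        return EffectCategory("downstream_gene")
    return EffectCategory("intergenic")


def load_gene_db(gff_path: str):
    """Create an in-memory gffutils database from a GFF3 file."""
    import gffutils

    return gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
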