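"""Consequence classification: positional classes, codon changes, InDel frames."""

import numpy as np

from bovivar import VariantSet, classify_indel_frame, classify_variant, tally_consequences
from bovivar.annotate import (CODING_UNKNOWN, DOWNSTREAM, FRAMESHIFT, INFRAME_DEL,
                              INFRAME_INS, INTERGENIC, INTRON, MISSENSE, NC_EXON,
                              SPLICE_ACCEPTOR, SPLICE_DONOR, SPLICE_REGION, STOP_GAINED,
                              STOP_LOST, SYNONYMOUS, UPSTREAM, UTR3, UTR5, _RANK,
                              AnnotationParams)
from bovivar.genemodel import GeneModel, Transcript
from bovivar.variants import Variant


def snp(chrom, pos, ref="A", alt="G"):
    return Variant(chrom, pos, ref, alt, 50.0, 30, 8, 7, "het")


# ---------------------------------------------------------------------------
# positional classes
# ---------------------------------------------------------------------------

def test_far_snp_is_intergenic(two_exon_gene):
    assert classify_variant(snp("1", 20_000), two_exon_gene) == INTERGENIC
    assert classify_variant(snp("9", 1000), two_exon_gene) == INTERGENIC  # unknown chrom


def test_downstream_five_kb_boundary():
    # plus-strand transcript ending at 0-based 2000 (last base pos0 1999)
    tx = Transcript("t", "g", "1", "+", ((1000, 2000),), ())
    model = GeneModel([tx])
    # 4,999 bp past the 3' end -> downstream; 5,001 bp -> intergenic
    assert classify_variant(snp("1", 2000 + 4999), model) == DOWNSTREAM
    assert classify_variant(snp("1", 2000 + 5001), model) == INTERGENIC


def test_upstream_downstream_strand_aware():
    tx = Transcript("t", "g", "1", "-", ((10_000, 12_000),), ())
    model = GeneModel([tx])
    assert classify_variant(snp("1", 12_500), model) == UPSTREAM
    assert classify_variant(snp("1", 9_500), model) == DOWNSTREAM


def test_utr_and_intron_classes(two_exon_gene):
    # exons 1000-1300/1500-1800, CDS 1100-1300+1500-1700 (plus strand)
    assert classify_variant(snp("1", 1050), two_exon_gene) == UTR5
    assert classify_variant(snp("1", 1750), two_exon_gene) == UTR3
    assert classify_variant(snp("1", 1400), two_exon_gene) == INTRON
    assert classify_variant(snp("1", 1200), two_exon_gene) == CODING_UNKNOWN


def test_splice_sites_and_region(two_exon_gene):
    # intron is 1300-1500 (0-based); positions are 1-based
    assert classify_variant(snp("1", 1301), two_exon_gene) == SPLICE_DONOR
    assert classify_variant(snp("1", 1302), two_exon_gene) == SPLICE_DONOR
    assert classify_variant(snp("1", 1500), two_exon_gene) == SPLICE_ACCEPTOR
    assert classify_variant(snp("1", 1305), two_exon_gene) == SPLICE_REGION  # 5 bp in
    assert classify_variant(snp("1", 1320), two_exon_gene) == INTRON         # 20 bp in


def test_noncoding_exon():
    tx = Transcript("t", "g", "1", "+", ((100, 400),), ())
    assert classify_variant(snp("1", 200), GeneModel([tx])) == NC_EXON


# ---------------------------------------------------------------------------
# codon comparison
# ---------------------------------------------------------------------------

def _coding_fixture(strand="+"):
    """Single-exon CDS with sequence ATG GAA TAG starting at 0-based 100."""
    cds_seq = "ATGGAATAG"
    if strand == "+":
        seq = "C" * 100 + cds_seq + "C" * 100
    else:
        comp = str.maketrans("ACGT", "TGCA")
        seq = "C" * 100 + cds_seq.translate(comp)[::-1] + "C" * 100
    tx = Transcript("t", "g", "1", strand, ((100, 109),), ((100, 109),))
    return GeneModel([tx]), {"1": seq}


def test_codon_synonymous_vs_missense():
    model, seq = _coding_fixture("+")
    # codon 2 = GAA (Glu) at 0-based 103..105 -> 1-based 104..106
    assert classify_variant(snp("1", 106, "A", "G"), model, seq) == SYNONYMOUS  # GAA->GAG
    assert classify_variant(snp("1", 105, "A", "C"), model, seq) == MISSENSE    # GAA->GCA
    assert classify_variant(snp("1", 104, "G", "T"), model, seq) == STOP_GAINED # GAA->TAA
    assert classify_variant(snp("1", 107, "T", "C"), model, seq) == STOP_LOST   # TAG->CAG


def test_codon_classification_minus_strand():
    model, seq = _coding_fixture("-")
    # mirrored: CDS occupies the same genomic window on the minus strand;
    # genomic base at 0-based 105 is the complement of CDS base 103
    # CDS offsets map genomic 108-k -> CDS k
    assert classify_variant(snp("1", 109 - 5, "T", "C"), model, seq) == SYNONYMOUS
    assert classify_variant(snp("1", 109 - 4, "T", "G"), model, seq) == MISSENSE
    assert classify_variant(snp("1", 109 - 3, "C", "A"), model, seq) == STOP_GAINED
    assert classify_variant(snp("1", 109 - 6, "A", "G"), model, seq) == STOP_LOST


# ---------------------------------------------------------------------------
# InDel frame classification
# ---------------------------------------------------------------------------

def indel(chrom, pos, ref, alt):
    return Variant(chrom, pos, ref, alt, 50.0, 30, 8, 7, "het")


def test_inframe_and_frameshift(two_exon_gene):
    # CDS block 1100-1300: anchor 1-based 1200, deletes 1200..1202 (0-based)
    assert classify_indel_frame(indel("1", 1200, "AGGG", "A"), two_exon_gene) == INFRAME_DEL
    assert classify_indel_frame(indel("1", 1200, "A", "AGGGG"), two_exon_gene) == FRAMESHIFT
    assert classify_indel_frame(indel("1", 1200, "A", "AGGG"), two_exon_gene) == INFRAME_INS


def test_intronic_indel_positional(two_exon_gene):
    assert classify_indel_frame(indel("1", 1400, "AGG", "A"), two_exon_gene) == INTRON


def test_classify_variant_dispatches_indels(two_exon_gene):
    assert classify_variant(indel("1", 1200, "A", "AGGGG"), two_exon_gene) == FRAMESHIFT


# ---------------------------------------------------------------------------
# severity resolution & strand mirror property
# ---------------------------------------------------------------------------

def test_most_severe_class_across_transcripts():
    coding = Transcript("a", "g", "1", "+", ((100, 400),), ((100, 400),))
    noncoding = Transcript("b", "h", "1", "+", ((100, 400),), ())
    model = GeneModel([coding, noncoding])
    assert classify_variant(snp("1", 200), model) == CODING_UNKNOWN


def _mirror_model(txs, length):
    out = []
    for tx in txs:
        m = lambda s, e: (length - e, length - s)
        out.append(Transcript(tx.tx_id, tx.gene_id, tx.chrom,
                              "-" if tx.strand == "+" else "+",
                              tuple(sorted(m(s, e) for s, e in tx.exons)),
                              tuple(sorted(m(s, e) for s, e in tx.cds))))
    return GeneModel(out)


def test_strand_mirror_invariance():
    """Reflecting the gene and the variants through the chromosome midpoint
    (swapping strand) must not change any positional classification."""
    length = 30_000
    tx = Transcript("t", "g", "1", "+", ((10_000, 10_300), (10_500, 11_000)),
                    ((10_100, 10_300), (10_500, 10_700)))
    fwd = GeneModel([tx])
    rev = _mirror_model([tx], length)
    rng = np.random.default_rng(4)
    for pos in rng.integers(4000, 17_000, 400):
        v = snp("1", int(pos))
        mirrored = snp("1", length - int(pos) + 1)
        assert classify_variant(v, fwd) == classify_variant(mirrored, rev), pos


# ---------------------------------------------------------------------------
# brute-force per-base oracle
# ---------------------------------------------------------------------------

def paint_base_map(model: GeneModel, length: int, params=AnnotationParams()):
    """Independent per-base expected labels, painted interval by interval."""
    per_base = [[] for _ in range(length)]

    def paint(lo, hi, label):
        for p in range(max(0, lo), min(length, hi)):
            per_base[p].append(label)

    for tx in model.transcripts:
        us, ue = tx.flank_upstream(params.flank)
        ds, de = tx.flank_downstream(params.flank)
        paint(us, ue, UPSTREAM)
        paint(ds, de, DOWNSTREAM)
        for s, e in tx.introns:
            for p in range(s, e):
                d5, d3 = p - s, e - 1 - p
                din = d5 if tx.strand == "+" else d3
                dout = d3 if tx.strand == "+" else d5
                if din < params.splice_site_bp:
                    per_base[p].append(SPLICE_DONOR)
                elif dout < params.splice_site_bp:
                    per_base[p].append(SPLICE_ACCEPTOR)
                elif min(d5, d3) < params.splice_intron_bp:
                    per_base[p].append(SPLICE_REGION)
                else:
                    per_base[p].append(INTRON)
        for s, e in tx.exons:
            for p in range(s, e):
                if any(cs <= p < ce for cs, ce in tx.cds):
                    label = CODING_UNKNOWN
                elif not tx.is_coding:
                    label = NC_EXON
                elif any(cs <= p < ce for cs, ce in tx.utr5):
                    label = UTR5
                elif any(cs <= p < ce for cs, ce in tx.utr3):
                    label = UTR3
                else:
                    label = NC_EXON
                near_junction = any(
                    (s2 - params.splice_exon_bp <= p < s2) or
                    (e2 <= p < e2 + params.splice_exon_bp)
                    for s2, e2 in tx.introns)
                if near_junction and label in (UTR5, UTR3, NC_EXON):
                    label = SPLICE_REGION
                per_base[p].append(label)
    return [min(labels, key=_RANK.__getitem__) if labels else INTERGENIC
            for labels in per_base]


def test_oracle_equivalence_on_toy_genome():
    txs = [
        Transcript("t1", "g1", "1", "+", ((2000, 2300), (2500, 3000)),
                   ((2100, 2300), (2500, 2800))),
        Transcript("t2", "g2", "1", "-", ((9000, 9400), (9600, 9900)), ()),
        Transcript("t3", "g3", "1", "-", ((2600, 2900), (3050, 3200)),
                   ((2700, 2900), (3050, 3100))),
    ]
    model = GeneModel(txs)
    length = 20_000
    expected = paint_base_map(model, length)
    rng = np.random.default_rng(11)
    positions = np.unique(rng.integers(0, length, 1500))
    for p0 in positions:
        got = classify_variant(snp("1", int(p0) + 1), model)
        assert got == expected[p0], f"pos0={p0}: {got} != {expected[p0]}"


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

def test_tally_partitions_the_set(two_exon_gene, random_variants):
    vs = random_variants(3, 150, max_pos=12_000)
    table = tally_consequences(vs, two_exon_gene)
    assert table["total"].sum() == len(vs)


def test_tally_empty(two_exon_gene):
    table = tally_consequences(VariantSet.empty(), two_exon_gene)
    assert table["total"].sum() == 0
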