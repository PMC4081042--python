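"""Lightweight variant consequence classifier.

Assigns each variant one consequence class from a transcript model:
interval containment decides the non-coding classes (intron, UTRs,
up/downstream within 5 kb, splice region/site, non-coding exon,
intergenic); coding SNPs are sub-classified by codon comparison under
the standard genetic code when reference sequence is available; coding
InDels are frameshift when their length is not a multiple of 3, else
inframe insertion/deletion.

A variant overlapping several transcripts gets the most severe class
under a fixed Ensembl-like severity order (:data:`SEVERITY`).
Up/downstream distances are measured from transcript boundaries,
strand-aware: "downstream" means within 5 kb past the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .genemodel import GeneModel, Transcript
from .variants import Variant, VariantSet

# consequence class labels
STOP_GAINED = "stop gained"
STOP_LOST = "stop lost"
FRAMESHIFT = "frameshift"
MISSENSE = "missense"
INFRAME_INS = "inframe insertion"
INFRAME_DEL = "inframe deletion"
CODING_UNKNOWN = "coding sequence"   # coding SNP without sequence context
SPLICE_DONOR = "splice donor"
SPLICE_ACCEPTOR = "splice acceptor"
SPLICE_REGION = "splice region"
UTR5 = "5' UTR"
UTR3 = "3' UTR"
SYNONYMOUS = "synonymous"
INTRON = "intron"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
NC_EXON = "non-coding exon"
INTERGENIC = "intergenic"

#: most severe first; ties across transcripts resolve to the earlier entry
SEVERITY = (
    STOP_GAINED, STOP_LOST, FRAMESHIFT, SPLICE_DONOR, SPLICE_ACCEPTOR,
    MISSENSE, CODING_UNKNOWN, INFRAME_INS, INFRAME_DEL, SPLICE_REGION,
    UTR5, UTR3, SYNONYMOUS, INTRON, UPSTREAM, DOWNSTREAM, NC_EXON, INTERGENIC,
)
_RANK = {c: i for i, c in enumerate(SEVERITY)}

_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class AnnotationParams:
    flank: int = 5000           # up/downstream window, bp
    splice_intron_bp: int = 8   # splice-region extent into the intron
    splice_exon_bp: int = 3     # splice-region extent into the exon
    splice_site_bp: int = 2     # donor/acceptor: first/last intronic bases


def _translate(codon: str) -> str:
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE.get(codon, "X")


def _in_any(pos0: int, intervals) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


def _reference_base(sequence, chrom: str, pos0: int) -> str:
    """Fetch one uppercase base from a dict-of-strings or pyfaidx-like object."""
    return str(sequence[chrom][pos0]).upper()


def _codon_change(tx: Transcript, pos0: int, ref: str, alt: str, sequence) -> str:
    """Classify a coding SNP by comparing reference and alternative codons."""
    off = tx.cds_offset(pos0)
    if off is None:  # caller guarantees coding; defensive
        return CODING_UNKNOWN
    codon_idx, within = divmod(off, 3)
    # genomic coordinates of the three codon positions, in CDS order
    genomic = _cds_positions(tx, codon_idx)
    bases = [_reference_base(sequence, tx.chrom, g) for g in genomic]
    if tx.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:within] + alt.upper() + ref_codon[within + 1:]
    aa_ref, aa_alt = _translate(ref_codon), _translate(alt_codon)
    if aa_ref == aa_alt:
        return SYNONYMOUS
    if aa_alt == "*":
        return STOP_GAINED
    if aa_ref == "*":
        return STOP_LOST
    return MISSENSE


def _cds_positions(tx: Transcript, codon_idx: int) -> list[int]:
    """Genomic 0-based coordinates of codon ``codon_idx`` (CDS order)."""
    want = {codon_idx * 3, codon_idx * 3 + 1, codon_idx * 3 + 2}
    out = {}
    off = 0
    blocks = tx.cds if tx.strand == "+" else tuple(reversed(tx.cds))
    for s, e in blocks:
        size = e - s
        for w in want:
            if off <= w < off + size:
                out[w] = (s + (w - off)) if tx.strand == "+" else (e - 1 - (w - off))
        off += size
    return [out[codon_idx * 3], out[codon_idx * 3 + 1], out[codon_idx * 3 + 2]]


def _splice_class(tx: Transcript, pos0: int, params: AnnotationParams) -> str | None:
    """Splice donor/acceptor/region membership at an exon-intron junction."""
    site, region = params.splice_site_bp, params.splice_intron_bp
    for istart, iend in tx.introns:
        donor_side = istart if tx.strand == "+" else iend - 1
        if istart <= pos0 < iend:
            d_start = pos0 - istart            # distance into intron from 5'(+) end
            d_end = iend - 1 - pos0
            if tx.strand == "+":
                if d_start < site:
                    return SPLICE_DONOR
                if d_end < site:
                    return SPLICE_ACCEPTOR
            else:
                if d_end < site:
                    return SPLICE_DONOR
                if d_start < site:
                    return SPLICE_ACCEPTOR
            if d_start < region or d_end < region:
                return SPLICE_REGION
            return None
        # exonic side of the junction
        if istart - params.splice_exon_bp <= pos0 < istart or iend <= pos0 < iend + params.splice_exon_bp:
            return SPLICE_REGION
    return None


def _classify_snp_for_tx(tx: Transcript, pos0: int, ref: str, alt: str,
                         sequence, params: AnnotationParams) -> str | None:
    labels: list[str] = []
    inside = tx.start <= pos0 < tx.end
    if inside:
        if _in_any(pos0, tx.cds):
            if sequence is not None:
                labels.append(_codon_change(tx, pos0, ref, alt, sequence))
            else:
                labels.append(CODING_UNKNOWN)
        elif _in_any(pos0, tx.exons):
            if not tx.is_coding:
                labels.append(NC_EXON)
            elif _in_any(pos0, tx.utr5):
                labels.append(UTR5)
            elif _in_any(pos0, tx.utr3):
                labels.append(UTR3)
        else:
            labels.append(INTRON)
        sp = _splice_class(tx, pos0, params)
        if sp:
            labels.append(sp)
    else:
        us, ue = tx.flank_upstream(params.flank)
        ds, de = tx.flank_downstream(params.flank)
        if us <= pos0 < ue:
            labels.append(UPSTREAM)
        if ds <= pos0 < de:
            labels.append(DOWNSTREAM)
    if not labels:
        return None
    return min(labels, key=_RANK.__getitem__)


def _indel_span(v: Variant) -> tuple[int, int]:
    """Affected 0-based interval: deletion -> the deleted bases; insertion ->
    the zero-length insertion point after the anchor base."""
    d = v.signed_length
    anchor0 = v.pos - 1
    if d < 0:
        return (anchor0 + 1, anchor0 + 1 - d)
    return (anchor0 + 1, anchor0 + 1)


def _indel_in_cds(tx: Transcript, v: Variant) -> bool:
    s, e = _indel_span(v)
    if e > s:  # deletion: any deleted base coding
        return any(cs < e and s < ce for cs, ce in tx.cds)
    # insertion: the insertion point strictly inside a CDS block
    return any(cs < s < ce for cs, ce in tx.cds)


def indel_overlaps_cds(v: Variant, gene_model: GeneModel) -> bool:
    """CDS overlap under the VCF anchor convention: deleted bases follow the
    anchor, an insertion sits at the junction after the anchor base."""
    s, e = _indel_span(v)
    return any(_indel_in_cds(tx, v)
               for tx in gene_model.overlapping(v.chrom, s, max(e, s + 1)))


def _classify_indel_for_tx(tx: Transcript, v: Variant, params: AnnotationParams) -> str | None:
    if _indel_in_cds(tx, v):
        if abs(v.signed_length) % 3 != 0:
            return FRAMESHIFT
        return INFRAME_INS if v.signed_length > 0 else INFRAME_DEL
    s, e = _indel_span(v)
    # positional class from a probe base: first deleted base for deletions,
    # the anchor base for insertions (the insertion point itself has no base)
    probe = s if e > s else v.pos - 1
    return _classify_snp_for_tx(tx, probe, "N", "N", None, params)


def classify_variant(v: Variant, gene_model: GeneModel, sequence=None,
                     params: AnnotationParams = AnnotationParams()) -> str:
    """Consequence class of one variant (SNP or InDel), after severity
    resolution across all overlapping transcripts."""
    if v.chrom not in gene_model.chromosomes:
        return INTERGENIC
    if v.is_snp:
        pos0 = v.pos - 1
        labels = [_classify_snp_for_tx(tx, pos0, v.ref, v.alt, sequence, params)
                  for tx in gene_model.overlapping(v.chrom, pos0, pos0 + 1)]
    else:
        return classify_indel_frame(v, gene_model, params=params)
    labels = [l for l in labels if l is not None]
    if not labels:
        return INTERGENIC
    return min(labels, key=_RANK.__getitem__)


def classify_indel_frame(v: Variant, gene_model: GeneModel,
                         params: AnnotationParams = AnnotationParams()) -> str:
    """Frameshift/inframe for CDS-overlapping InDels, positional class otherwise."""
    if v.is_snp:
        raise ValueError("classify_indel_frame expects an InDel")
    if v.chrom not in gene_model.chromosomes:
        return INTERGENIC
    s, e = _indel_span(v)
    labels = [_classify_indel_for_tx(tx, v, params)
              for tx in gene_model.overlapping(v.chrom, s, max(e, s + 1))]
    labels = [l for l in labels if l is not None]
    if not labels:
        return INTERGENIC
    return min(labels, key=_RANK.__getitem__)


def tally_consequences(variants: VariantSet, gene_model: GeneModel, sequence=None,
                       catalog: pd.DataFrame | None = None,
                       params: AnnotationParams = AnnotationParams()) -> pd.DataFrame:
    """Class-count table over a callset; one resolved class per variant, so
    the counts partition the set. With a catalog, a known/novel split is added."""
    labels = [classify_variant(v, gene_model, sequence, params) for v in variants]
    out = pd.DataFrame({"consequence": pd.Categorical(labels, categories=list(SEVERITY))})
    if catalog is not None:
        from .summary import catalog_keys  # tally-time known/novel split
        known = variants.keys().isin(catalog_keys(catalog)) if len(catalog) else \
            np.zeros(len(variants), dtype=bool)
        out["status"] = np.where(known, "known", "novel")
        table = out.groupby(["consequence", "status"], observed=False).size().unstack(fill_value=0)
    else:
        table = out.groupby("consequence", observed=False).size().to_frame("count")
    table["total"] = table.sum(axis=1) if catalog is not None else table["count"]
    return table
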