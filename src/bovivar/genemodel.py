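"""Transcript models for consequence classification.

A :class:`GeneModel` holds transcripts with exon and CDS intervals
(internal 0-based half-open coordinates) and answers interval queries
through per-chromosome interval trees. Introns are derived as the gaps
between consecutive exons; UTRs as the exonic sequence outside the CDS
span, 5' or 3' according to strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

Interval = tuple[int, int]


def _merge(intervals: list[Interval]) -> tuple[Interval, ...]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return tuple(out)


@dataclass(frozen=True)
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.tx_id}: missing or invalid strand {self.strand!r}")
        object.__setattr__(self, "exons", _merge(list(self.exons)))
        object.__setattr__(self, "cds", _merge(list(self.cds)))
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"transcript {self.tx_id}: CDS [{cs},{ce}) outside exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @cached_property
    def introns(self) -> tuple[Interval, ...]:
        return tuple((self.exons[i][1], self.exons[i + 1][0])
                     for i in range(len(self.exons) - 1))

    @cached_property
    def cds_span(self) -> Interval | None:
        return (self.cds[0][0], self.cds[-1][1]) if self.cds else None

    @cached_property
    def utr5(self) -> tuple[Interval, ...]:
        return self._utrs()[0]

    @cached_property
    def utr3(self) -> tuple[Interval, ...]:
        return self._utrs()[1]

    def _utrs(self) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
        if not self.cds:
            return (), ()
        cs, ce = self.cds_span
        left, right = [], []
        for es, ee in self.exons:
            if es < cs:
                left.append((es, min(ee, cs)))
            if ee > ce:
                right.append((max(es, ce), ee))
        if self.strand == "+":
            return tuple(left), tuple(right)
        return tuple(right), tuple(left)

    def flank_upstream(self, size: int) -> Interval:
        """Strand-aware upstream flank; on '-' it lies beyond the transcript end."""
        if self.strand == "+":
            return (max(0, self.start - size), self.start)
        return (self.end, self.end + size)

    def flank_downstream(self, size: int) -> Interval:
        if self.strand == "+":
            return (self.end, self.end + size)
        return (max(0, self.start - size), self.start)

    # CDS coordinate mapping, used for codon lookup
    @cached_property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_offset(self, pos0: int) -> int | None:
        """0-based offset within the spliced CDS of genomic coordinate pos0,
        counted from the start codon (strand-aware); None if non-coding."""
        off = 0
        for s, e in self.cds:
            if s <= pos0 < e:
                plus = off + (pos0 - s)
                return plus if self.strand == "+" else self.cds_length - 1 - plus
            off += e - s
        return None


class GeneModel:
    """Transcript collection with fast interval lookup."""

    def __init__(self, transcripts: list[Transcript], flank: int = 5000):
        self.transcripts = list(transcripts)
        self.flank = int(flank)
        self._trees: dict[str, IntervalTree] = {}
        for tx in self.transcripts:
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            tree.addi(max(0, tx.start - self.flank), tx.end + self.flank, tx)

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[Transcript]:
        """Transcripts whose flank-extended span overlaps [start0, end0)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start0, end0)),
                      key=lambda t: (t.start, t.tx_id))

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_gene_model(path, flank: int = 5000) -> GeneModel:
    """Load transcripts from GFF3 (gene/mRNA/exon/CDS) or BED12."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return GeneModel(_read_bed12(path), flank=flank)
    return GeneModel(_read_gff3(path), flank=flank)


def _read_gff3(path: Path) -> list[Transcript]:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        if mrna.strand not in ("+", "-"):
            raise ValueError(f"transcript {mrna.id}: missing strand")
        exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            exons = [(mrna.start - 1, mrna.end)]
        gene = next(iter(mrna.attributes.get("Parent", [])), mrna.id)
        out.append(Transcript(mrna.id, gene, mrna.seqid, mrna.strand,
                              tuple(exons), tuple(cds)))
    return out


def _read_bed12(path: Path) -> list[Transcript]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 fields")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: missing strand")
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            cds = []
            if thick_e > thick_s:
                for es, ee in exons:
                    s, e = max(es, thick_s), min(ee, thick_e)
                    if e > s:
                        cds.append((s, e))
            out.append(Transcript(name, name, chrom, strand, tuple(exons), tuple(cds)))
    return out


# ---------------------------------------------------------------------------
# writer (round-trips for fixtures; GFF3 subset)
# ---------------------------------------------------------------------------

def write_gene_model(model: GeneModel, path) -> None:
    """Write transcripts as GFF3 (gene/mRNA/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(model.transcripts, key=lambda t: (t.chrom, t.start, t.tx_id)):
            g, m = tx.gene_id, tx.tx_id
            fh.write(f"{tx.chrom}\t.\tgene\t{tx.start + 1}\t{tx.end}\t.\t{tx.strand}\t.\t"
                     f"ID=gene:{g}\n")
            fh.write(f"{tx.chrom}\t.\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t{tx.strand}\t.\t"
                     f"ID={m};Parent=gene:{g}\n")
            for i, (s, e) in enumerate(tx.exons, 1):
                fh.write(f"{tx.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                         f"ID={m}.exon{i};Parent={m}\n")
            for i, (s, e) in enumerate(tx.cds, 1):
                fh.write(f"{tx.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t"
                         f"ID={m}.cds{i};Parent={m}\n")
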