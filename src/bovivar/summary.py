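"""Summary statistics over filtered callsets.

Transition/transversion ratio, homozygous:heterozygous ratio, novelty
against a known-variant catalog, multi-breed sharing patterns and InDel
length spectra. Multiallelic records are expected to be pre-split into
biallelic rows (the VCF reader does this); matching across breeds and
against the catalog requires allele identity, not just position.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .genemodel import GeneModel
from .variants import HET, HOM_ALT, VariantSet

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding used for all reported percentages/ratios."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Ts/Tv
# ---------------------------------------------------------------------------

def ts_tv_counts(snps: VariantSet) -> tuple[int, int]:
    df = snps.df.loc[snps.is_snp.to_numpy()]
    if df.empty:
        raise ValueError("no SNPs to classify")
    ts = sum(1 for r, a in zip(df["ref"], df["alt"]) if (r, a) in TRANSITIONS)
    return ts, len(df) - ts


def ts_tv_ratio(snps: VariantSet) -> float:
    """Transition/transversion ratio; transitions are A<->G and C<->T."""
    ts, tv = ts_tv_counts(snps)
    if tv == 0:
        raise ZeroDivisionError("no transversions; Ts/Tv undefined")
    return ts / tv


# ---------------------------------------------------------------------------
# hom:het
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomHet:
    """Genotype balance of a callset, reported as 1:x with x = het/hom."""

    hom: int
    het: int

    @property
    def ratio(self) -> float:
        if self.hom == 0:
            raise ZeroDivisionError("no homozygous-alt genotypes; ratio undefined")
        return self.het / self.hom

    @property
    def normalized(self) -> float:
        """het per hom, rounded to one decimal (the '1:x' convention)."""
        return round_half_up(self.ratio, 1)

    def __str__(self) -> str:
        return f"1:{self.normalized}"


def hom_het_ratio(variants: VariantSet) -> HomHet:
    gt = variants.df["gt"]
    return HomHet(int((gt == HOM_ALT).sum()), int((gt == HET).sum()))


# ---------------------------------------------------------------------------
# novelty against a known-variant catalog
# ---------------------------------------------------------------------------

def catalog_keys(catalog: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(catalog[["chrom", "pos", "ref", "alt"]])


@dataclass(frozen=True)
class NoveltyPartition:
    known: int
    novel: int

    @property
    def total(self) -> int:
        return self.known + self.novel

    @property
    def novel_pct(self) -> float:
        if self.total == 0:
            raise ZeroDivisionError("empty callset")
        return round_half_up(100.0 * self.novel / self.total, 2)


def novelty_partition(variants: VariantSet, catalog: pd.DataFrame) -> NoveltyPartition:
    """Split a callset into known/novel by exact (chrom, pos, ref, alt) match."""
    if len(catalog):
        known = variants.keys().isin(catalog_keys(catalog))
    else:
        known = np.zeros(len(variants), dtype=bool)
    k = int(np.sum(known))
    return NoveltyPartition(known=k, novel=len(variants) - k)


# ---------------------------------------------------------------------------
# multi-breed overlap (Venn-style membership patterns)
# ---------------------------------------------------------------------------

@dataclass
class OverlapTable:
    """Membership bit-pattern over breeds -> variant count.

    ``patterns`` maps a tuple of breed names (the breeds carrying the
    variant) to the number of union variants with exactly that pattern.
    """

    breeds: tuple[str, ...]
    patterns: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.patterns.values())

    def breed_total(self, breed: str) -> int:
        return sum(c for p, c in self.patterns.items() if breed in p)

    def specific(self, breed: str) -> int:
        return self.patterns.get((breed,), 0)

    def shared_all(self) -> int:
        return self.patterns.get(tuple(sorted(self.breeds)), 0)

    def specific_pct(self, breed: str) -> float:
        return round_half_up(100.0 * self.specific(breed) / self.breed_total(breed), 1)

    def shared_all_pct(self, breed: str) -> float:
        return round_half_up(100.0 * self.shared_all() / self.breed_total(breed), 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"pattern": "+".join(p), "n_breeds": len(p), "count": c}
                for p, c in sorted(self.patterns.items())]
        return pd.DataFrame(rows)


def multi_breed_overlap(callsets: Mapping[str, VariantSet]) -> OverlapTable:
    """Sharing structure of variants across breeds, matched by
    (chrom, pos, ref, alt). Permutation-invariant in breed order."""
    breeds = tuple(sorted(callsets))
    acc: dict[tuple, set] = {}
    for b in breeds:
        for key in callsets[b].keys():
            acc.setdefault(tuple(key), set()).add(b)
    patterns: dict[tuple[str, ...], int] = {}
    for key, members in acc.items():
        p = tuple(sorted(members))
        patterns[p] = patterns.get(p, 0) + 1
    return OverlapTable(breeds, patterns)


# ---------------------------------------------------------------------------
# InDel length spectrum
# ---------------------------------------------------------------------------

@dataclass
class IndelSpectrum:
    histogram: pd.Series        # signed length -> count
    short_fraction: float       # |len| <= 3 ("less than 4 bp")
    inframe_fraction: float     # |len| multiple of 3

    @property
    def total(self) -> int:
        return int(self.histogram.sum())


def indel_length_spectrum(indels: VariantSet, *, coding_only: bool = False,
                          gene_model: GeneModel | None = None) -> IndelSpectrum:
    """Histogram of signed InDel lengths plus the short (<4 bp) and 3n fractions.

    With ``coding_only`` the spectrum is restricted to InDels overlapping
    a CDS interval of ``gene_model`` (required in that case).
    """
    lengths = indels.signed_length.to_numpy()
    mask = lengths != 0
    if coding_only:
        if gene_model is None:
            raise ValueError("coding_only requires a gene model")
        from .annotate import indel_overlaps_cds  # local import, avoids cycle
        cds = np.array([indel_overlaps_cds(v, gene_model) for v in indels], dtype=bool)
        mask &= cds
    lengths = lengths[mask]
    if lengths.size == 0:
        return IndelSpectrum(pd.Series(dtype=np.int64), float("nan"), float("nan"))
    hist = pd.Series(lengths).value_counts().sort_index()
    absl = np.abs(lengths)
    return IndelSpectrum(hist,
                         short_fraction=float((absl <= 3).mean()),
                         inframe_fraction=float((absl % 3 == 0).mean()))
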