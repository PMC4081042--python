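"""Chip-vs-WGS genotype concordance.

Array markers carry two alleles, A and B; after harmonization A is the
reference allele and B the alternative, so chip calls live in
{A/A, A/B, B/B, no-call} and WGS genotypes in
{hom-ref, het, hom-alt, no-call}. Harmonization matches markers to WGS
records by (chrom, pos); a marker is excluded when its allele pair is
incompatible with the WGS ref/alt (allowing an unambiguous strand flip
for non-A/T, non-C/G markers), and a chip site with no WGS record is a
WGS hom-ref column entry (single-sample callsets only contain
non-reference sites).

Two metrics follow the contingency table:

* genotype concordance at variant sites — concordant non-reference
  genotypes over chip non-reference genotypes. Default denominator:
  chip non-reference sites at which WGS also produced a non-reference
  call (the two concordant plus the two discordant non-ref x non-ref
  cells); a strict variant using all included chip non-reference sites
  is available as ``denominator="all-chip-nonref"``.
* non-reference sensitivity — chip non-reference genotypes recovered
  as non-reference by WGS, over all included chip non-reference
  genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .summary import round_half_up
from .variants import HET, HOM_ALT, HOM_REF, NO_CALL, VariantSet

log = logging.getLogger("bovivar")

CHIP_CALLS = ("A/A", "A/B", "B/B", "./.")
WGS_CALLS = (HOM_REF, HET, HOM_ALT, NO_CALL)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ConcordanceMatrix:
    """Chip-call x WGS-genotype contingency counts plus exclusions."""

    table: pd.DataFrame     # index CHIP_CALLS, columns WGS_CALLS
    excluded: int = 0

    def __post_init__(self) -> None:
        self.table = self.table.reindex(index=list(CHIP_CALLS),
                                        columns=list(WGS_CALLS), fill_value=0).astype(np.int64)

    @classmethod
    def from_cells(cls, cells: dict[tuple[str, str], int], excluded: int = 0
                   ) -> "ConcordanceMatrix":
        t = pd.DataFrame(0, index=list(CHIP_CALLS), columns=list(WGS_CALLS), dtype=np.int64)
        for (row, col), n in cells.items():
            t.loc[row, col] = n
        return cls(t, excluded)

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    @property
    def panel_size(self) -> int:
        return self.total + self.excluded


_SWAP = {"A/A": "B/B", "A/B": "A/B", "B/B": "A/A", "./.": "./."}


def harmonize(chip: pd.DataFrame, wgs: VariantSet) -> ConcordanceMatrix:
    """Build the contingency table from a chip genotype table and a callset.

    ``chip`` needs columns marker/chrom/pos/allele_a/allele_b/call with
    calls in {A/A, A/B, B/B, ./.}. Duplicate marker positions keep the
    first occurrence with a warning.
    """
    chip = chip.copy()
    dup = chip.duplicated(subset=["chrom", "pos"])
    if dup.any():
        log.warning("%d duplicate chip marker positions; keeping first", int(dup.sum()))
        chip = chip[~dup]
    bad = ~chip["call"].isin(CHIP_CALLS)
    if bad.any():
        raise ValueError(f"unknown chip call(s): {sorted(chip.loc[bad, 'call'].unique())}")

    wdf = wgs.df.drop_duplicates(subset=["chrom", "pos"], keep="first")
    merged = chip.merge(wdf[["chrom", "pos", "ref", "alt", "gt"]],
                        on=["chrom", "pos"], how="left")
    matched = merged["ref"].notna().to_numpy()
    a = merged["allele_a"].astype(str).str.upper().to_numpy()
    b = merged["allele_b"].astype(str).str.upper().to_numpy()
    ref = merged["ref"].astype(str).to_numpy()
    alt = merged["alt"].astype(str).to_numpy()

    direct = (a == ref) & (b == alt)
    swapped = (a == alt) & (b == ref)
    ambiguous = np.isin(a, ["A", "T"]) & np.isin(b, ["A", "T"]) | \
        np.isin(a, ["C", "G"]) & np.isin(b, ["C", "G"])
    ca = np.vectorize(_COMPLEMENT.get, otypes=[object])(a, "?").astype(str)
    cb = np.vectorize(_COMPLEMENT.get, otypes=[object])(b, "?").astype(str)
    flip_direct = ~ambiguous & (ca == ref) & (cb == alt)
    flip_swapped = ~ambiguous & (ca == alt) & (cb == ref)

    compatible = direct | swapped | flip_direct | flip_swapped
    excluded = int((matched & ~compatible).sum())

    call = merged["call"].to_numpy(dtype=object).copy()
    swap_mask = matched & (swapped | flip_swapped)
    call[swap_mask] = [_SWAP[c] for c in call[swap_mask]]
    wgs_gt = np.where(matched, merged["gt"].to_numpy(dtype=object), HOM_REF)

    keep = ~matched | compatible
    table = pd.crosstab(pd.Series(call[keep], name="chip"),
                        pd.Series(wgs_gt[keep], name="wgs"))
    return ConcordanceMatrix(table, excluded)


def genotype_concordance(m: ConcordanceMatrix, denominator: str = "nonref-called") -> float:
    """Genotype concordance at variant sites, percent (one decimal, half-up).

    Numerator: chip A/B called het plus chip B/B called hom-alt. Default
    denominator adds the two discordant non-ref x non-ref cells; the
    ``"all-chip-nonref"`` variant divides by every included chip
    non-reference genotype instead.
    """
    t = m.table
    num = int(t.loc["A/B", HET] + t.loc["B/B", HOM_ALT])
    if denominator == "nonref-called":
        den = num + int(t.loc["A/B", HOM_ALT] + t.loc["B/B", HET])
    elif denominator == "all-chip-nonref":
        den = int(t.loc[["A/B", "B/B"]].to_numpy().sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if den == 0:
        raise ZeroDivisionError("no chip non-reference genotypes in denominator")
    return round_half_up(100.0 * num / den, 1)


def nonref_sensitivity(m: ConcordanceMatrix) -> float:
    """Chip non-reference genotypes recovered as non-reference by WGS,
    percent of all included chip non-reference genotypes."""
    t = m.table
    nonref_rows = t.loc[["A/B", "B/B"]]
    den = int(nonref_rows.to_numpy().sum())
    if den == 0:
        raise ZeroDivisionError("no chip non-reference genotypes")
    num = int(nonref_rows[[HET, HOM_ALT]].to_numpy().sum())
    return round_half_up(100.0 * num / den, 1)


def error_rate_estimate(m: ConcordanceMatrix) -> float:
    """Overall chip-vs-WGS genotype mismatch rate among markers called on
    both platforms — an estimate of the chip genotyping error rate when the
    WGS genotypes are taken as truth."""
    t = m.table.loc[["A/A", "A/B", "B/B"], [HOM_REF, HET, HOM_ALT]].to_numpy()
    total = t.sum()
    if total == 0:
        raise ZeroDivisionError("no doubly-called markers")
    agree = t[0, 0] + t[1, 1] + t[2, 2]
    return float(1.0 - agree / total)
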