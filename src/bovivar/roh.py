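"""Regions-of-homozygosity detection with fixed 400-kb bins.

Each autosome is divided into non-overlapping bins on a fixed grid
anchored at coordinate 0 (the final partial bin keeps its true length).
Per bin the homozygosity ratio hom/(hom+het) is computed over the
genotyped variants it contains; bins reaching the ratio threshold
(default 0.95) with at least a minimum number of informative genotypes
qualify, and maximal runs of adjacent qualifying bins are merged into
one ROH.

Only hom-ALT genotypes are observable as homozygous in a single-sample
callset (hom-ref sites produce no record), so "homozygous SNP count"
means hom-alt records. Bins with too few informative genotypes are
treated as non-qualifying: an empty bin is evidence-free, not evidence
of homozygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .variants import HET, HOM_ALT, VariantSet

log = logging.getLogger("bovivar")

BIN_LENGTH = 400_000

#: ROH size classes in Mb, half-open [lower, upper)
SIZE_CLASSES = (("<1 Mb", 0.0, 1.0), ("1-5 Mb", 1.0, 5.0), ("5-10 Mb", 5.0, 10.0),
                ("10-15 Mb", 10.0, 15.0), (">15 Mb", 15.0, float("inf")))


@dataclass(frozen=True)
class ROH:
    chrom: str
    start: int   # 0-based half-open
    end: int
    n_bins: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def size_class(self) -> str:
        mb = self.length / 1e6
        for name, lo, hi in SIZE_CLASSES:
            if lo <= mb < hi:
                return name
        raise AssertionError("unreachable")


def bin_homozygosity(genotypes, layout: GenomeLayout,
                     bin_length: int = BIN_LENGTH) -> pd.DataFrame:
    """Per-bin hom/het counts and homozygosity ratio over the autosomes.

    ``genotypes`` is a VariantSet or a DataFrame with chrom/pos/gt columns
    (1-based positions). A variant whose 0-based coordinate sits exactly on
    a grid boundary belongs to the right-hand (later) bin. Returns one row
    per bin of every autosome, including empty bins (ratio NaN).
    """
    if isinstance(genotypes, VariantSet):
        df = genotypes.df
    else:
        df = genotypes
    auto = layout.autosomes()
    rows = []
    for chrom, clen in zip(auto.names, auto.lengths):
        sub = df[(df["chrom"] == chrom) & df["gt"].isin([HOM_ALT, HET])]
        n_bins = int(np.ceil(clen / bin_length))
        bin_idx = (sub["pos"].to_numpy() - 1) // bin_length
        hom = np.bincount(bin_idx[(sub["gt"] == HOM_ALT).to_numpy()], minlength=n_bins)
        het = np.bincount(bin_idx[(sub["gt"] == HET).to_numpy()], minlength=n_bins)
        starts = np.arange(n_bins, dtype=np.int64) * bin_length
        rows.append(pd.DataFrame({
            "chrom": chrom, "bin": np.arange(n_bins), "start": starts,
            "end": np.minimum(starts + bin_length, clen),
            "hom": hom[:n_bins], "het": het[:n_bins],
        }))
    out = pd.concat(rows, ignore_index=True)
    informative = out["hom"] + out["het"]
    with np.errstate(invalid="ignore"):
        out["ratio"] = np.where(informative > 0, out["hom"] / informative, np.nan)
    return out


def call_roh(bins: pd.DataFrame, ratio_threshold: float = 0.95,
             min_informative: int = 20) -> list[ROH]:
    """Merge maximal runs of adjacent qualifying bins into ROHs.

    A bin qualifies when it has at least ``min_informative`` genotyped
    variants and homozygosity ratio >= ``ratio_threshold``; adjacency means
    consecutive bin indices on one chromosome.
    """
    rohs: list[ROH] = []
    n_thin = int(((bins["hom"] + bins["het"]) > 0).sum() -
                 ((bins["hom"] + bins["het"]) >= min_informative).sum())
    if n_thin:
        log.info("%d non-empty bins below the informative minimum (%d)", n_thin, min_informative)
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("bin")
        ok = (((sub["hom"] + sub["het"]) >= min_informative) &
              (sub["ratio"] >= ratio_threshold)).to_numpy()
        if not ok.any():
            continue
        idx = sub["bin"].to_numpy()
        change = np.concatenate([[True], (ok[1:] != ok[:-1]) | (np.diff(idx) != 1)])
        run_id = np.cumsum(change)
        for rid in np.unique(run_id):
            members = np.flatnonzero(run_id == rid)
            if not ok[members[0]]:
                continue
            block = sub.iloc[members]
            rohs.append(ROH(chrom=str(chrom), start=int(block["start"].iloc[0]),
                            end=int(block["end"].iloc[-1]), n_bins=len(members)))
    rohs.sort(key=lambda r: (r.chrom, r.start))
    return rohs


def size_distribution(rohs: list[ROH]) -> pd.Series:
    """ROH counts per size class (classes partition the list)."""
    counts = pd.Series(0, index=[name for name, *_ in SIZE_CLASSES], dtype=np.int64)
    for r in rohs:
        counts[r.size_class] += 1
    return counts


def roh_bins(rohs: list[ROH], bin_length: int = BIN_LENGTH) -> set[tuple[str, int]]:
    """Grid coordinates (chrom, bin index) of every bin inside the given ROHs."""
    out: set[tuple[str, int]] = set()
    for r in rohs:
        first = r.start // bin_length
        last = (r.end - 1) // bin_length
        out.update((r.chrom, b) for b in range(first, last + 1))
    return out


def roh_overlap(per_breed_bins: dict[str, set[tuple[str, int]]]) -> dict:
    """Shared/specific 400-kb bin patterns across breeds (Venn-style)."""
    breeds = tuple(sorted(per_breed_bins))
    union = set().union(*per_breed_bins.values()) if per_breed_bins else set()
    patterns: dict[tuple[str, ...], int] = {}
    for b in union:
        p = tuple(s for s in breeds if b in per_breed_bins[s])
        patterns[p] = patterns.get(p, 0) + 1
    return {
        "breeds": breeds,
        "patterns": patterns,
        "union_size": len(union),
        "specific": {s: patterns.get((s,), 0) for s in breeds},
        "shared_all": patterns.get(breeds, 0),
    }
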