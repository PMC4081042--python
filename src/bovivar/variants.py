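"""Variant records and the tabular container used across the pipeline.

A :class:`VariantSet` wraps a pandas DataFrame with one row per called
biallelic variant in a single sample's callset. Columns:

``chrom``      chromosome name (str)
``pos``        1-based VCF position (int); for InDels the anchor base
``ref``        reference allele sequence
``alt``        alternative allele sequence
``qual``       Phred-scaled variant quality
``depth``      total read depth at the site
``alt_fwd``    forward-strand reads supporting the alternative allele
``alt_rev``    reverse-strand reads supporting the alternative allele
``gt``         genotype, one of :data:`GENOTYPES`

SNP/insertion/deletion type and the signed InDel length are derived
from the allele strings (``len(alt) - len(ref)``; 0 for SNPs, positive
for insertions, negative for deletions).
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

HOM_REF = "hom-ref"
HET = "het"
HOM_ALT = "hom-alt"
NO_CALL = "no-call"
GENOTYPES = (HOM_REF, HET, HOM_ALT, NO_CALL)

COLUMNS = ("chrom", "pos", "ref", "alt", "qual", "depth", "alt_fwd", "alt_rev", "gt")

SNP = "snp"
INSERTION = "insertion"
DELETION = "deletion"


class Variant(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    alt_fwd: int
    alt_rev: int
    gt: str

    @property
    def signed_length(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def vtype(self) -> str:
        d = self.signed_length
        return SNP if d == 0 else (INSERTION if d > 0 else DELETION)

    @property
    def is_snp(self) -> bool:
        return self.signed_length == 0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class VariantSet:
    """Sorted collection of variants backed by a DataFrame."""

    def __init__(self, df: pd.DataFrame, *, sort: bool = True, validate: bool = True):
        df = df.loc[:, list(COLUMNS)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["qual"] = df["qual"].astype(float)
        for c in ("depth", "alt_fwd", "alt_rev"):
            df[c] = df[c].astype(np.int64)
        for c in ("chrom", "ref", "alt", "gt"):
            df[c] = df[c].astype(str)
        if validate:
            self._validate(df)
        if sort:
            df = df.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        bad = ~df["gt"].isin(GENOTYPES)
        if bad.any():
            raise ValueError(f"unknown genotype value(s): {sorted(df.loc[bad, 'gt'].unique())}")
        if (df["depth"] < df["alt_fwd"] + df["alt_rev"]).any():
            raise ValueError("depth smaller than per-strand alt read sum")
        if (df["qual"] < 0).any():
            raise ValueError("negative quality")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[Variant | tuple], **kw) -> "VariantSet":
        df = pd.DataFrame(list(records), columns=list(COLUMNS))
        return cls(df, **kw)

    @classmethod
    def empty(cls) -> "VariantSet":
        return cls(pd.DataFrame(columns=list(COLUMNS)), sort=False, validate=False)

    # -- basic protocol --------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Variant]:
        for row in self.df.itertuples(index=False):
            yield Variant(*row)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        a, b = self.df, other.df
        same_exact = all(a[c].equals(b[c]) for c in COLUMNS if c != "qual")
        return same_exact and np.allclose(a["qual"], b["qual"], atol=1e-3)

    # -- derived columns -------------------------------------------------
    @property
    def signed_length(self) -> pd.Series:
        return self.df["alt"].str.len() - self.df["ref"].str.len()

    @property
    def is_snp(self) -> pd.Series:
        return self.signed_length == 0

    @property
    def vtype(self) -> pd.Series:
        d = self.signed_length
        return pd.Series(np.where(d == 0, SNP, np.where(d > 0, INSERTION, DELETION)),
                         index=self.df.index)

    def keys(self) -> pd.MultiIndex:
        """(chrom, pos, ref, alt) identity used for catalog and cross-breed matching."""
        return pd.MultiIndex.from_frame(self.df[["chrom", "pos", "ref", "alt"]])

    # -- subsetting ------------------------------------------------------
    def subset(self, mask) -> "VariantSet":
        return VariantSet(self.df.loc[np.asarray(mask)], sort=False, validate=False)

    def snps(self) -> "VariantSet":
        return self.subset(self.is_snp.to_numpy())

    def indels(self) -> "VariantSet":
        return self.subset(~self.is_snp.to_numpy())
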