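"""Readers and writers for the formats the pipeline touches.

External conventions are respected at the boundary: VCF and GFF3 are
1-based inclusive, BED is 0-based half-open. Internally all interval
arithmetic is 0-based half-open; the conversion (subtract 1 from a
1-based start, keep the end) is bijective.

Per-strand alternative-allele read counts are carried in a configurable
VCF INFO field. The default, ``DP4`` with the alt-forward/alt-reverse
counts in slots 3 and 4, matches the samtools/bcftools convention
(ref-fwd, ref-rev, alt-fwd, alt-rev); callers that emit a dedicated
two-integer field can be accommodated with a :class:`VcfFieldMap`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

from .layout import GenomeLayout
from .variants import HET, HOM_ALT, HOM_REF, NO_CALL, VariantSet

log = logging.getLogger("bovivar")

_GT_TO_TUPLE = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), NO_CALL: (None, None)}


@dataclass(frozen=True)
class VcfFieldMap:
    """Where to find depth and per-strand alt counts in a VCF record.

    ``strand_slice`` selects the (forward, reverse) alt counts within the
    integer-tuple INFO field ``strand_field``; (2, 3) picks the last two
    entries of a samtools-style DP4.
    """

    depth_field: str = "DP"
    strand_field: str = "DP4"
    strand_slice: tuple[int, int] = (2, 3)


def _record_id(rec: pysam.VariantRecord) -> str:
    return f"{rec.chrom}:{rec.pos} {rec.ref}>{','.join(rec.alts or ['.'])}"


def read_variants(path, fields: VcfFieldMap = VcfFieldMap(),
                  rename: Mapping[str, str] | None = None) -> VariantSet:
    """Read a single-sample VCF into a :class:`VariantSet`.

    Multiallelic records are split into one row per alternative allele.
    Missing depth/strand/genotype information is a hard error naming the
    offending record; unsorted input is sorted with a warning.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"expected a single-sample VCF, found {len(samples)} samples")
        last = None
        sorted_in = True
        for rec in vf:
            if rec.alts is None:
                continue
            try:
                depth = int(rec.info[fields.depth_field])
                strand = rec.info[fields.strand_field]
                fwd = int(strand[fields.strand_slice[0]])
                rev = int(strand[fields.strand_slice[1]])
            except KeyError as e:
                raise ValueError(f"record {_record_id(rec)} lacks required field {e}") from None
            gt_tuple = rec.samples[samples[0]].get("GT")
            if gt_tuple is None:
                raise ValueError(f"record {_record_id(rec)} lacks a genotype")
            gt = _decode_gt(gt_tuple)
            qual = float(rec.qual) if rec.qual is not None else 0.0
            chrom = rename.get(rec.chrom, rec.chrom) if rename else rec.chrom
            if last is not None and (chrom, rec.pos) < last:
                sorted_in = False
            last = (chrom, rec.pos)
            for alt in rec.alts:
                rows.append((chrom, rec.pos, rec.ref, alt, qual, depth, fwd, rev, gt))
    if not sorted_in:
        log.warning("input VCF %s was not coordinate-sorted; sorting", path)
        warnings.warn(f"input VCF {path} was not coordinate-sorted; sorting", stacklevel=2)
    if not rows:
        return VariantSet.empty()
    return VariantSet.from_records(rows)


def _decode_gt(gt: tuple) -> str:
    alleles = set(a for a in gt if a is not None)
    if not alleles:
        return NO_CALL
    if alleles == {0}:
        return HOM_REF
    if alleles == {1}:
        return HOM_ALT
    return HET


def write_variants(vs: VariantSet, path, layout: GenomeLayout | None = None,
                   fields: VcfFieldMap = VcfFieldMap(), sample: str = "sample") -> None:
    """Write a :class:`VariantSet` as an uncompressed single-sample VCF."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">')
    header.add_line('##INFO=<ID=DP4,Number=4,Type=Integer,'
                    'Description="Ref fwd, ref rev, alt fwd, alt rev read counts">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if layout is not None:
        contigs = {n: l for n, l in zip(layout.names, layout.lengths)}
    else:
        # contig lines still required: use max position per chromosome
        contigs = {}
        for chrom, sub in vs.df.groupby("chrom", sort=True):
            contigs[chrom] = int(sub["pos"].max()) + 1000
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in vs:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt), qual=round(float(v.qual), 2))
            alt_total = v.alt_fwd + v.alt_rev
            ref_total = v.depth - alt_total
            rec.info["DP"] = v.depth
            rec.info["DP4"] = (ref_total - ref_total // 2, ref_total // 2, v.alt_fwd, v.alt_rev)
            rec.samples[sample]["GT"] = _GT_TO_TUPLE[v.gt]
            out.write(rec)


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------

def write_regions(regions, path, *, coords: str = "1-inclusive") -> None:
    """Write genomic intervals as BED (0-based half-open).

    ``regions`` is an iterable of (chrom, start, end[, name[, score]])
    tuples, or a DataFrame with those columns. ``coords`` declares the
    input convention: ``"1-inclusive"`` (VCF-like, converted) or
    ``"0-half-open"`` (written verbatim).
    """
    if coords not in ("1-inclusive", "0-half-open"):
        raise ValueError(f"unknown coordinate convention {coords!r}")
    if isinstance(regions, pd.DataFrame):
        regions = list(regions.itertuples(index=False))
    with open(path, "w") as fh:
        for row in regions:
            chrom, start, end, *rest = tuple(row)
            start, end = int(start), int(end)
            if coords == "1-inclusive":
                start -= 1
            if end <= start:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            extras = "".join(f"\t{x}" for x in rest)
            fh.write(f"{chrom}\t{start}\t{end}{extras}\n")


def read_regions(path) -> pd.DataFrame:
    """Read a BED3+ file; returns 0-based half-open intervals."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:3])
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# TSV tables: known-variant catalog, chip genotypes, window counts, read starts
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = ["chrom", "pos", "ref", "alt"]


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.loc[:, CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog lacks column(s) {sorted(missing)}")
    df["pos"] = df["pos"].astype(np.int64)
    return df.loc[:, CATALOG_COLUMNS]


CHIP_COLUMNS = ["marker", "chrom", "pos", "allele_a", "allele_b", "call"]


def write_chip_table(chip: pd.DataFrame, path) -> None:
    chip.loc[:, CHIP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chip_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CHIP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"chip table lacks column(s) {sorted(missing)}")
    df["pos"] = df["pos"].astype(np.int64)
    return df.loc[:, CHIP_COLUMNS]


WINDOW_COLUMNS = ["chrom", "start", "end", "test", "ref"]


def write_windows(windows: pd.DataFrame, path) -> None:
    windows.loc[:, WINDOW_COLUMNS].to_csv(path, sep="\t", index=False)


def read_windows(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for c in ("start", "end", "test", "ref"):
        df[c] = df[c].astype(np.int64)
    return df.loc[:, WINDOW_COLUMNS]


def read_read_starts(path) -> dict[str, np.ndarray]:
    """Read a two-column TSV (chrom, 1-based position) of best-hit read starts."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"],
                     dtype={0: str, 1: np.int64}, comment="#")
    return {str(c): np.sort(sub["pos"].to_numpy()) for c, sub in df.groupby("chrom")}


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML (or JSON; JSON is a YAML subset) parameter file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def setup_logging(verbose: int = 0) -> None:
    """Route package logs to stderr; -v for info, -vv for debug."""
    level = logging.WARNING - 10 * min(int(verbose), 2)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
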