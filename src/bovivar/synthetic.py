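"""Synthetic inputs with controlled statistical structure.

Stand-in for a multi-breed bovine resequencing experiment: diploid
per-breed callsets with configurable transition/transversion ratio,
hom:het balance, novelty against a known-variant catalog and
cross-breed sharing; InDel length spectra with a 3n enrichment inside
coding sequence; Poisson read-depth window tracks with embedded
copy-number segments; autozygous genomes for ROH detection; and chip
genotype tables with error, no-call and allele-incompatibility rates.

Every generator draws from its own named random stream derived from
one global seed, so a fixture can be regenerated independently and the
same seed yields byte-identical outputs. Each generator also returns a
machine-readable truth table for parameter-recovery tests.

Defaults mirror the ratios a deep (~30x) multi-breed bovine study
reports: Ts/Tv 2.24, hom:het 1:1.6, 54.12% novel SNPs, deletions
slightly outnumbering insertions, ~76.5% of InDels shorter than 4 bp
(signed lengths within -49..+31).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .variants import HET, HOM_ALT, VariantSet

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}
BASES = np.array(["A", "C", "G", "T"])

_STREAMS = {"callsets": 1, "depth": 2, "chip": 3, "autozygous": 4, "reference": 5}


def default_layout() -> GenomeLayout:
    """Small multi-chromosome toy genome (4 autosomes + X, 52 Mb)."""
    return GenomeLayout(("1", "2", "3", "4", "X"),
                        (12_000_000, 10_000_000, 16_000_000, 8_000_000, 6_000_000))


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int          # 0-based half-open
    end: int
    copy_ratio: float   # test/reference rate ratio inside the segment

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError("copy ratio must be > 0")
        if self.end <= self.start:
            raise ValueError("empty CNV segment")


@dataclass(frozen=True)
class AutozygousSegment:
    chrom: str
    start: int          # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty autozygous segment")


def _default_cnv_segments() -> tuple[CnvSegment, ...]:
    # one clean gain: copy ratio 2 spanning 300 half-overlapping 10-kb windows
    return (CnvSegment("2", 2_000_000, 3_505_000, 2.0),)


def _default_roh_segments() -> tuple[AutozygousSegment, ...]:
    # three grid-aligned segments of 0.8, 4 and 12 Mb
    return (AutozygousSegment("1", 1_200_000, 2_000_000),
            AutozygousSegment("2", 2_000_000, 6_000_000),
            AutozygousSegment("3", 2_000_000, 14_000_000))


@dataclass(frozen=True)
class SimulationConfig:
    layout: GenomeLayout = field(default_factory=default_layout)
    seed: int = 0
    # breed callsets
    n_breeds: int = 4
    snps_per_breed: int = 100_000
    ts_tv: float = 2.24
    het_per_hom: float = 1.6          # hom:het = 1:1.6
    shared_fraction: float = 0.355    # drawn from the all-breeds shared pool
    novel_fraction: float = 0.5412    # absent from the known catalog
    # InDels
    indels_per_breed: int = 10_000
    indel_insertion_fraction: float = 0.466
    indel_length_p: float = 0.383     # geometric; P(|len|<=3) ~ 0.765
    indel_max_insertion: int = 31
    indel_max_deletion: int = 49
    coding_3n_boost: float = 4.0      # weight multiplier on 3n lengths in CDS
    # per-variant sampling model
    depth_mean: float = 29.5
    depth_sd: float = 5.0
    low_quality_fraction: float = 0.05  # quality below the Phred-20 filter line
    # read-depth tracks
    window_length: int = 10_000
    read_rate: float = 0.3            # read starts per bp (~30x coverage of 90-bp reads)
    cnv_segments: tuple[CnvSegment, ...] = field(default_factory=_default_cnv_segments)
    # autozygosity
    snp_density: float = 1 / 2000     # genotyped variants per bp
    het_fraction: float = 0.615       # background heterozygote fraction
    autozygous_het_fraction: float = 0.01
    roh_segments: tuple[AutozygousSegment, ...] = field(default_factory=_default_roh_segments)
    # chip
    chip_markers: int = 50_000
    chip_nonref_fraction: float = 0.5
    chip_error_rate: float = 0.002
    chip_no_call_rate: float = 0.003
    chip_incompatible_rate: float = 0.01

    def __post_init__(self) -> None:
        fracs = (self.shared_fraction, self.novel_fraction, self.indel_insertion_fraction,
                 self.indel_length_p, self.low_quality_fraction, self.het_fraction,
                 self.autozygous_het_fraction, self.chip_nonref_fraction,
                 self.chip_error_rate, self.chip_no_call_rate, self.chip_incompatible_rate)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.ts_tv <= 0 or self.het_per_hom <= 0:
            raise ValueError("ratios must be > 0")
        for seg in self.cnv_segments + self.roh_segments:
            if seg.chrom not in self.layout:
                raise ValueError(f"truth segment on unknown chromosome {seg.chrom!r}")
            if seg.end > self.layout.length_of(seg.chrom):
                raise ValueError(f"truth segment beyond chromosome end: {seg}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# position sampling
# ---------------------------------------------------------------------------

def _unique_positions(rng: np.random.Generator, layout: GenomeLayout, n: int,
                      margin: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """n distinct random sites as (chrom index, 1-based position), at least
    ``margin`` bp clear of each chromosome end (room for deletion spans)."""
    capacity = sum(max(0, l - 2 * margin) for l in layout.lengths)
    if n > capacity:
        raise ValueError(f"requested {n} sites but genome capacity is {capacity}")
    chosen = np.empty(0, dtype=np.int64)
    g = layout.total_length
    while chosen.size < n:
        draw = rng.integers(0, g, size=int((n - chosen.size) * 1.4) + 32, dtype=np.int64)
        ci, within = layout.split_linear(draw)
        lens = np.asarray(layout.lengths)[ci]
        ok = (within >= margin) & (within < lens - margin)
        chosen = np.unique(np.concatenate([chosen, draw[ok]]))
    chosen = rng.permutation(chosen)[:n]
    ci, within = layout.split_linear(chosen)
    return ci, within + 1  # 1-based


# ---------------------------------------------------------------------------
# per-variant sampling model (shared by SNP and InDel records)
# ---------------------------------------------------------------------------

def _call_fields(rng: np.random.Generator, n: int, cfg: SimulationConfig):
    """(gt, qual, depth, alt_fwd, alt_rev) arrays for n variant records."""
    hom = rng.random(n) < 1.0 / (1.0 + cfg.het_per_hom)
    gt = np.where(hom, HOM_ALT, HET)
    low = rng.random(n) < cfg.low_quality_fraction
    qual = np.where(low, rng.uniform(5.0, 20.0, n), rng.uniform(20.0, 60.0, n))
    depth = np.maximum(np.rint(rng.normal(cfg.depth_mean, cfg.depth_sd, n)), 0).astype(np.int64)
    alt_total = np.where(hom, depth, rng.binomial(depth, 0.5))
    alt_fwd = rng.binomial(alt_total, 0.5)
    return gt, np.round(qual, 2), depth, alt_fwd, alt_total - alt_fwd


# ---------------------------------------------------------------------------
# breed callsets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCallsets:
    callsets: dict[str, VariantSet]
    catalog: pd.DataFrame                 # known-variant catalog (chrom,pos,ref,alt)
    sites: pd.DataFrame                   # per-site truth table
    per_breed: pd.DataFrame               # realized summary statistics per breed


def _snp_alleles(rng: np.random.Generator, n: int, ts_tv: float):
    ref = BASES[rng.integers(0, 4, n)]
    is_ts = rng.random(n) < ts_tv / (1.0 + ts_tv)
    tv_pick = rng.integers(0, 2, n)
    alt = np.array([TRANSITION[r] if t else TRANSVERSIONS[r][k]
                    for r, t, k in zip(ref, is_ts, tv_pick)])
    return ref, alt, is_ts


def _indel_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig,
                   coding: np.ndarray) -> np.ndarray:
    """Signed lengths: geometric magnitudes (truncated), 3n weights boosted
    inside coding sequence, sign by the insertion fraction."""
    ins = rng.random(n) < cfg.indel_insertion_fraction
    out = np.empty(n, dtype=np.int64)
    p = cfg.indel_length_p
    for is_ins, maxlen in ((True, cfg.indel_max_insertion), (False, cfg.indel_max_deletion)):
        lengths = np.arange(1, maxlen + 1)
        w = p * (1 - p) ** (lengths - 1)
        wb = w * np.where(lengths % 3 == 0, cfg.coding_3n_boost, 1.0)
        for is_coding, weights in ((False, w), (True, wb)):
            mask = (ins == is_ins) & (coding == is_coding)
            if mask.any():
                out[mask] = rng.choice(lengths, size=int(mask.sum()),
                                       p=weights / weights.sum())
    out[~ins] *= -1
    return out


def simulate_breed_callsets(config: SimulationConfig, gene_model=None,
                            reference=None) -> SimulatedCallsets:
    """Per-breed callsets plus catalog and truth tables.

    Sites are split into an all-breeds shared pool (``shared_fraction``)
    and breed-specific remainders; alleles, novelty and (for InDels)
    signed lengths are site-level so sharing is consistent, while
    genotype, quality, depth and strand counts are drawn per breed.
    With a ``gene_model``, InDel sites inside CDS use 3n-boosted length
    weights; with a ``reference`` (dict of sequences or pyfaidx Fasta),
    allele bases are read from it instead of drawn at random.
    """
    rng = config.rng("callsets")
    breeds = [f"breed{i + 1}" for i in range(config.n_breeds)]

    ns_shared = int(round(config.shared_fraction * config.snps_per_breed))
    ns_spec = config.snps_per_breed - ns_shared
    ni_shared = int(round(config.shared_fraction * config.indels_per_breed))
    ni_spec = config.indels_per_breed - ni_shared
    n_snp_sites = ns_shared + config.n_breeds * ns_spec
    n_indel_sites = ni_shared + config.n_breeds * ni_spec
    n_sites = n_snp_sites + n_indel_sites

    ci, pos = _unique_positions(rng, config.layout, n_sites,
                                margin=config.indel_max_deletion + 10)
    chroms = np.asarray(config.layout.names)[ci]

    is_snp_site = np.zeros(n_sites, dtype=bool)
    is_snp_site[:n_snp_sites] = True
    shared = np.zeros(n_sites, dtype=bool)
    shared[:ns_shared] = True
    shared[n_snp_sites:n_snp_sites + ni_shared] = True
    # breed owner of each specific site (-1 = shared)
    owner = np.full(n_sites, -1, dtype=np.int64)
    owner[ns_shared:n_snp_sites] = np.repeat(np.arange(config.n_breeds), ns_spec)
    owner[n_snp_sites + ni_shared:] = np.repeat(np.arange(config.n_breeds), ni_spec)

    known = rng.random(n_sites) < (1.0 - config.novel_fraction)

    # alleles
    ref = np.empty(n_sites, dtype=object)
    alt = np.empty(n_sites, dtype=object)
    snp_ref, snp_alt, is_ts = _snp_alleles(rng, n_snp_sites, config.ts_tv)
    ref[:n_snp_sites] = snp_ref
    alt[:n_snp_sites] = snp_alt

    idx_indel = np.arange(n_snp_sites, n_sites)
    coding = np.zeros(n_indel_sites, dtype=bool)
    if gene_model is not None:
        for j, k in enumerate(idx_indel):
            p0 = int(pos[k])  # 0-based coordinate of the base after the anchor
            coding[j] = any(any(s <= p0 < e for s, e in tx.cds)
                            for tx in gene_model.overlapping(str(chroms[k]), p0, p0 + 1))
    lengths = _indel_lengths(rng, n_indel_sites, config, coding)

    def _bases(chrom: str, start0: int, n: int) -> str:
        if reference is not None:
            return str(reference[chrom][start0:start0 + n]).upper()
        return "".join(BASES[rng.integers(0, 4, n)])

    for j, k in enumerate(idx_indel):
        anchor = _bases(str(chroms[k]), int(pos[k]) - 1, 1)
        if lengths[j] > 0:
            ref[k] = anchor
            alt[k] = anchor + _bases(str(chroms[k]), int(pos[k]), int(lengths[j]))
        else:
            ref[k] = anchor + _bases(str(chroms[k]), int(pos[k]), int(-lengths[j]))
            alt[k] = anchor
    if reference is not None:
        ref[:n_snp_sites] = [_bases(str(c), int(p) - 1, 1) for c, p in
                             zip(chroms[:n_snp_sites], pos[:n_snp_sites])]
        alt[:n_snp_sites] = [TRANSITION[r] if t else TRANSVERSIONS[r][k]
                             for r, t, k in zip(ref[:n_snp_sites], is_ts,
                                                rng.integers(0, 2, n_snp_sites))]

    sites = pd.DataFrame({
        "chrom": chroms, "pos": pos, "ref": ref.astype(str), "alt": alt.astype(str),
        "shared": shared, "owner": owner, "known": known,
        "signed_length": np.concatenate([np.zeros(n_snp_sites, dtype=np.int64), lengths]),
        "coding": np.concatenate([np.zeros(n_snp_sites, dtype=bool), coding]),
    })

    callsets: dict[str, VariantSet] = {}
    stats_rows = []
    for b, breed in enumerate(breeds):
        carrier = shared | (owner == b)
        sub = sites.loc[carrier, ["chrom", "pos", "ref", "alt"]].copy()
        gt, qual, depth, fwd, rev = _call_fields(rng, len(sub), config)
        sub["qual"], sub["depth"] = qual, depth
        sub["alt_fwd"], sub["alt_rev"], sub["gt"] = fwd, rev, gt
        vs = VariantSet(sub[["chrom", "pos", "ref", "alt", "qual", "depth",
                             "alt_fwd", "alt_rev", "gt"]])
        callsets[breed] = vs
        site_known = sites.loc[carrier, "known"]
        site_snp = is_snp_site[carrier]
        ts = int(np.sum(is_ts[np.flatnonzero(carrier[:n_snp_sites])])) \
            if n_snp_sites else 0
        stats_rows.append({
            "breed": breed, "n_variants": len(vs), "n_snps": int(site_snp.sum()),
            "transitions": ts, "transversions": int(site_snp.sum()) - ts,
            "hom": int((gt == HOM_ALT).sum()), "het": int((gt == HET).sum()),
            "novel_fraction": float((~site_known).mean()),
        })
    per_breed = pd.DataFrame(stats_rows).set_index("breed")
    catalog = sites.loc[sites["known"], ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    return SimulatedCallsets(callsets, catalog, sites, per_breed)


# ---------------------------------------------------------------------------
# read-depth tracks
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDepth:
    windows: pd.DataFrame        # chrom/start/end/test/ref window counts
    segments: pd.DataFrame       # truth CNV segments (chrom/start/end/copy_ratio)
    read_rate: float
    layout: GenomeLayout

    @property
    def total_reads(self) -> int:
        """Expected per-sample read-start count implied by the rate."""
        return int(round(self.read_rate * self.layout.total_length))


def simulate_depth_tracks(config: SimulationConfig) -> SimulatedDepth:
    """Half-overlapping window counts: reference ~ Poisson(lambda), test ~
    Poisson(lambda * copy ratio) inside truth segments (pro-rated by window
    overlap), Poisson(lambda) elsewhere."""
    rng = config.rng("depth")
    layout = config.layout
    wlen, stride = config.window_length, config.window_length // 2
    if wlen < 2:
        raise ValueError("window length must be >= 2")
    frames = []
    for chrom, clen in zip(layout.names, layout.lengths):
        starts = np.arange(0, clen, stride, dtype=np.int64)
        ends = np.minimum(starts + wlen, clen)
        lam = config.read_rate * (ends - starts)
        factor = np.ones(len(starts))
        for seg in config.cnv_segments:
            if seg.chrom != chrom:
                continue
            overlap = np.maximum(0, np.minimum(ends, seg.end) - np.maximum(starts, seg.start))
            factor += (seg.copy_ratio - 1.0) * overlap / (ends - starts)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "test": rng.poisson(lam * factor), "ref": rng.poisson(lam),
        }))
    windows = pd.concat(frames, ignore_index=True)
    segments = pd.DataFrame([{"chrom": s.chrom, "start": s.start, "end": s.end,
                              "copy_ratio": s.copy_ratio} for s in config.cnv_segments],
                            columns=["chrom", "start", "end", "copy_ratio"])
    return SimulatedDepth(windows, segments, config.read_rate, layout)


# ---------------------------------------------------------------------------
# chip genotypes
# ---------------------------------------------------------------------------

@dataclass
class SimulatedChip:
    chip: pd.DataFrame    # marker/chrom/pos/allele_a/allele_b/call
    truth: pd.DataFrame   # + true_call, is_error, is_nocall, is_incompatible


def simulate_chip(config: SimulationConfig, wgs: VariantSet) -> SimulatedChip:
    """Chip genotype table for the sample behind ``wgs``.

    Markers subsample the callset's SNP sites (becoming non-reference
    calls that mirror the WGS genotype) plus homozygous-reference sites
    absent from the callset. Corruptions: a fixed number of
    allele-incompatible markers (round(incompatible_rate * panel)),
    no-calls, then genotyping errors to a uniformly chosen other call.
    """
    rng = config.rng("chip")
    m = config.chip_markers
    snp_rows = wgs.df.loc[wgs.is_snp.to_numpy()].reset_index(drop=True)
    n_var = min(int(round(m * config.chip_nonref_fraction)), len(snp_rows))
    pick = rng.choice(len(snp_rows), size=n_var, replace=False)
    var = snp_rows.iloc[np.sort(pick)]

    # hom-ref markers at fresh positions (absent from the callset)
    taken = set(zip(wgs.df["chrom"], wgs.df["pos"]))
    need = m - n_var
    ci, pos = _unique_positions(rng, config.layout, int(need * 1.2) + 8)
    names = np.asarray(config.layout.names)
    fresh = [(c, p) for c, p in zip(names[ci], pos) if (c, p) not in taken][:need]
    if len(fresh) < need:
        raise ValueError("could not place hom-ref markers off the callset")
    hr_chrom = np.array([c for c, _ in fresh])
    hr_pos = np.array([p for _, p in fresh], dtype=np.int64)
    a_idx = rng.integers(0, 4, need)
    hr_a = BASES[a_idx]
    hr_b = BASES[(a_idx + rng.integers(1, 4, need)) % 4]

    chrom = np.concatenate([var["chrom"].to_numpy(), hr_chrom])
    pos_all = np.concatenate([var["pos"].to_numpy(), hr_pos])
    allele_a = np.concatenate([var["ref"].to_numpy(), hr_a])
    allele_b = np.concatenate([var["alt"].to_numpy(), hr_b])
    gt_map = {"hom-ref": "A/A", HET: "A/B", HOM_ALT: "B/B"}
    true_call = np.concatenate([var["gt"].map(gt_map).to_numpy(),
                                np.full(need, "A/A", dtype=object)]).astype(object)

    n = len(chrom)
    order = rng.permutation(n)
    chrom, pos_all = chrom[order], pos_all[order]
    allele_a, allele_b, true_call = allele_a[order], allele_b[order], true_call[order]
    at_variant = order < n_var

    # allele incompatibilities: a fixed count, placed among variant-site markers
    n_inc = min(int(round(config.chip_incompatible_rate * m)), int(at_variant.sum()))
    inc_idx = rng.choice(np.flatnonzero(at_variant), size=n_inc, replace=False)
    is_incompatible = np.zeros(n, dtype=bool)
    is_incompatible[inc_idx] = True
    for i in inc_idx:
        others = [x for x in BASES if x not in (allele_a[i], allele_b[i])]
        allele_b[i] = others[rng.integers(0, len(others))]

    call = true_call.copy()
    u = rng.random(n)
    is_nocall = u < config.chip_no_call_rate
    is_error = ~is_nocall & (u < config.chip_no_call_rate + config.chip_error_rate)
    call[is_nocall] = "./."
    calls3 = ("A/A", "A/B", "B/B")
    for i in np.flatnonzero(is_error):
        others = [c for c in calls3 if c != true_call[i]]
        call[i] = others[rng.integers(0, 2)]

    marker = np.array([f"mk{i:06d}" for i in range(n)])
    chip = pd.DataFrame({"marker": marker, "chrom": chrom, "pos": pos_all,
                         "allele_a": allele_a, "allele_b": allele_b, "call": call})
    truth = chip.assign(true_call=true_call, is_error=is_error, is_nocall=is_nocall,
                        is_incompatible=is_incompatible, at_variant_site=at_variant)
    return SimulatedChip(chip, truth)


# ---------------------------------------------------------------------------
# autozygous genome
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAutozygousGenome:
    genotypes: pd.DataFrame   # chrom/pos/gt
    segments: pd.DataFrame    # truth ROH segments


def simulate_autozygous_genome(config: SimulationConfig) -> SimulatedAutozygousGenome:
    """Genotyped variant positions (uniform at ``snp_density``) whose
    heterozygote fraction drops from ``het_fraction`` to
    ``autozygous_het_fraction`` inside the truth segments. Autosomes only."""
    rng = config.rng("autozygous")
    layout = config.layout.autosomes()
    frames = []
    for chrom, clen in zip(layout.names, layout.lengths):
        n = int(min(rng.poisson(config.snp_density * clen), clen))
        drawn = np.empty(0, dtype=np.int64)
        while drawn.size < n:
            extra = rng.integers(0, clen, size=int((n - drawn.size) * 1.2) + 16, dtype=np.int64)
            drawn = np.unique(np.concatenate([drawn, extra]))
        pos = np.sort(rng.permutation(drawn)[:n]) + 1
        inside = np.zeros(len(pos), dtype=bool)
        for seg in config.roh_segments:
            if seg.chrom == chrom:
                inside |= (pos > seg.start) & (pos <= seg.end)
        p_het = np.where(inside, config.autozygous_het_fraction, config.het_fraction)
        gt = np.where(rng.random(len(pos)) < p_het, HET, HOM_ALT)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "gt": gt}))
    genotypes = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["chrom", "pos", "gt"])
    segments = pd.DataFrame([{"chrom": s.chrom, "start": s.start, "end": s.end}
                             for s in config.roh_segments],
                            columns=["chrom", "start", "end"])
    return SimulatedAutozygousGenome(genotypes, segments)


# ---------------------------------------------------------------------------
# reference sequence (toy genomes for codon-level annotation)
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig) -> dict[str, str]:
    """Random uniform-base sequence per chromosome. Intended for small toy
    layouts; a 50-Mb genome is better generated per-region on demand."""
    rng = config.rng("reference")
    return {name: "".join(BASES[rng.integers(0, 4, length)])
            for name, length in zip(config.layout.names, config.layout.lengths)}
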