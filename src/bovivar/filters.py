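"""Six-rule hard-filter cascade for raw single-sample variant calls.

The cascade removes:

1. variants with quality below a minimum (default Phred 20);
2. variants with very low read depth (default < 10) or very high read
   depth (more than mean + 3·SD, with mean and SD taken over the raw,
   pre-filter callset);
3. variants lacking at least one forward AND one reverse read
   supporting the alternative allele;
4. SNPs within a small distance (default 5 bp, inclusive) of another
   SNP — both members of the pair are removed;
5. SNPs within 5 bp of an InDel — the SNP is removed, the InDel kept;
6. InDels within 10 bp of another InDel — both removed.

All six rules are evaluated as predicates against the *original* input
set (proximity is measured among all raw variants, not among the
survivors of earlier rules), so the result does not depend on any rule
ordering and re-applying the cascade to its own output is a no-op.
Distances compare VCF anchor positions and are inclusive
(|Δpos| ≤ k triggers the rule).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import VariantSet

log = logging.getLogger("bovivar")

RULES = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class FilterParams:
    min_quality: float = 20.0
    min_depth: int = 10
    high_depth_k: float = 3.0       # high bound = mean + k·SD of raw depths
    min_strand_alt: int = 1         # per strand
    snp_snp_bp: int = 5
    snp_indel_bp: int = 5
    indel_indel_bp: int = 10

    def __post_init__(self) -> None:
        numeric = (self.min_quality, self.min_depth, self.high_depth_k,
                   self.min_strand_alt, self.snp_snp_bp, self.snp_indel_bp,
                   self.indel_indel_bp)
        if any(x < 0 for x in numeric):
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterResult:
    retained: VariantSet
    removed: VariantSet
    rule_counts: dict[int, int]           # variants failing each rule (overlaps possible)
    depth_bounds: tuple[float, float]
    fail_rules: pd.DataFrame = field(repr=False)  # boolean matrix, input order

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def compute_depth_bounds(variants: VariantSet, params: FilterParams = FilterParams()
                         ) -> tuple[float, float]:
    """(low, high) read-depth bounds: low is the configured minimum, high is
    mean + k·SD over the raw callset (population SD, ddof=0)."""
    if len(variants) == 0:
        raise ValueError("cannot compute depth bounds of an empty callset")
    d = variants.df["depth"].to_numpy(dtype=float)
    high = float(d.mean() + params.high_depth_k * d.std(ddof=0))
    return (float(params.min_depth), high)


def _proximity_fail(pos: np.ndarray, other: np.ndarray, k: int) -> np.ndarray:
    """For each sorted position in `pos`, is any position in sorted `other`
    (excluding an identical index when arrays are the same object) within k bp?"""
    if len(other) == 0 or len(pos) == 0:
        return np.zeros(len(pos), dtype=bool)
    fail = np.zeros(len(pos), dtype=bool)
    # nearest neighbours on each side suffice for a distance test
    if other is pos:
        # `pos[i]` sits at index i in the sorted array; neighbours are i-1, i+1
        left = np.arange(len(pos)) - 1
        right = np.arange(len(pos)) + 1
    else:
        idx = np.searchsorted(other, pos)
        left = idx - 1
        right = idx
    ok_l = left >= 0
    fail[ok_l] |= (pos[ok_l] - other[left[ok_l]]) <= k
    ok_r = right < len(other)
    fail[ok_r] |= (other[right[ok_r]] - pos[ok_r]) <= k
    return fail


def apply_filters(variants: VariantSet, params: FilterParams = FilterParams(),
                  depth_bounds: tuple[float, float] | None = None) -> FilterResult:
    """Apply the six-rule cascade; see module docstring for semantics.

    ``depth_bounds`` fixes the rule-2 (low, high) thresholds; by default
    they are estimated from the input itself (mean + k·SD of its raw
    depths). Passing the bounds of the original raw callset makes the
    cascade idempotent on its own output.
    """
    df = variants.df
    n = len(df)
    fails = pd.DataFrame(False, index=range(n),
                         columns=[f"rule{r}" for r in RULES])
    if n == 0:
        return FilterResult(VariantSet.empty(), VariantSet.empty(),
                            {r: 0 for r in RULES}, (float(params.min_depth), np.inf), fails)
    if not df["pos"].groupby(df["chrom"], sort=False).apply(
            lambda s: bool(s.is_monotonic_increasing)).all():
        warnings.warn("unsorted variant input; sorting before filtering", stacklevel=2)
        variants = VariantSet(df, sort=True)
        df = variants.df

    low, high = depth_bounds if depth_bounds is not None \
        else compute_depth_bounds(variants, params)
    depth = df["depth"].to_numpy()
    fails["rule1"] = (df["qual"] < params.min_quality).to_numpy()
    fails["rule2"] = (depth < low) | (depth > high)
    fails["rule3"] = ((df["alt_fwd"] < params.min_strand_alt) |
                      (df["alt_rev"] < params.min_strand_alt)).to_numpy()

    is_snp = variants.is_snp.to_numpy()
    for chrom, sub in df.groupby("chrom", sort=False):
        loc = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        snp_mask = is_snp[loc]
        spos, ipos = pos[snp_mask], pos[~snp_mask]
        r4 = _proximity_fail(spos, spos, params.snp_snp_bp)
        r5 = _proximity_fail(spos, ipos, params.snp_indel_bp)
        r6 = _proximity_fail(ipos, ipos, params.indel_indel_bp)
        fails.loc[loc[snp_mask], "rule4"] = r4
        fails.loc[loc[snp_mask], "rule5"] = r5
        fails.loc[loc[~snp_mask], "rule6"] = r6

    any_fail = fails.any(axis=1).to_numpy()
    counts = {r: int(fails[f"rule{r}"].sum()) for r in RULES}
    retained = variants.subset(~any_fail)
    removed = variants.subset(any_fail)
    log.info("filter cascade: %d in, %d retained, per-rule removals %s",
             n, len(retained), counts)
    return FilterResult(retained, removed, counts, (low, high), fails)


def removal_summary(result: FilterResult) -> pd.DataFrame:
    """Per-rule removal counts as a tidy table (for the CLI summary TSV)."""
    rows = [{"rule": r, "removed": result.rule_counts[r]} for r in RULES]
    rows.append({"rule": "any", "removed": result.n_removed})
    return pd.DataFrame(rows)
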