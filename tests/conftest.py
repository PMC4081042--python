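"""Shared fixtures: tiny genomes, variant factories, toy gene models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bovivar import GenomeLayout, VariantSet
from bovivar.genemodel import GeneModel, Transcript
from bovivar.variants import HET, HOM_ALT, HOM_REF


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout(("1", "2"), (1_000_000, 800_000))


@pytest.fixture
def make_variant():
    """Factory for a variant row that passes every filter by default."""

    def _make(chrom="1", pos=100, ref="A", alt="G", qual=50.0, depth=30,
              alt_fwd=8, alt_rev=7, gt=HET):
        return (chrom, pos, ref, alt, qual, depth, alt_fwd, alt_rev, gt)

    return _make


@pytest.fixture
def variant_set(make_variant):
    def _make(rows):
        return VariantSet.from_records([make_variant(**r) for r in rows])

    return _make


def random_variant_frame(rng: np.random.Generator, n: int, *, n_chroms: int = 2,
                         max_pos: int = 2000, indel_fraction: float = 0.3) -> pd.DataFrame:
    """Random raw-callset rows exercising all six filter rules."""
    chrom = rng.integers(1, n_chroms + 1, n).astype(str)
    pos = rng.integers(1, max_pos + 1, n)
    bases = np.array(["A", "C", "G", "T"])
    base_idx = rng.integers(0, 4, n)
    is_indel = rng.random(n) < indel_fraction
    ins = rng.random(n) < 0.5
    ref, alt = [], []
    for i in range(n):
        b = bases[base_idx[i]]
        if not is_indel[i]:
            ref.append(b)
            alt.append(bases[(base_idx[i] + rng.integers(1, 4)) % 4])
        else:
            ext = "".join(bases[rng.integers(0, 4, rng.integers(1, 6))])
            if ins[i]:
                ref.append(b)
                alt.append(b + ext)
            else:
                ref.append(b + ext)
                alt.append(b)
    ref, alt = np.array(ref, dtype=object), np.array(alt, dtype=object)
    depth = rng.integers(0, 61, n)
    alt_total = rng.integers(0, depth + 1)
    alt_fwd = rng.integers(0, alt_total + 1)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref.astype(str), "alt": alt.astype(str),
        "qual": np.round(rng.uniform(0, 60, n), 2), "depth": depth,
        "alt_fwd": alt_fwd, "alt_rev": alt_total - alt_fwd,
        "gt": np.array([HOM_REF, HET, HOM_ALT])[rng.integers(0, 3, n)],
    })


@pytest.fixture
def random_variants():
    def _make(seed: int, n: int = 200, **kw) -> VariantSet:
        return VariantSet(random_variant_frame(np.random.default_rng(seed), n, **kw))

    return _make


@pytest.fixture
def two_exon_gene() -> GeneModel:
    """Plus-strand coding transcript: exons 1000-1300 / 1500-1800,
    CDS 1100-1300 + 1500-1700 (0-based half-open)."""
    tx = Transcript("tx1", "g1", "1", "+", ((1000, 1300), (1500, 1800)),
                    ((1100, 1300), (1500, 1700)))
    return GeneModel([tx])
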