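"""Genome layout: ordered chromosome names and lengths.

All modules that need chromosome boundaries (window tiling, binning,
position simulation) take a :class:`GenomeLayout`. Lengths are in base
pairs; internal coordinates throughout the package are 0-based
half-open, while VCF/GFF positions are 1-based inclusive at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# chromosome names that are never treated as autosomes
NON_AUTOSOMES = frozenset({"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"})


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with their lengths (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be > 0")
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        object.__setattr__(self, "lengths", tuple(int(l) for l in self.lengths))

    @property
    def by_name(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.by_name[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.by_name

    def autosomes(self) -> "GenomeLayout":
        """Layout restricted to autosomes (drops X/Y/MT-style names)."""
        keep = [(n, l) for n, l in zip(self.names, self.lengths) if n not in NON_AUTOSOMES]
        if not keep:
            raise ValueError("no autosomes in layout")
        names, lengths = zip(*keep)
        return GenomeLayout(names, lengths)

    # -- linearized coordinates, used by the simulators ------------------
    def offsets(self) -> np.ndarray:
        """Cumulative start offset of each chromosome in a concatenated genome."""
        return np.concatenate([[0], np.cumsum(self.lengths)[:-1]]).astype(np.int64)

    def split_linear(self, linear: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map linear 0-based coordinates to (chromosome index, within-chromosome coord)."""
        bounds = np.cumsum(self.lengths)
        idx = np.searchsorted(bounds, linear, side="right")
        if np.any(idx >= len(self.names)):
            raise ValueError("linear coordinate beyond genome end")
        within = linear - self.offsets()[idx]
        return idx, within
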