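"""Fixed-width genome tilings: the coordinate frame for binned read-depth analysis.

A binning tiles every chromosome with adjacent, non-overlapping windows of a
user-chosen width; the final window of each chromosome may be shorter.  All
coordinates are 0-based half-open internally and in BED-style outputs;
human-readable region strings are rendered 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBinning",
    "make_binning",
    "read_chrom_sizes",
    "parse_region",
    "format_region",
]


@dataclass(frozen=True)
class GenomeBinning:
    """Tiling of a genome into fixed-width bins.

    Attributes
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    bin_size:
        Nominal bin width in bp; every bin except possibly the last per
        chromosome has exactly this length.
    chrom_index, starts, ends:
        Per-bin arrays: index into ``chromosomes``, and the half-open span.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    chrom_index: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def is_partial(self) -> np.ndarray:
        """Boolean per bin: True for terminal bins shorter than ``bin_size``."""
        return (self.ends - self.starts) < self.bin_size

    def chrom_slice(self, name: str) -> slice:
        """Contiguous slice of bin indices belonging to chromosome ``name``."""
        idx = self.chrom_names.index(name)
        lo = int(np.searchsorted(self.chrom_index, idx, side="left"))
        hi = int(np.searchsorted(self.chrom_index, idx, side="right"))
        return slice(lo, hi)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos`` (0-based)."""
        sl = self.chrom_slice(chrom)
        length = dict(self.chromosomes)[chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside chromosome {chrom!r} (length {length})")
        return sl.start + pos // self.bin_size

    def to_frame(self) -> pd.DataFrame:
        names = np.asarray(self.chrom_names, dtype=object)
        return pd.DataFrame(
            {"chrom": names[self.chrom_index], "start": self.starts, "end": self.ends}
        )


def make_binning(chrom_sizes, bin_size: int) -> GenomeBinning:
    """Tile each chromosome with ``bin_size`` windows, keeping the partial tail bin.

    Parameters
    ----------
    chrom_sizes:
        Iterable of ``(name, length_bp)``; order is preserved.
    bin_size:
        Window width in bp, > 0.
    """
    chrom_sizes = tuple((str(n), int(l)) for n, l in chrom_sizes)
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    names = [n for n, _ in chrom_sizes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in chrom_sizes")
    for name, length in chrom_sizes:
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    chrom_index, starts, ends = [], [], []
    for ci, (_, length) in enumerate(chrom_sizes):
        bin_starts = np.arange(0, length, bin_size, dtype=np.int64)
        chrom_index.append(np.full(len(bin_starts), ci, dtype=np.int64))
        starts.append(bin_starts)
        ends.append(np.minimum(bin_starts + bin_size, length))
    return GenomeBinning(
        chromosomes=chrom_sizes,
        bin_size=int(bin_size),
        chrom_index=np.concatenate(chrom_index),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
    )


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    """Read a two-column ``name<TAB>length`` chromosome-sizes table."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], comment="#")
    return [(str(n), int(l)) for n, l in zip(df[0], df[1])]


_REGION_RE = re.compile(r"^(?:chr)?(\w+):([\d,]+)[-–]([\d,]+)$", re.IGNORECASE)


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse a region string like ``"Chr8:6,800,000-11,800,000"``.

    The printed numbers are interpreted as half-open boundary coordinates
    (bin edges), so the span length is simply ``end - start``.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region string {text!r}")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if end <= start:
        raise ValueError(f"region {text!r} has end <= start")
    return chrom, start, end


def format_region(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open span as a 1-based inclusive region string."""
    return f"{chrom}:{start + 1:,}-{end:,}"
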