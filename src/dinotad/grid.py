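"""Fixed-resolution binning of a genome into a per-chromosome bin grid.

Coordinates are 0-based half-open throughout the package. Each chromosome is
tiled in ``resolution``-sized steps; the final bin may be short, and its true
length is retained for per-bp conversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from dinotad.errors import CoordinateError


@dataclass(frozen=True)
class BinGrid:
    """Bin index <-> (chromosome, start) mapping at a fixed resolution.

    Parameters
    ----------
    chromosomes:
        Chromosome names, in genome order.
    lengths:
        Chromosome lengths in bp, keyed by name.
    resolution:
        Bin size in bp.
    """

    chromosomes: tuple[str, ...]
    lengths: dict[str, int]
    resolution: int
    _n_bins: dict[str, int] = field(init=False, repr=False)

    def __init__(self, chromosomes, lengths, resolution):
        object.__setattr__(self, "chromosomes", tuple(chromosomes))
        object.__setattr__(self, "lengths", dict(lengths))
        object.__setattr__(self, "resolution", int(resolution))
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        missing = [c for c in self.chromosomes if c not in self.lengths]
        if missing:
            raise ValueError(f"lengths missing for chromosomes: {missing}")
        object.__setattr__(
            self,
            "_n_bins",
            {c: math.ceil(self.lengths[c] / self.resolution) for c in self.chromosomes},
        )

    def n_bins(self, chrom: str) -> int:
        """Number of bins tiling ``chrom`` (``ceil(length / resolution)``)."""
        self._check_chrom(chrom)
        return self._n_bins[chrom]

    def bin_index(self, chrom: str, start: int) -> int:
        """Bin index of the bin whose start is ``start`` (must lie on the grid)."""
        self._check_chrom(chrom)
        if start % self.resolution != 0:
            raise CoordinateError(
                f"position {chrom}:{start} is not a multiple of resolution {self.resolution}"
            )
        idx = start // self.resolution
        if not 0 <= idx < self._n_bins[chrom]:
            raise CoordinateError(f"bin start {chrom}:{start} outside chromosome")
        return idx

    def bin_start(self, chrom: str, index: int) -> int:
        """Genomic start (bp) of bin ``index`` on ``chrom``."""
        self._check_chrom(chrom)
        if not 0 <= index < self._n_bins[chrom]:
            raise CoordinateError(f"bin index {index} outside {chrom}")
        return index * self.resolution

    def bin_span(self, chrom: str, index: int) -> tuple[int, int]:
        """Half-open (start, end) of bin ``index``; the last bin may be short."""
        start = self.bin_start(chrom, index)
        return start, min(start + self.resolution, self.lengths[chrom])

    def bin_of_position(self, chrom: str, pos: int) -> int:
        """Bin index containing arbitrary position ``pos`` (not required on-grid)."""
        self._check_chrom(chrom)
        if not 0 <= pos <= self.lengths[chrom]:
            raise CoordinateError(f"position {chrom}:{pos} outside chromosome")
        return min(pos // self.resolution, self._n_bins[chrom] - 1)

    def same_grid(self, other: "BinGrid") -> bool:
        return (
            self.chromosomes == other.chromosomes
            and self.lengths == other.lengths
            and self.resolution == other.resolution
        )

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self.lengths:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
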