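"""Genomic interval arithmetic for locus and gene windows.

All coordinates here are 0-based half-open (BED convention); conversion from
1-based VCF positions happens at construction time only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from .panel_io import DataError


@dataclass(frozen=True)
class Region:
    """A genomic interval ``[start, end)``, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos1(self, chrom: str, pos1: int) -> bool:
        """Membership test for a 1-based position."""
        return chrom == self.chrom and self.start <= pos1 - 1 < self.end


class RegionSet:
    """A sorted, pairwise-disjoint set of regions (the result of a merge)."""

    def __init__(self, regions: Sequence[Region]):
        self.regions = list(regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        strip = lambda rs: [(r.chrom, r.start, r.end) for r in rs]
        return strip(self.regions) == strip(other.regions)

    @property
    def covered_bp(self) -> int:
        return sum(len(r) for r in self.regions)

    def contains_pos1(self, chrom: str, pos1: int) -> bool:
        return any(r.contains_pos1(chrom, pos1) for r in self.regions)


def locus_window(chrom: str, index_pos: int, flank_bp: int = 100_000,
                 label: str = "") -> Region:
    """Window of ±``flank_bp`` around a 1-based index-variant position.

    Covers every 1-based position ``p`` with ``|p - index_pos| <= flank_bp``,
    clipped at the chromosome start (position 1).  The default flank gives a
    200 kb locus around a GWAS index SNP.
    """
    if flank_bp < 0:
        raise DataError(f"flank_bp must be >= 0, got {flank_bp}")
    if index_pos < 1:
        raise DataError(f"index_pos must be >= 1, got {index_pos}")
    start0 = max(0, index_pos - 1 - flank_bp)
    end0 = index_pos + flank_bp  # half-open end covers 1-based index_pos+flank
    return Region(chrom, start0, end0, label)


def gene_region(chrom: str, transcripts: Sequence[tuple[int, int]],
                flank_bp: int = 50_000, label: str = "") -> Region:
    """Spanning interval over a gene's transcripts plus flanking sequence.

    ``transcripts`` are 0-based half-open (start, end) pairs on one
    chromosome; the result is ``[min(start) - flank, max(end) + flank)``
    clipped at 0.  The default 50 kb flank matches the priority-gene window.
    """
    if not transcripts:
        raise DataError("gene_region: empty transcript list")
    if flank_bp < 0:
        raise DataError(f"flank_bp must be >= 0, got {flank_bp}")
    start = max(0, min(s for s, _ in transcripts) - flank_bp)
    end = max(e for _, e in transcripts) + flank_bp
    return Region(chrom, start, end, label)


def merge_regions(regions: Iterable[Region]) -> RegionSet:
    """Merge overlapping and touching regions into a minimal disjoint set.

    Labels of merged regions are joined with ``;`` (empty labels dropped).
    Idempotent; the union of the output equals the union of the input.
    """
    regs = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[Region] = []
    for r in regs:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            labels = [x for x in (last.label, r.label) if x]
            merged[-1] = Region(
                last.chrom, last.start, max(last.end, r.end),
                ";".join(dict.fromkeys(labels)),
            )
        else:
            merged.append(r)
    return RegionSet(merged)


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` table."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def clip_to_chrom(region: Region, sizes: Optional[dict[str, int]]) -> Region:
    """Right-clip a region at the chromosome end when sizes are known."""
    if sizes is None or region.chrom not in sizes:
        return region
    end = min(region.end, sizes[region.chrom])
    return Region(region.chrom, region.start, end, region.label)
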