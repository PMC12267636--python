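"""Strand-aware genomic intervals and interval-set operations.

All coordinates are 0-based half-open (BED native); GFF3 input is converted
on read by :mod:`trdar.io`.  :class:`RegionSet` is the universal currency for
consensus ATAC peaks, ChIP peaks, chromatin-state segments and blacklist
hotspots throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Iterator, List, Optional

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A located, optionally stranded genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.`` (default unstranded).
    id : str, optional
        Stable identifier, unique within a :class:`RegionSet`.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got ({self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 base on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """An ordered collection of uniquely identified intervals.

    Regions without an ``id`` are assigned sequential ones (``region_000001``
    ...) at construction.  Overlap queries run against per-chromosome interval
    trees built lazily.
    """

    def __init__(self, regions: Iterable[GenomicInterval]):
        regions = list(regions)
        out: List[GenomicInterval] = []
        seen: Dict[str, int] = {}
        auto = 0
        for r in regions:
            if r.id is None:
                auto += 1
                r = replace(r, id=f"region_{auto:06d}")
            if r.id in seen:
                raise ValueError(f"duplicate region id {r.id!r}")
            seen[r.id] = len(out)
            out.append(r)
        self._regions = out
        self._index = seen
        self._trees: Optional[Dict[str, IntervalTree]] = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._index

    def __getitem__(self, region_id: str) -> GenomicInterval:
        return self._regions[self._index[region_id]]

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self._regions]  # type: ignore[misc]

    # -- queries ------------------------------------------------------------
    def _chrom_trees(self) -> Dict[str, IntervalTree]:
        if self._trees is None:
            trees: Dict[str, IntervalTree] = {}
            for r in self._regions:
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.id)
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> List[str]:
        """Ids of member regions sharing >= 1 base with ``chrom:start-end``."""
        tree = self._chrom_trees().get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, iv.data))
        return [iv.data for iv in hits]

    def overlap_map(self, other: "RegionSet") -> Dict[str, List[str]]:
        """Map each of our region ids to the ids of ``other`` it overlaps.

        A pair is reported iff the two intervals share at least one base on
        the same chromosome (half-open semantics: ``(0,10)`` and ``(10,20)``
        do not overlap).  The underlying relation is symmetric.
        """
        return {
            r.id: other.overlapping(r.chrom, r.start, r.end)  # type: ignore[misc]
            for r in self._regions
        }

    def filter_blacklist(self, hotspots: "RegionSet") -> "RegionSet":
        """Drop member regions overlapping any hotspot by >= 1 base.

        An empty hotspot set is the identity.  The number of removed regions
        is logged.
        """
        if len(hotspots) == 0:
            return RegionSet(self._regions)
        kept = [
            r
            for r in self._regions
            if not hotspots.overlapping(r.chrom, r.start, r.end)
        ]
        logger.info(
            "blacklist filter removed %d of %d regions",
            len(self._regions) - len(kept),
            len(self._regions),
        )
        return RegionSet(kept)

    def subset(self, region_ids: Iterable[str]) -> "RegionSet":
        return RegionSet(self[i] for i in region_ids)

    # -- frames -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self._regions],
                "start": [r.start for r in self._regions],
                "end": [r.end for r in self._regions],
                "id": [r.id for r in self._regions],
                "strand": [r.strand for r in self._regions],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        ids = df["id"] if "id" in df.columns else [None] * len(df)
        strands = df["strand"] if "strand" in df.columns else ["."] * len(df)
        return cls(
            GenomicInterval(c, int(s), int(e), strand=str(st), id=i)
            for c, s, e, st, i in zip(df["chrom"], df["start"], df["end"], strands, ids)
        )


def overlap_regions(a: RegionSet, b: RegionSet) -> Dict[str, List[str]]:
    """Shared >= 1 bp overlap mapping from ``a`` ids to lists of ``b`` ids."""
    return a.overlap_map(b)


def filter_blacklist(peaks: RegionSet, hotspots: RegionSet) -> RegionSet:
    """Remove peaks overlapping blacklist hotspots (genomic-DNA control)."""
    return peaks.filter_blacklist(hotspots)
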