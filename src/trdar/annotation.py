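"""Peak-to-gene assignment and genomic-category classification.

Each region receives exactly one category by precedence
``Promoter > 5'UTR > 3'UTR > Exon > Intron > Distal Intergenic``, where the
promoter window spans ``tss_upstream`` bases upstream to ``tss_downstream``
bases downstream of the TSS, mirrored on the minus strand.  Regions labelled
Intron or Distal Intergenic (and nothing coding/promoter-proximal) form the
distal non-coding (distNC) class used as an enhancer proxy.

The closest gene is the gene whose TSS lies nearest the region midpoint;
the signed TSS distance is negative upstream of the TSS (strand-aware).
Region strand is ignored for classification (ATAC peaks are unstranded);
gene strand orients the promoter window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.base import BaseEstimator

from .intervals import GenomicInterval, RegionSet

CATEGORIES = ("Promoter", "5'UTR", "3'UTR", "Exon", "Intron", "Distal Intergenic")
DISTNC_CATEGORIES = frozenset({"Intron", "Distal Intergenic"})


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon/intron/UTR structure on one chromosome.

    ``gene_span`` is 0-based half-open; the TSS is ``gene_span[0]`` on the
    plus strand and ``gene_span[1] - 1`` on the minus strand.  Exons must lie
    within the span and be non-overlapping after sorting.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_span: Tuple[int, int]
    exons: Tuple[Tuple[int, int], ...] = ()
    five_prime_utrs: Tuple[Tuple[int, int], ...] = ()
    three_prime_utrs: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        s, e = self.gene_span
        if not (0 <= s < e):
            raise ValueError(f"{self.gene_id}: bad gene span {self.gene_span}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: gene strand must be + or -")
        prev_end = None
        for xs, xe in sorted(self.exons):
            if xs < s or xe > e:
                raise ValueError(f"{self.gene_id}: exon ({xs},{xe}) outside span")
            if prev_end is not None and xs < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = xe

    @property
    def tss(self) -> int:
        return self.gene_span[0] if self.strand == "+" else self.gene_span[1] - 1

    def promoter_window(self, upstream: int, downstream: int) -> Tuple[int, int]:
        """Strand-aware promoter window, half-open on the downstream side."""
        if self.strand == "+":
            return max(0, self.tss - upstream), self.tss + downstream
        return max(0, self.tss - downstream + 1), self.tss + upstream + 1


@dataclass
class AnnotationConfig:
    """Promoter window sizes and the category precedence order."""

    tss_upstream: int = 1500
    tss_downstream: int = 500
    category_precedence: Tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        if self.tss_upstream < 0 or self.tss_downstream < 0:
            raise ValueError("promoter window sizes must be >= 0")


@dataclass(frozen=True)
class AnnotatedRegion:
    """A region joined to its genomic category and closest gene."""

    region: GenomicInterval
    category: str
    closest_gene: Optional[str]
    distance_to_tss: Optional[int]

    @property
    def is_distnc(self) -> bool:
        return self.category in DISTNC_CATEGORIES

    @property
    def is_prom(self) -> bool:
        return self.category == "Promoter"

    @property
    def is_3putr(self) -> bool:
        return self.category == "3'UTR"


class RegionAnnotator(BaseEstimator):
    """Classify regions by genomic context and assign their closest gene.

    Parameters
    ----------
    tss_upstream, tss_downstream : int
        Promoter window extent around the TSS (defaults 1500 / 500 bases).

    Attributes
    ----------
    genes_ : list of GeneModel
        The fitted annotation.
    n_genes_ : int
    """

    def __init__(self, tss_upstream: int = 1500, tss_downstream: int = 500):
        self.tss_upstream = tss_upstream
        self.tss_downstream = tss_downstream

    # -- fitting ------------------------------------------------------------
    def fit(self, genes: Sequence[GeneModel], y=None) -> "RegionAnnotator":
        genes = list(genes)
        if not genes:
            raise ValueError("genes must be non-empty")
        AnnotationConfig(self.tss_upstream, self.tss_downstream)  # validate
        self.genes_ = genes
        self.n_genes_ = len(genes)
        self._gene_by_id = {g.gene_id: g for g in genes}
        if len(self._gene_by_id) != len(genes):
            raise ValueError("gene ids must be unique")
        trees: Dict[str, Dict[str, IntervalTree]] = {}

        def _add(chrom: str, layer: str, start: int, end: int) -> None:
            trees.setdefault(chrom, {}).setdefault(layer, IntervalTree()).addi(
                start, end
            )

        tss_pos: Dict[str, List[int]] = {}
        tss_ids: Dict[str, List[str]] = {}
        for g in genes:
            ps, pe = g.promoter_window(self.tss_upstream, self.tss_downstream)
            if ps < pe:
                _add(g.chrom, "Promoter", ps, pe)
            for s, e in g.five_prime_utrs:
                _add(g.chrom, "5'UTR", s, e)
            for s, e in g.three_prime_utrs:
                _add(g.chrom, "3'UTR", s, e)
            for s, e in g.exons:
                _add(g.chrom, "Exon", s, e)
            _add(g.chrom, "Gene", *g.gene_span)
            tss_pos.setdefault(g.chrom, []).append(g.tss)
            tss_ids.setdefault(g.chrom, []).append(g.gene_id)
        self._trees = trees
        # sort TSS arrays by (position, gene_id) so equidistant ties resolve
        # to the lexicographically smallest gene id deterministically
        self._tss: Dict[str, Tuple[np.ndarray, List[str], np.ndarray]] = {}
        for chrom, pos in tss_pos.items():
            order = sorted(range(len(pos)), key=lambda i: (pos[i], tss_ids[chrom][i]))
            arr = np.array([pos[i] for i in order])
            ids = [tss_ids[chrom][i] for i in order]
            self._tss[chrom] = (arr, ids, arr)
        return self

    # -- annotation ---------------------------------------------------------
    def _category(self, region: GenomicInterval) -> str:
        layers = self._trees.get(region.chrom, {})
        for cat in ("Promoter", "5'UTR", "3'UTR", "Exon"):
            t = layers.get(cat)
            if t is not None and t.overlap(region.start, region.end):
                return cat
        t = layers.get("Gene")
        if t is not None and t.overlap(region.start, region.end):
            return "Intron"
        return "Distal Intergenic"

    def _closest(self, region: GenomicInterval) -> Tuple[Optional[str], Optional[int]]:
        entry = self._tss.get(region.chrom)
        if entry is None:
            return None, None
        arr, ids, _ = entry
        mid = region.midpoint
        j = int(np.searchsorted(arr, mid))
        dbest = min(
            abs(int(arr[k]) - mid) for k in (j - 1, j) if 0 <= k < len(arr)
        )
        # all TSS at distance dbest (duplicated positions allowed); ties break
        # to the lexicographically smallest gene id
        lo = int(np.searchsorted(arr, mid - dbest, side="left"))
        hi = int(np.searchsorted(arr, mid + dbest, side="right"))
        candidates = [k for k in range(lo, hi) if abs(int(arr[k]) - mid) == dbest]
        best = min(candidates, key=lambda k: ids[k])
        gene = self._gene_by_id[ids[best]]
        signed = mid - gene.tss if gene.strand == "+" else gene.tss - mid
        return ids[best], int(signed)

    def annotate(self, region: GenomicInterval) -> AnnotatedRegion:
        """Annotate a single region (warns for unknown chromosomes)."""
        if region.chrom not in self._trees and region.chrom not in self._tss:
            warnings.warn(
                f"region {region.id or region} on chromosome {region.chrom!r} "
                "absent from the annotation; labelled Distal Intergenic "
                "with no closest gene"
            )
            return AnnotatedRegion(region, "Distal Intergenic", None, None)
        gene, dist = self._closest(region)
        return AnnotatedRegion(region, self._category(region), gene, dist)

    def transform(self, regions: Iterable[GenomicInterval]) -> pd.DataFrame:
        """Annotate regions into the standard AnnotatedRegion table."""
        rows = []
        for r in regions:
            a = self.annotate(r)
            rows.append(
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "id": r.id,
                    "category": a.category,
                    "closest_gene": a.closest_gene,
                    "distance_to_tss": a.distance_to_tss,
                    "is_distnc": a.is_distnc,
                    "is_prom": a.is_prom,
                    "is_3putr": a.is_3putr,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "start",
                "end",
                "id",
                "category",
                "closest_gene",
                "distance_to_tss",
                "is_distnc",
                "is_prom",
                "is_3putr",
            ],
        )

    def fit_transform(self, genes, regions) -> pd.DataFrame:
        return self.fit(genes).transform(regions)


def classify_region(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    cfg: Optional[AnnotationConfig] = None,
) -> AnnotatedRegion:
    """One-shot wrapper around :class:`RegionAnnotator` for a single region."""
    cfg = cfg or AnnotationConfig()
    ann = RegionAnnotator(cfg.tss_upstream, cfg.tss_downstream).fit(genes)
    return ann.annotate(region)


def annotate_regions(
    regions: RegionSet,
    genes: Sequence[GeneModel],
    cfg: Optional[AnnotationConfig] = None,
) -> pd.DataFrame:
    cfg = cfg or AnnotationConfig()
    return RegionAnnotator(cfg.tss_upstream, cfg.tss_downstream).fit(genes).transform(
        regions
    )
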