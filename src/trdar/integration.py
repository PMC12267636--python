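"""Joining DARs to DEGs: transcriptionally relevant DARs and their
cross-condition directional overlaps.

A trDAR is a significant differentially accessible region whose closest gene
is a significant differentially expressed gene changing in the concordant
direction: regions that open with an upregulated closest gene, or regions
that close with a repressed closest gene.  Directional overlap asks whether,
say, regions opening under one condition are the same regions closing under
another ("x > y": open in x, closed in y), via a two-sided Fisher test
against the shared consensus-peak universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .enrichment import EnrichmentRecord, bh_fdr, fisher_two_sided
from .intervals import RegionSet

TRDAR_COLUMNS = [
    "id",
    "chrom",
    "start",
    "end",
    "category",
    "closest_gene",
    "acc_direction",
    "expr_direction",
    "contrast_id",
]

_CONCORDANT = {("open", "up"), ("closed", "down")}


@dataclass(frozen=True)
class DirectionalContrastPair:
    """A cross-condition comparison in the "x > y" / "x < y" notation."""

    contrast_x: str
    contrast_y: str
    relation: str  # x_gt_y: open in x, closed in y; x_lt_y: the reverse

    def __post_init__(self) -> None:
        if self.relation not in {"x_gt_y", "x_lt_y"}:
            raise ValueError("relation must be 'x_gt_y' or 'x_lt_y'")

    @property
    def directions(self) -> Tuple[str, str]:
        return ("open", "closed") if self.relation == "x_gt_y" else ("closed", "open")


def call_trdars(
    dars: pd.DataFrame,
    degs: pd.DataFrame,
    annot: pd.DataFrame,
    contrast_id: str = "contrast",
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Emit trDARs from DAR calls, DEG calls and region annotations.

    Parameters
    ----------
    dars, degs : DataFrame
        Differential tables (``feature_id, log2fc, p, fdr, direction``) over
        regions and genes; ``direction`` already encodes significance
        (``ns`` otherwise).  DAR directions are open/closed; DEG directions
        up/down (open/closed DEG labels are mapped to up/down).
    annot : DataFrame
        AnnotatedRegion table mapping every DAR id to its closest gene.

    Returns
    -------
    (trdars, diagnostics)
        trDAR table plus counts of regions excluded at each step, including
        DARs whose closest gene is absent from the DEG universe.
    """
    deg_map = degs.set_index("feature_id")["direction"].to_dict()
    relabel = {"open": "up", "closed": "down"}
    annot_idx = annot.set_index("id")
    missing = [i for i in dars["feature_id"] if i not in annot_idx.index]
    if missing:
        raise ValueError(f"DARs without annotation: {missing[:5]} ...")

    diagnostics = {
        "dars_total": len(dars),
        "dars_significant": 0,
        "gene_not_in_deg_universe": 0,
        "gene_not_significant": 0,
        "discordant": 0,
        "trdars": 0,
    }
    rows = []
    for rec in dars.itertuples(index=False):
        if rec.direction == "ns":
            continue
        diagnostics["dars_significant"] += 1
        a = annot_idx.loc[rec.feature_id]
        gene = a["closest_gene"]
        if gene is None or pd.isna(gene) or gene not in deg_map:
            diagnostics["gene_not_in_deg_universe"] += 1
            continue
        gdir = deg_map[gene]
        if gdir == "ns":
            diagnostics["gene_not_significant"] += 1
            continue
        gdir = relabel.get(gdir, gdir)
        if (rec.direction, gdir) not in _CONCORDANT:
            diagnostics["discordant"] += 1
            continue
        rows.append(
            {
                "id": rec.feature_id,
                "chrom": a["chrom"],
                "start": a["start"],
                "end": a["end"],
                "category": a["category"],
                "closest_gene": gene,
                "acc_direction": rec.direction,
                "expr_direction": gdir,
                "contrast_id": contrast_id,
            }
        )
    diagnostics["trdars"] = len(rows)
    trdars = pd.DataFrame(rows, columns=TRDAR_COLUMNS)
    return trdars, diagnostics


def proximal_gene_counts(trdars: pd.DataFrame) -> Dict[str, int]:
    """Unique closest genes per accessibility direction."""
    return {
        direction: int(grp["closest_gene"].nunique())
        for direction, grp in trdars.groupby("acc_direction")
    }


def _member_ids(
    trdars: pd.DataFrame,
    direction: str,
    universe: RegionSet,
) -> Set[str]:
    """Universe ids matched by trDARs of one direction.

    trDAR ids present in the universe match by identity (shared consensus
    peak set); any others fall back to >= 1 bp interval overlap.
    """
    sub = trdars[trdars["acc_direction"] == direction]
    out: Set[str] = set()
    for rec in sub.itertuples(index=False):
        if rec.id in universe:
            out.add(rec.id)
        else:
            out.update(universe.overlapping(rec.chrom, int(rec.start), int(rec.end)))
    return out


def directional_overlap(
    trdars_x: pd.DataFrame,
    trdars_y: pd.DataFrame,
    pair: DirectionalContrastPair,
    universe: RegionSet,
) -> EnrichmentRecord:
    """Two-sided Fisher test of a directional trDAR overlap.

    Builds the 2x2 table over the consensus universe: regions in both the
    x-set and the y-set, x only, y only, and the universe remainder, where
    the x/y sets respect the directional relation (``x_gt_y`` pairs "open in
    x" with "closed in y").
    """
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")
    dx, dy = pair.directions
    set_x = _member_ids(trdars_x, dx, universe)
    set_y = _member_ids(trdars_y, dy, universe)
    a = len(set_x & set_y)
    b = len(set_x - set_y)
    c = len(set_y - set_x)
    d = len(universe) - len(set_x | set_y)
    odds, p = fisher_two_sided(a, b, c, d)
    label = ">" if pair.relation == "x_gt_y" else "<"
    return EnrichmentRecord(
        set_label=f"{pair.contrast_x} {label} {pair.contrast_y}",
        target_label=f"{pair.contrast_y}",
        ov_da=a,
        ov_nda=c,
        tot_tgt=len(set_y),
        n_da=len(set_x),
        n_nda=len(universe) - len(set_x),
        odds_ratio=odds,
        p=p,
    )


def directional_overlap_matrix(
    trdars_by_contrast: Mapping[str, pd.DataFrame],
    pairs: Sequence[DirectionalContrastPair],
    universe: RegionSet,
    category: Optional[str] = None,
) -> pd.DataFrame:
    """All requested directional overlaps with BH FDR across the run.

    ``category`` restricts every trDAR table (and hence the tested sets) to
    one genomic category, e.g. distNC via ``category="distnc"`` or a literal
    category name.
    """

    def _restrict(df: pd.DataFrame) -> pd.DataFrame:
        if category is None:
            return df
        if category.lower() == "distnc":
            return df[df["category"].isin(["Intron", "Distal Intergenic"])]
        return df[df["category"] == category]

    rows = []
    for pair in pairs:
        rec = directional_overlap(
            _restrict(trdars_by_contrast[pair.contrast_x]),
            _restrict(trdars_by_contrast[pair.contrast_y]),
            pair,
            universe,
        )
        rows.append(
            {
                "contrast_x": pair.contrast_x,
                "contrast_y": pair.contrast_y,
                "relation": pair.relation,
                "category": category or "all",
                "ov_xy": rec.ov_da,
                "n_x": rec.n_da,
                "n_y": rec.tot_tgt,
                "odds_ratio": rec.odds_ratio,
                "p": rec.p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["p"])
    return df
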