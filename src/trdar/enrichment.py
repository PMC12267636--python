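"""Two-sided Fisher overlap machinery.

Covers chromatin-state enrichment with ``ov_da / ov_nda / tot_tgt``
bookkeeping and state aggregation, and gene-set enrichment against cell-type
expression signatures, age-regulated gene lists and GO-style term
collections.  All tests are two-sided Fisher exact tests against an explicit
background, BH-adjusted within each run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import RegionSet

ENRICHMENT_COLUMNS = [
    "set_label",
    "target_label",
    "ov_da",
    "ov_nda",
    "tot_tgt",
    "n_da",
    "n_nda",
    "odds_ratio",
    "p",
    "fdr",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One 2x2 overlap test: subset (DA) vs background (NDA) against a target."""

    set_label: str
    target_label: str
    ov_da: int
    ov_nda: int
    tot_tgt: int
    n_da: int
    n_nda: int
    odds_ratio: float
    p: float
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if self.ov_da > self.n_da or self.ov_nda > self.n_nda:
            raise ValueError("overlap counts exceed set sizes")


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities <= that of the observed
    table at fixed margins.  The odds ratio is the sample odds ratio
    ``(a d)/(b c)`` (``inf`` when only ``b c`` is zero).  A zero margin makes
    the table degenerate: p = 1 and the odds ratio is NaN.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalize(records: List[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=ENRICHMENT_COLUMNS)
    if len(df):
        df["fdr"] = bh_fdr(df["p"])
    return df


# ---------------------------------------------------------------------------
# chromatin-state enrichment
# ---------------------------------------------------------------------------


def state_enrichment(
    subset: RegionSet,
    background: RegionSet,
    states: pd.DataFrame,
    set_label: str = "subset",
) -> pd.DataFrame:
    """Per-state Fisher enrichment of ``subset`` vs ``background`` regions.

    ``states`` is a labelled interval table (columns chrom, start, end,
    state).  ``ov_da`` / ``ov_nda`` count subset / background regions with a
    >= 1 bp overlap with any interval of the state; a state track absent
    from a region's chromosome simply yields no overlap.  BH is applied
    across states.
    """
    records = []
    n_da, n_nda = len(subset), len(background)
    for state, grp in states.groupby("state", sort=True):
        track = RegionSet.from_frame(grp.assign(id=None))
        ov_da = sum(
            1 for r in subset if track.overlapping(r.chrom, r.start, r.end)
        )
        ov_nda = sum(
            1 for r in background if track.overlapping(r.chrom, r.start, r.end)
        )
        odds, p = fisher_two_sided(ov_da, n_da - ov_da, ov_nda, n_nda - ov_nda)
        records.append(
            EnrichmentRecord(
                set_label, str(state), ov_da, ov_nda, len(grp), n_da, n_nda, odds, p
            )
        )
    return _finalize(records)


def aggregate_states(
    records: pd.DataFrame, merge_map: Mapping[str, str]
) -> pd.DataFrame:
    """Merge chromatin states by summing ov_da, ov_nda and tot_tgt.

    States that share a merged label (e.g. the two Polycomb-repressed
    states) have their overlap counts and target totals summed; Fisher and
    BH are then recomputed on the merged tables.  All merged states must
    share the same subset/background sizes.
    """
    unknown = set(merge_map) - set(records["target_label"])
    if unknown:
        raise ValueError(f"merge_map references unknown states: {sorted(unknown)}")
    df = records.copy()
    df["merged"] = df["target_label"].map(lambda s: merge_map.get(s, s))
    out = []
    for label, grp in df.groupby("merged", sort=True):
        if grp["n_da"].nunique() > 1 or grp["n_nda"].nunique() > 1:
            raise ValueError("merged states must share subset/background sizes")
        n_da = int(grp["n_da"].iloc[0])
        n_nda = int(grp["n_nda"].iloc[0])
        ov_da = int(grp["ov_da"].sum())
        ov_nda = int(grp["ov_nda"].sum())
        # summed overlap counts can exceed the region count when a region
        # overlaps several of the merged states; cap at the set size as the
        # 2x2 table requires
        ov_da, ov_nda = min(ov_da, n_da), min(ov_nda, n_nda)
        odds, p = fisher_two_sided(ov_da, n_da - ov_da, ov_nda, n_nda - ov_nda)
        out.append(
            EnrichmentRecord(
                str(grp["set_label"].iloc[0]),
                str(label),
                ov_da,
                ov_nda,
                int(grp["tot_tgt"].sum()),
                n_da,
                n_nda,
                odds,
                p,
            )
        )
    return _finalize(out)


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------


@dataclass
class GeneSetConfig:
    """Rules for building gene sets from raw tables.

    ``signature_min_counts``: a gene enters a cell-type signature when its
    expression exceeds this (strictly more than 100 counts by default).
    ``age_deg_p`` / fold-change rule: age-regulated genes are those with
    p below the threshold and linear fold change above 1 (up) or below 1
    (down); genes at exactly the boundary are excluded.  Set
    ``fc_log_scale`` when the table reports log fold changes (boundary 0
    instead of 1).
    """

    signature_min_counts: float = 100
    age_deg_p: float = 0.05
    fc_log_scale: bool = False

    def __post_init__(self) -> None:
        if self.signature_min_counts <= 0 or self.age_deg_p <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def fc_boundary(self) -> float:
        return 0.0 if self.fc_log_scale else 1.0


def signature_sets(
    expr: pd.DataFrame, cfg: Optional[GeneSetConfig] = None
) -> Dict[str, Set[str]]:
    """Highly-expressed gene sets per cell type (genes x cell types input)."""
    cfg = cfg or GeneSetConfig()
    return {
        str(ct): set(expr.index[expr[ct] > cfg.signature_min_counts])
        for ct in expr.columns
    }


def age_deg_sets(
    table: pd.DataFrame, cfg: Optional[GeneSetConfig] = None, label: str = "age"
) -> Dict[str, Set[str]]:
    """Up/down age-regulated gene sets from a (gene, p, fold_change) table."""
    cfg = cfg or GeneSetConfig()
    sig = table[table["p"] < cfg.age_deg_p]
    b = cfg.fc_boundary
    return {
        f"{label}_up": set(sig.loc[sig["fold_change"] > b, "gene"]),
        f"{label}_down": set(sig.loc[sig["fold_change"] < b, "gene"]),
    }


def gene_set_overlap(
    query_genes: Set[str],
    target_sets: Mapping[str, Set[str]],
    universe: Set[str],
    set_label: str = "query",
) -> pd.DataFrame:
    """Fisher overlap of a query gene list against named target sets.

    Target sets are intersected with the universe first; background is
    ``universe \\ query``.  BH is applied across target sets.  An empty
    query yields p = 1 everywhere.
    """
    if not query_genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    query = set(query_genes)
    bg = universe - query
    records = []
    for name in sorted(target_sets):
        tgt = set(target_sets[name]) & universe
        ov_da = len(query & tgt)
        ov_nda = len(bg & tgt)
        odds, p = fisher_two_sided(
            ov_da, len(query) - ov_da, ov_nda, len(bg) - ov_nda
        )
        records.append(
            EnrichmentRecord(
                set_label, name, ov_da, ov_nda, len(tgt), len(query), len(bg), odds, p
            )
        )
    return _finalize(records)
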