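"""trDAR calling and directional cross-condition overlaps."""

import numpy as np
import pandas as pd
import pytest

from trdar.integration import (
    DirectionalContrastPair,
    call_trdars,
    directional_overlap,
    directional_overlap_matrix,
    proximal_gene_counts,
)
from trdar.intervals import GenomicInterval, RegionSet


def _annot(peaks):
    rows = []
    for i, (pid, gene, category) in enumerate(peaks):
        rows.append(
            {
                "chrom": "chr1",
                "start": i * 1000,
                "end": i * 1000 + 200,
                "id": pid,
                "category": category,
                "closest_gene": gene,
                "distance_to_tss": 0,
                "is_distnc": category in ("Intron", "Distal Intergenic"),
                "is_prom": category == "Promoter",
                "is_3putr": category == "3'UTR",
            }
        )
    return pd.DataFrame(rows)


def _diff(records):
    return pd.DataFrame(records, columns=["feature_id", "log2fc", "p", "fdr", "direction"])


def test_concordant_open_up_is_trdar():
    dars = _diff([("p1", 2.0, 0.001, 0.01, "open")])
    degs = _diff([("g1", 1.5, 0.01, 0.04, "up")])
    annot = _annot([("p1", "g1", "Distal Intergenic")])
    trdars, diag = call_trdars(dars, degs, annot)
    assert len(trdars) == 1
    assert trdars.iloc[0]["acc_direction"] == "open"
    assert trdars.iloc[0]["expr_direction"] == "up"
    assert diag["trdars"] == 1


def test_discordant_open_down_is_excluded():
    dars = _diff([("p1", 2.0, 0.001, 0.01, "open")])
    degs = _diff([("g1", -1.5, 0.01, 0.04, "down")])
    trdars, diag = call_trdars(dars, degs, _annot([("p1", "g1", "Intron")]))
    assert len(trdars) == 0
    assert diag["discordant"] == 1


def test_gene_missing_from_deg_universe_is_diagnosed():
    dars = _diff([("p1", 2.0, 0.001, 0.01, "open")])
    degs = _diff([("gOther", 1.0, 0.5, 0.9, "ns")])
    trdars, diag = call_trdars(dars, degs, _annot([("p1", "gMissing", "Intron")]))
    assert len(trdars) == 0
    assert diag["gene_not_in_deg_universe"] == 1


def test_planted_mixture_recovers_exactly_the_concordant_pairs():
    """40 concordant, 40 discordant, 40 DAR-only: only the 40 concordant
    pairs come back when every call is significant."""
    peaks, dars, degs = [], [], []
    for i in range(120):
        pid, gene = f"p{i:03d}", f"g{i:03d}"
        acc_dir = "open" if i % 2 == 0 else "closed"
        sign = 1 if acc_dir == "open" else -1
        peaks.append((pid, gene, "Distal Intergenic"))
        dars.append((pid, sign * 2.0, 1e-4, 1e-3, acc_dir))
        if i < 40:  # concordant
            expr = "up" if acc_dir == "open" else "down"
            degs.append((gene, sign * 1.0, 1e-4, 1e-3, expr))
        elif i < 80:  # discordant
            expr = "down" if acc_dir == "open" else "up"
            degs.append((gene, -sign * 1.0, 1e-4, 1e-3, expr))
        # else DAR-only: gene absent from DEG table
    trdars, diag = call_trdars(_diff(dars), _diff(degs), _annot(peaks))
    assert len(trdars) == 40
    assert set(trdars["id"]) == {f"p{i:03d}" for i in range(40)}
    assert diag["discordant"] == 40
    assert diag["gene_not_in_deg_universe"] == 40
    counts = proximal_gene_counts(trdars)
    assert counts["open"] == 20 and counts["closed"] == 20
    # trDAR count never exceeds the significant DARs
    assert diag["trdars"] <= diag["dars_significant"]


def _universe(n=100):
    return RegionSet(
        GenomicInterval("chr1", i * 1000, i * 1000 + 200, id=f"u{i:03d}")
        for i in range(n)
    )


def _trdar_table(ids, direction, universe, category="Distal Intergenic"):
    rows = []
    for i in ids:
        r = universe[i]
        rows.append(
            {
                "id": i,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "category": category,
                "closest_gene": "g",
                "acc_direction": direction,
                "expr_direction": "up" if direction == "open" else "down",
                "contrast_id": "c",
            }
        )
    return pd.DataFrame(rows)


def test_nested_sets_give_strong_overlap():
    universe = _universe(200)
    ids = universe.ids
    x = _trdar_table(ids[:20], "open", universe)
    y = _trdar_table(ids[:40], "closed", universe)
    rec = directional_overlap(
        x, y, DirectionalContrastPair("iis", "aging", "x_gt_y"), universe
    )
    assert rec.ov_da == 20
    assert rec.odds_ratio > 1
    assert rec.p < 0.05


def test_independent_sets_are_null():
    rng = np.random.default_rng(4)
    universe = _universe(400)
    ids = np.array(universe.ids)
    x = _trdar_table(rng.choice(ids, 100, replace=False), "open", universe)
    y = _trdar_table(rng.choice(ids, 100, replace=False), "closed", universe)
    rec = directional_overlap(
        x, y, DirectionalContrastPair("a", "b", "x_gt_y"), universe
    )
    assert rec.p > 0.01
    assert 0.3 < rec.odds_ratio < 3.0


def test_transpose_symmetry_swapping_contrasts():
    """Swapping x and y while flipping the relation leaves p unchanged."""
    rng = np.random.default_rng(11)
    universe = _universe(300)
    ids = np.array(universe.ids)
    open_ids = rng.choice(ids, 60, replace=False)
    closed_ids = rng.choice(ids, 80, replace=False)
    x = _trdar_table(open_ids, "open", universe)
    y = _trdar_table(closed_ids, "closed", universe)
    fwd = directional_overlap(
        x, y, DirectionalContrastPair("iis", "aging", "x_gt_y"), universe
    )
    rev = directional_overlap(
        y, x, DirectionalContrastPair("aging", "iis", "x_lt_y"), universe
    )
    assert fwd.p == pytest.approx(rev.p, rel=1e-12)
    assert fwd.ov_da == rev.ov_da


def test_empty_universe_rejected():
    x = pd.DataFrame(columns=["id", "chrom", "start", "end", "category",
                              "closest_gene", "acc_direction", "expr_direction",
                              "contrast_id"])
    with pytest.raises(ValueError):
        directional_overlap(
            x, x, DirectionalContrastPair("a", "b", "x_gt_y"), RegionSet([])
        )


def test_invalid_relation_rejected():
    with pytest.raises(ValueError):
        DirectionalContrastPair("a", "b", "sideways")


def test_category_restriction_partitions_trdars():
    universe = _universe(100)
    ids = universe.ids
    mixed = pd.concat(
        [
            _trdar_table(ids[:10], "open", universe, category="Distal Intergenic"),
            _trdar_table(ids[10:18], "open", universe, category="Promoter"),
            _trdar_table(ids[18:30], "open", universe, category="3'UTR"),
        ]
    )
    by_cat = {
        "distnc": 10,
        "Promoter": 8,
        "3'UTR": 12,
    }
    total = 0
    y = _trdar_table(ids[50:60], "closed", universe)
    for cat, expected in by_cat.items():
        tab = directional_overlap_matrix(
            {"x": mixed, "y": y},
            [DirectionalContrastPair("x", "y", "x_gt_y")],
            universe,
            category=cat,
        )
        assert tab["n_x"].iloc[0] == expected
        total += tab["n_x"].iloc[0]
    assert total == len(mixed)


def test_cross_universe_matching_by_overlap():
    """trDARs from a different peak set match universe regions by >= 1 bp."""
    universe = _universe(50)
    shifted = pd.DataFrame(
        [
            {
                "id": "foreign_1",
                "chrom": "chr1",
                "start": 50,  # overlaps u000 (0-200)
                "end": 250,
                "category": "Distal Intergenic",
                "closest_gene": "g",
                "acc_direction": "open",
                "expr_direction": "up",
                "contrast_id": "c",
            }
        ]
    )
    y = _trdar_table(["u000"], "closed", universe)
    rec = directional_overlap(
        shifted, y, DirectionalContrastPair("a", "b", "x_gt_y"), universe
    )
    assert rec.ov_da == 1
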