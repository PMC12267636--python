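"""Fisher machinery: exact p vs enumeration, BH step-up, state aggregation,
and gene-set construction rules."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from trdar.enrichment import (
    GeneSetConfig,
    age_deg_sets,
    aggregate_states,
    bh_fdr,
    fisher_two_sided,
    gene_set_overlap,
    signature_sets,
    state_enrichment,
)
from trdar.intervals import GenomicInterval, RegionSet


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration with exact integer arithmetic."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    pmf = {x: comb(c1, x) * comb(n - c1, r1 - x) for x in range(lo, hi + 1)}
    obs = pmf[a]
    # include tables at most as probable as observed (relative tolerance as
    # in standard implementations)
    total = sum(v for v in pmf.values() if v <= obs + obs * 1e-7)
    return total / denom


def test_fisher_mode_table_p_is_one():
    odds, p = fisher_two_sided(1, 9, 1, 9)
    assert p == pytest.approx(1.0)
    assert odds == pytest.approx(1.0)


def test_fisher_perfect_diagonal():
    odds, p = fisher_two_sided(5, 0, 0, 5)
    assert p == pytest.approx(2 / 252)  # both extreme tables of C(10,5)=252
    assert odds == np.inf


def test_fisher_zero_margin_degenerate():
    odds, p = fisher_two_sided(0, 0, 3, 7)
    assert p == 1.0
    assert np.isnan(odds)


def test_fisher_negative_counts_rejected():
    with pytest.raises(ValueError):
        fisher_two_sided(-1, 2, 3, 4)


def test_fisher_matches_enumeration_on_random_tables():
    rng = np.random.default_rng(31)
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        _, p = fisher_two_sided(a, b, c, d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------


def bh_oracle(p):
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        out[i] = prev
    return out


def test_bh_equal_spacing_collapses_to_common_value():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_single_value_unchanged():
    assert bh_fdr([0.2])[0] == pytest.approx(0.2)


def test_bh_empty():
    assert bh_fdr([]).size == 0


def test_bh_matches_stepup_oracle():
    rng = np.random.default_rng(0)
    p = rng.random(100)
    assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


def test_bh_preserves_p_ordering():
    rng = np.random.default_rng(1)
    p = rng.random(50)
    fdr = bh_fdr(p)
    order = np.argsort(p, kind="stable")
    assert (np.diff(fdr[order]) >= -1e-12).all()


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# state enrichment
# ---------------------------------------------------------------------------


def _grid_regions(n, chrom="chr1", width=100, gap=100, prefix="r"):
    return RegionSet(
        GenomicInterval(chrom, i * (width + gap), i * (width + gap) + width,
                        id=f"{prefix}{i:03d}")
        for i in range(n)
    )


def test_subset_inside_one_state_is_most_enriched():
    universe = _grid_regions(60)
    ids = universe.ids
    subset = universe.subset(ids[:20])
    background = universe.subset(ids[20:])
    # stateA covers exactly the subset's intervals; stateB covers the rest
    states = pd.DataFrame(
        [("chr1", universe[i].start, universe[i].end, "stateA") for i in ids[:20]]
        + [("chr1", universe[i].start, universe[i].end, "stateB") for i in ids[20:]],
        columns=["chrom", "start", "end", "state"],
    )
    table = state_enrichment(subset, background, states).set_index("target_label")
    assert table.loc["stateA", "ov_da"] == 20
    assert table.loc["stateA", "ov_nda"] == 0
    assert table.loc["stateA", "p"] == table["p"].min()
    assert table.loc["stateA", "odds_ratio"] == np.inf


def test_uniform_subset_gives_null_odds():
    rng = np.random.default_rng(5)
    universe = _grid_regions(200)
    pick = rng.choice(universe.ids, size=60, replace=False)
    subset = universe.subset(pick)
    background = universe.subset([i for i in universe.ids if i not in set(pick)])
    # one broad state covering a random half of the regions
    covered = rng.choice(universe.ids, size=100, replace=False)
    states = pd.DataFrame(
        [("chr1", universe[i].start, universe[i].end, "s") for i in covered],
        columns=["chrom", "start", "end", "state"],
    )
    table = state_enrichment(subset, background, states)
    assert 0.4 < table["odds_ratio"].iloc[0] < 2.5
    assert table["p"].iloc[0] > 0.05


def test_state_on_missing_chromosome_counts_as_no_overlap():
    universe = _grid_regions(10)
    subset = universe.subset(universe.ids[:5])
    background = universe.subset(universe.ids[5:])
    states = pd.DataFrame(
        [("chrM", 0, 1000, "mito")], columns=["chrom", "start", "end", "state"]
    )
    table = state_enrichment(subset, background, states)
    assert table["ov_da"].iloc[0] == 0
    assert table["p"].iloc[0] == 1.0


def test_aggregate_states_sums_counts_and_conserves_totals():
    records = pd.DataFrame(
        [
            ("s", "PC repressed 1", 5, 10, 100, 50, 200, 2.0, 0.2, 0.3),
            ("s", "PC repressed 2", 3, 10, 150, 50, 200, 1.2, 0.5, 0.5),
            ("s", "Enhancer", 9, 4, 80, 50, 200, 9.0, 0.001, 0.003),
        ],
        columns=["set_label", "target_label", "ov_da", "ov_nda", "tot_tgt",
                 "n_da", "n_nda", "odds_ratio", "p", "fdr"],
    )
    merged = aggregate_states(
        records, {"PC repressed 1": "PC repressed", "PC repressed 2": "PC repressed"}
    ).set_index("target_label")
    assert merged.loc["PC repressed", "ov_da"] == 8
    assert merged.loc["PC repressed", "ov_nda"] == 20
    assert merged.loc["PC repressed", "tot_tgt"] == 250
    # conservation of summed counts
    assert merged["ov_da"].sum() == records["ov_da"].sum()
    # Fisher recomputed on merged counts
    expected_odds, expected_p = fisher_two_sided(8, 42, 20, 180)
    assert merged.loc["PC repressed", "p"] == pytest.approx(expected_p)
    assert merged.loc["PC repressed", "odds_ratio"] == pytest.approx(expected_odds)


def test_aggregate_with_zero_state_is_unchanged():
    records = pd.DataFrame(
        [
            ("s", "A", 5, 10, 100, 50, 200, 2.0, 0.2, 0.2),
            ("s", "Z", 0, 0, 0, 50, 200, np.nan, 1.0, 1.0),
        ],
        columns=["set_label", "target_label", "ov_da", "ov_nda", "tot_tgt",
                 "n_da", "n_nda", "odds_ratio", "p", "fdr"],
    )
    merged = aggregate_states(records, {"Z": "A"}).set_index("target_label")
    assert merged.loc["A", "ov_da"] == 5
    assert merged.loc["A", "tot_tgt"] == 100


def test_aggregate_unknown_state_errors():
    records = pd.DataFrame(
        [("s", "A", 1, 1, 10, 5, 20, 1.0, 1.0, 1.0)],
        columns=["set_label", "target_label", "ov_da", "ov_nda", "tot_tgt",
                 "n_da", "n_nda", "odds_ratio", "p", "fdr"],
    )
    with pytest.raises(ValueError, match="unknown states"):
        aggregate_states(records, {"nope": "x"})


def test_aggregate_matches_direct_recount():
    """Merging must equal testing the union of the merged interval sets."""
    rng = np.random.default_rng(9)
    universe = _grid_regions(120)
    pick = rng.choice(universe.ids, size=40, replace=False)
    subset = universe.subset(pick)
    background = universe.subset([i for i in universe.ids if i not in set(pick)])
    rows = []
    for i in universe.ids:
        r = universe[i]
        if rng.random() < 0.3:
            rows.append(("chr1", r.start, r.end, f"part{int(rng.integers(0, 2)) + 1}"))
    states = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    per_state = state_enrichment(subset, background, states)
    merged = aggregate_states(
        per_state, {"part1": "whole", "part2": "whole"}
    ).set_index("target_label")
    direct = state_enrichment(
        subset, background, states.assign(state="whole")
    ).set_index("target_label")
    # counts agree because the parts are disjoint interval sets
    assert merged.loc["whole", "ov_da"] == direct.loc["whole", "ov_da"]
    assert merged.loc["whole", "ov_nda"] == direct.loc["whole", "ov_nda"]
    assert merged.loc["whole", "p"] == pytest.approx(direct.loc["whole", "p"])


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def test_signature_threshold_is_strict():
    expr = pd.DataFrame(
        {"neuronX": [100, 101, 99], "neuronY": [500, 0, 101]},
        index=["g1", "g2", "g3"],
    )
    sets = signature_sets(expr)
    assert sets["neuronX"] == {"g2"}  # exactly 100 is excluded
    assert sets["neuronY"] == {"g1", "g3"}


def test_age_deg_sets_fold_change_rule():
    table = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d", "e"],
            "p": [0.01, 0.01, 0.2, 0.04, 0.01],
            "fold_change": [2.0, 0.5, 3.0, 1.0, 1.5],
        }
    )
    sets = age_deg_sets(table, label="neurons")
    assert sets["neurons_up"] == {"a", "e"}
    assert sets["neurons_down"] == {"b"}  # p >= 0.05 and FC == 1 excluded


def test_query_equal_to_target_ranks_first():
    universe = {f"g{i}" for i in range(200)}
    query = {f"g{i}" for i in range(20)}
    targets = {
        "match": set(query),
        "half": {f"g{i}" for i in range(10, 30)},
        "other": {f"g{i}" for i in range(100, 120)},
    }
    table = gene_set_overlap(query, targets, universe).sort_values("p")
    assert table.iloc[0]["target_label"] == "match"
    assert table.iloc[0]["odds_ratio"] == np.inf


def test_empty_query_gives_p_one():
    universe = {f"g{i}" for i in range(50)}
    table = gene_set_overlap(set(), {"t": {"g1", "g2"}}, universe)
    assert (table["p"] == 1.0).all()


def test_query_outside_universe_rejected():
    with pytest.raises(ValueError):
        gene_set_overlap({"zz"}, {"t": {"g1"}}, {"g1", "g2"})


def test_gene_set_config_validation():
    with pytest.raises(ValueError):
        GeneSetConfig(signature_min_counts=0)
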