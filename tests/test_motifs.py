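"""PWM parsing, exact score-distribution thresholds, and strand-aware scanning."""

import numpy as np
import pytest

from trdar.motifs import (
    PWM,
    MotifScanner,
    chip_enrichment,
    exact_score_distribution,
    exact_score_threshold,
    motif_enrichment,
    read_homer_motifs,
    scan_sequence,
    write_homer_motifs,
    _discretized_log_odds,
)
from trdar.intervals import GenomicInterval, RegionSet

RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(RC[c] for c in reversed(seq))


def informative_pwm(consensus, info=0.9, name="m"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), (1 - info) / 3)
    for i, c in enumerate(consensus):
        m[i, idx[c]] = info
    return PWM(name=name, matrix=m)


# ---------------------------------------------------------------------------
# Homer I/O
# ---------------------------------------------------------------------------


def test_homer_header_and_length(tmp_path):
    path = tmp_path / "one.motif"
    path.write_text(
        ">TAAT\tlin39\t6.5\n"
        "0.05\t0.05\t0.05\t0.85\n"
        "0.85\t0.05\t0.05\t0.05\n"
        "0.85\t0.05\t0.05\t0.05\n"
        "0.05\t0.05\t0.05\t0.85\n"
    )
    motifs = read_homer_motifs(path)
    assert len(motifs) == 1
    assert motifs[0].name == "lin39"
    assert motifs[0].consensus == "TAAT"
    assert len(motifs[0]) == 4


def test_homer_malformed_header_reports_line(tmp_path):
    path = tmp_path / "bad.motif"
    path.write_text(">JUSTONEFIELD\n0.25\t0.25\t0.25\t0.25\n")
    with pytest.raises(ValueError, match=":1:"):
        read_homer_motifs(path)


def test_homer_row_not_summing_warns_and_renormalizes(tmp_path):
    path = tmp_path / "odd.motif"
    path.write_text(">AC\tm\t0\n0.5\t0.5\t0.5\t0.5\n0.25\t0.25\t0.25\t0.25\n")
    with pytest.warns(UserWarning, match="renormaliz"):
        motifs = read_homer_motifs(path)
    assert np.allclose(motifs[0].matrix.sum(axis=1), 1.0)


def test_homer_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    motifs = [
        PWM(name=f"m{i}", matrix=rng.dirichlet(np.ones(4), size=6)) for i in range(3)
    ]
    path = tmp_path / "rt.motif"
    write_homer_motifs(motifs, path)
    back = read_homer_motifs(path, pseudocount=0.0)
    for orig, rt in zip(motifs, back):
        assert rt.name == orig.name
        assert np.allclose(rt.matrix, orig.matrix, atol=1e-5)


def test_uniform_motif_has_zero_log_odds():
    pwm = PWM(name="u", matrix=np.full((4, 4), 0.25))
    assert np.allclose(pwm.log_odds, 0.0, atol=0.01)


# ---------------------------------------------------------------------------
# exact threshold
# ---------------------------------------------------------------------------


def test_uniform_pwm_degenerate_distribution():
    pwm = PWM(name="u", matrix=np.full((2, 4), 0.25), pseudocount=0.0)
    scores, probs = exact_score_distribution(pwm)
    assert scores.size == 1
    assert scores[0] == pytest.approx(0.0)
    assert probs[0] == pytest.approx(1.0)
    assert exact_score_threshold(pwm, alpha=0.3) == pytest.approx(0.0)


@pytest.mark.parametrize("L", [2, 4, 6, 8])
def test_dp_tail_matches_brute_force_enumeration(L):
    rng = np.random.default_rng(L)
    pwm = PWM(name="t", matrix=rng.dirichlet(np.ones(4) * 0.7, size=L))
    scores, probs = exact_score_distribution(pwm)
    q = _discretized_log_odds(pwm, 1e-3)
    grids = np.meshgrid(*[q[i] for i in range(L)], indexing="ij")
    all_scores = sum(grids).ravel() * 1e-3
    uniform_p = 0.25**L
    for thr in np.quantile(all_scores, [0.25, 0.5, 0.9, 0.99, 1.0]):
        dp_tail = probs[scores >= thr - 1e-12].sum()
        brute_tail = uniform_p * (all_scores >= thr - 1e-12).sum()
        assert dp_tail == pytest.approx(brute_tail, abs=1e-9)


def test_threshold_monotone_in_alpha():
    rng = np.random.default_rng(7)
    pwm = PWM(name="t", matrix=rng.dirichlet(np.ones(4) * 0.5, size=8))
    alphas = [0.2, 0.1, 0.05, 0.01, 1e-3, 1e-4]
    thresholds = [exact_score_threshold(pwm, alpha=a) for a in alphas]
    assert all(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:]))


def test_alpha_below_minimum_tail_returns_max_with_warning():
    pwm = informative_pwm("ACG")
    with pytest.warns(UserWarning, match="minimum attainable"):
        thr = exact_score_threshold(pwm, alpha=1e-6)
    scores, _ = exact_score_distribution(pwm)
    assert thr == pytest.approx(scores[-1])


def test_invalid_alpha_rejected():
    pwm = informative_pwm("ACGT")
    with pytest.raises(ValueError):
        exact_score_threshold(pwm, alpha=0.7)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def test_planted_consensus_found_at_offset():
    pwm = informative_pwm("ACGTAC")
    thr = exact_score_threshold(pwm, alpha=1e-3)
    seq = "T" * 10 + "ACGTAC" + "T" * 10
    hits = scan_sequence(seq, pwm, thr)
    forward = [h for h in hits if h[1] == "+"]
    assert len(forward) == 1
    assert forward[0][0] == 10


def test_all_n_sequence_has_no_hits():
    pwm = informative_pwm("ACGT")
    assert scan_sequence("N" * 50, pwm, threshold=-100.0) == []


def test_sequence_shorter_than_motif_yields_no_hits():
    pwm = informative_pwm("ACGTACGT")
    assert scan_sequence("ACG", pwm, threshold=-100.0) == []


def test_scanning_is_strand_symmetric():
    """Reverse-complementing every sequence leaves hit status unchanged."""
    rng = np.random.default_rng(13)
    pwm = informative_pwm("TGATTACA")
    scanner = MotifScanner(pwm, alpha=1e-3).fit()
    seqs = {}
    for i in range(60):
        s = "".join(rng.choice(list("ACGT"), size=80))
        if i % 3 == 0:
            s = s[:30] + "TGATTACA" + s[38:]
        seqs[f"r{i}"] = s
    hits_fwd = scanner.hit_regions(seqs)
    hits_rc = scanner.hit_regions({k: revcomp(v) for k, v in seqs.items()})
    assert hits_fwd == hits_rc


def test_hit_rate_matches_analytic_tail():
    """Across random sequences the per-region hit rate should follow the
    per-window tail probability within binomial error."""
    rng = np.random.default_rng(5)
    pwm = informative_pwm("ACGTAC", info=0.7)
    alpha = 5e-3
    scanner = MotifScanner(pwm, alpha=alpha).fit()
    scores, probs = exact_score_distribution(scanner._pwm)
    tail = probs[scores >= scanner.threshold_ - 1e-12].sum()
    n_seq, seq_len = 400, 60
    n_windows = 2 * (seq_len - len(pwm) + 1)
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT"), size=seq_len))
        for i in range(n_seq)
    }
    rate = len(scanner.hit_regions(seqs)) / n_seq
    expected = 1 - (1 - tail) ** n_windows  # windows ~ independent
    assert abs(rate - expected) < 4 * np.sqrt(expected * (1 - expected) / n_seq) + 0.01


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def test_planted_motif_enriched_over_null_background():
    rng = np.random.default_rng(23)
    pwm = informative_pwm("TTGACGTCAA", name="planted")
    targets, background = {}, {}
    for i in range(150):
        s = "".join(rng.choice(list("ACGT"), size=100))
        if rng.random() < 0.5:
            s = s[:40] + "TTGACGTCAA" + s[50:]
        targets[f"t{i}"] = s
    for i in range(600):
        background[f"b{i}"] = "".join(rng.choice(list("ACGT"), size=100))
    table = motif_enrichment(targets, background, [pwm])
    assert table["p"].iloc[0] < 1e-6
    assert table["odds_ratio"].iloc[0] > 5


def test_targets_sampled_from_background_are_null():
    rng = np.random.default_rng(29)
    pwm = informative_pwm("ACGTACGT", name="m")
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT"), size=100)) for i in range(400)
    }
    ids = list(seqs)
    pick = set(rng.choice(ids, size=100, replace=False))
    targets = {i: seqs[i] for i in pick}
    background = {i: seqs[i] for i in ids if i not in pick}
    table = motif_enrichment(targets, background, [pwm])
    assert table["p"].iloc[0] > 0.05


def test_empty_background_rejected():
    with pytest.raises(ValueError):
        motif_enrichment({"a": "ACGT"}, {}, [informative_pwm("ACGT")])


def test_chip_peaks_covering_targets_maximal_enrichment():
    targets = RegionSet(
        [GenomicInterval("chr1", i * 1000, i * 1000 + 200, id=f"t{i}") for i in range(10)]
    )
    background = RegionSet(
        [GenomicInterval("chr2", i * 1000, i * 1000 + 200, id=f"b{i}") for i in range(30)]
    )
    chip = RegionSet([GenomicInterval("chr1", 0, 10_000, id="peakset")])
    table = chip_enrichment(targets, background, {"TF": chip})
    assert table["ov_da"].iloc[0] == 10
    assert table["ov_nda"].iloc[0] == 0
    assert table["odds_ratio"].iloc[0] == np.inf
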