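"""Differential testing of accessibility / expression count matrices.

The differential caller is a from-scratch negative-binomial Wald test with a
single common dispersion shared by all features (tagwise dispersion is
deliberately not modelled).  Between-sample normalization uses trimmed mean
of M-values (TMM) effective size factors.  A rank-based Wilcoxon test is
provided for the per-cell-type single-cell comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .enrichment import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class DifferentialConfig:
    """Threshold and normalization choices for the differential caller."""

    fdr_threshold: float = 0.05
    normalization: str = "tmm"  # or "library-size"
    dispersion_mode: str = "common"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.normalization not in {"tmm", "library-size"}:
            raise ValueError("normalization must be 'tmm' or 'library-size'")
        if self.dispersion_mode != "common":
            raise ValueError("only common dispersion is supported")


class CountMatrix:
    """Integer counts, features x samples, with a condition label per sample."""

    def __init__(self, counts: pd.DataFrame, sample_groups: Mapping[str, str]):
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        missing = set(counts.columns) - set(sample_groups)
        if missing:
            raise ValueError(f"samples without a group assignment: {sorted(missing)}")
        self.counts = counts.astype(np.int64)
        self.sample_groups = dict(sample_groups)

    @property
    def feature_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> List[str]:
        return [s for s in self.sample_ids if self.sample_groups[s] == group]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Effective size factors: library size x TMM composition factor.

    The reference sample is the one whose upper quartile of count
    proportions is closest to the mean upper quartile.  Per sample, M-values
    (log2 proportion ratios vs the reference) are double-trimmed (``trim_m``
    per tail of M, ``trim_a`` per tail of A) over features non-zero in both
    samples, and combined by a precision-weighted mean.  Factors are rescaled
    so that they multiply to 1; normalized counts are ``counts / factor``.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"sample {counts.columns[zero[0]]!r} has all-zero counts"
        )
    P = X / lib
    uq = np.quantile(P, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    def _tmm(s: int) -> float:
        if s == ref:
            return 1.0
        keep = (X[:, s] > 0) & (X[:, ref] > 0)
        if keep.sum() == 0:
            return 1.0
        ps, pr = P[keep, s], P[keep, ref]
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        # asymptotic inverse variance of M (delta method, binomial sampling)
        w = (lib[s] - X[keep, s]) / (lib[s] * X[keep, s]) + (
            lib[ref] - X[keep, ref]
        ) / (lib[ref] * X[keep, ref])
        w = np.maximum(w, 1e-10)  # a feature holding a whole library
        n = M.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep2.sum() == 0 or not np.isfinite(w[keep2]).all():
            return 1.0
        f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
        return float(2.0**f)

    comp = np.array([_tmm(s) for s in range(X.shape[1])])
    factors = lib * comp
    factors = factors / np.exp(np.mean(np.log(factors)))  # multiply to 1
    return pd.Series(factors, index=counts.columns, name="factor")


class TMMNormalizer(BaseEstimator):
    """TMM effective-size-factor normalization as a transformer."""

    def __init__(self, trim_m: float = 0.30, trim_a: float = 0.05):
        self.trim_m = trim_m
        self.trim_a = trim_a

    def fit(self, counts: pd.DataFrame, y=None) -> "TMMNormalizer":
        self.factors_ = tmm_factors(counts, self.trim_m, self.trim_a)
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return counts / self.factors_

    def fit_transform(self, counts: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(counts).transform(counts)


# ---------------------------------------------------------------------------
# common-dispersion NB Wald test
# ---------------------------------------------------------------------------

_PSEUDO = 0.5  # added to group means before taking log ratios


def _common_dispersion(Z: np.ndarray, groups: List[np.ndarray]) -> float:
    """Method-of-moments common dispersion across features.

    Per feature, the pooled within-group variance ``s2`` (median-unbiased via
    the chi-square median correction for its degrees of freedom) and pooled
    mean ``mu`` give ``phi_f = max(0, (s2 - mu) / mu^2)``; the common value
    is the median over features.
    """
    n_total = sum(g.size for g in groups)
    df = n_total - len(groups)
    if df <= 0:
        raise ValueError("need >= 2 samples per group to estimate dispersion")
    ss = np.zeros(Z.shape[0])
    for idx in groups:
        sub = Z[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df * (df / stats.chi2.median(df))
    mu = Z.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.maximum(0.0, (s2 - mu) / mu**2)
    phi = phi[np.isfinite(phi)]
    return float(np.median(phi)) if phi.size else 0.0


class NBDifferentialTest(BaseEstimator):
    """Two-group differential test for count features (DARs / DEGs).

    Counts are TMM-normalized, a single common NB dispersion is estimated by
    the method of moments, and each feature gets a two-sided Wald test on its
    log2 fold change with a delta-method standard error under
    ``Var(X) = mu + phi mu^2``.  BH FDR is applied over all tested features;
    features with zero counts everywhere are excluded and logged.

    Attributes
    ----------
    results_ : DataFrame
        Columns ``feature_id, log2fc, p, fdr, direction`` where direction is
        ``open/up``-style sign at ``fdr <= fdr_threshold`` else ``ns``.
    dispersion_ : float
    factors_ : Series
    skipped_ : list of feature ids excluded for zero total count.
    """

    def __init__(
        self,
        fdr_threshold: float = 0.05,
        normalization: str = "tmm",
        direction_labels: Tuple[str, str] = ("open", "closed"),
    ):
        self.fdr_threshold = fdr_threshold
        self.normalization = normalization
        self.direction_labels = direction_labels

    def fit(self, m: CountMatrix, group_a: str, group_b: str) -> "NBDifferentialTest":
        DifferentialConfig(self.fdr_threshold, self.normalization)
        sa, sb = m.samples_in(group_a), m.samples_in(group_b)
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError(
                f"need >= 2 samples per group, got {len(sa)} vs {len(sb)}"
            )
        counts = m.counts[sa + sb]
        nonzero = counts.sum(axis=1) > 0
        self.skipped_ = list(counts.index[~nonzero])
        if self.skipped_:
            logger.info("excluding %d all-zero features", len(self.skipped_))
        counts = counts.loc[nonzero]
        if self.normalization == "tmm":
            self.factors_ = tmm_factors(counts)
        else:
            lib = counts.sum(axis=0).astype(float)
            f = lib / np.exp(np.mean(np.log(lib)))
            self.factors_ = pd.Series(f, index=counts.columns, name="factor")
        Z = counts.to_numpy(dtype=float) / self.factors_.to_numpy()
        ia = np.arange(len(sa))
        ib = np.arange(len(sa), len(sa) + len(sb))
        self.dispersion_ = _common_dispersion(Z, [ia, ib])

        mu_a = Z[:, ia].mean(axis=1)
        mu_b = Z[:, ib].mean(axis=1)
        log2fc = np.log2(mu_b + _PSEUDO) - np.log2(mu_a + _PSEUDO)
        phi = self.dispersion_
        var_log = (1.0 / (mu_a + _PSEUDO) + phi) / len(sa) + (
            1.0 / (mu_b + _PSEUDO) + phi
        ) / len(sb)
        se = np.sqrt(var_log) / np.log(2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, log2fc / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        fdr = bh_fdr(p)
        up, down = self.direction_labels
        direction = np.where(
            fdr <= self.fdr_threshold,
            np.where(log2fc > 0, up, down),
            "ns",
        )
        direction = np.where((fdr <= self.fdr_threshold) & (log2fc == 0), "ns", direction)
        self.results_ = pd.DataFrame(
            {
                "feature_id": counts.index,
                "log2fc": log2fc,
                "p": p,
                "fdr": fdr,
                "direction": direction,
            }
        ).reset_index(drop=True)
        return self

    def significant(self) -> pd.DataFrame:
        return self.results_[self.results_["direction"] != "ns"].reset_index(drop=True)


def nb_test(
    m: CountMatrix,
    group_a: str,
    group_b: str,
    cfg: Optional[DifferentialConfig] = None,
    direction_labels: Tuple[str, str] = ("open", "closed"),
) -> pd.DataFrame:
    """Functional wrapper over :class:`NBDifferentialTest`; returns results_."""
    cfg = cfg or DifferentialConfig()
    est = NBDifferentialTest(
        fdr_threshold=cfg.fdr_threshold,
        normalization=cfg.normalization,
        direction_labels=direction_labels,
    )
    return est.fit(m, group_a, group_b).results_


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (single-cell per-cell-type comparison)
# ---------------------------------------------------------------------------


def wilcoxon_de(
    expr_a: Sequence[float], expr_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test for two per-cell expression vectors.

    Returns the rank-sum statistic of the first sample (midrank ties) and the
    two-sided p: exact enumeration for n1+n2 <= 25 without ties, otherwise
    the normal approximation with tie correction.  Complete ties give p = 1.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    if np.unique(pooled).size == 1:
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    n = a.size + b.size
    if n <= 25 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return w, float(min(1.0, res.pvalue))


def wilcoxon_de_table(
    expr: pd.DataFrame, cells_a: Sequence[str], cells_b: Sequence[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene-wise Wilcoxon DE with BH adjustment (genes x cells input)."""
    stats_p = [
        wilcoxon_de(expr.loc[g, list(cells_a)], expr.loc[g, list(cells_b)])
        for g in expr.index
    ]
    p = np.array([x[1] for x in stats_p])
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "feature_id": expr.index,
            "statistic": [x[0] for x in stats_p],
            "p": p,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
        }
    ).reset_index(drop=True)
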