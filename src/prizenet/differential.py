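"""Differential filtering, normalization, site collapsing and cluster counting.

This module houses the statistical rules applied before network integration:
Benjamini-Hochberg FDR adjustment, total-signal normalization of TMT channel
intensities, two-sample tests for simulated replicates, the fold-change /
FDR retention filter, reduction of ubiquitin sites to one record per protein,
and per-gene counting of differentially expressed single-cell clusters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ParameterError
from .omics_io import ClusterDEMatrix, Layer, OmicsMeasurement

#: p-value reported when group means differ but there is no residual variance
#: (a noiseless simulation); keeps p inside (0, 1].
_MIN_P = 1e-300


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} min(1, p_(j) * n / j) over the sorted sequence;
    the output is monotone in the input and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("bh_adjust requires at least one p-value")
    if np.any(~((p > 0.0) & (p <= 1.0))):
        raise ParameterError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def normalize_total_signal(intensity_table: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-channel totals (total-TMT-signal normalization).

    Each value is divided by its channel total and multiplied by the mean
    channel total, so all channel sums agree afterwards.
    """
    totals = intensity_table.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise FormatError(
            f"channel '{zero.index[0]}' has zero total signal"
        )
    return intensity_table / totals * totals.mean()


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value; degenerate zero-variance cases handled."""
    a = np.asarray(group_a, float)[None, :]
    b = np.asarray(group_b, float)[None, :]
    return float(welch_t_test_matrix(a, b)[0])


def welch_t_test_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test along the last axis.

    Rows with zero pooled variance return p = 1 when the means agree and a
    representable minimum p when they differ (the noiseless simulation case).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise ParameterError("each group needs at least two replicates")
    na, nb = a.shape[-1], b.shape[-1]
    ma, mb = a.mean(-1), b.mean(-1)
    va, vb = a.var(-1, ddof=1), b.var(-1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0.0
    p = np.where(zero_se & (ma == mb), 1.0, p)
    p = np.where(zero_se & (ma != mb), _MIN_P, p)
    return np.clip(p, _MIN_P, 1.0)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    from scipy.special import polygamma

    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-feature variances (limma-style).

    Fits a scaled inverse-chi-square prior to the observed variances via the
    moments of log s^2 and returns the posterior variances together with the
    prior degrees of freedom (inf when the variances are homogeneous, in which
    case every variance collapses to the common value).
    """
    from scipy.special import polygamma, psi

    ok = s2 > 0
    if not ok.any():
        return s2.copy(), 0.0
    e = np.log(s2[ok]) - float(psi(df / 2.0)) + math.log(df / 2.0)
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    resid = e_var - float(polygamma(1, df / 2.0))
    if resid <= 0.0 or e.size < 2:
        d0 = math.inf
        s0_2 = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0_2 = float(
            np.exp(e.mean() + psi(d0 / 2.0) - math.log(d0 / 2.0))
        )
    if math.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def moderated_t_test_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized moderated (empirical-Bayes) two-sample t-test, last axis.

    Per-feature pooled variances are shrunk toward a common prior fitted
    across all features; the t statistic uses the posterior variance with
    ``df + prior df`` degrees of freedom.  This is the standard
    small-replicate test for omics differential expression: with only a few
    replicates per group the per-feature variance estimate is too unstable
    for BH-adjusted significance, while information sharing across thousands
    of features restores power at controlled FDR.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise ParameterError("each group needs at least two replicates")
    na, nb = a.shape[-1], b.shape[-1]
    df = na + nb - 2.0
    ma, mb = a.mean(-1), b.mean(-1)
    s2 = ((na - 1) * a.var(-1, ddof=1) + (nb - 1) * b.var(-1, ddof=1)) / df
    s2_post, d0 = _squeeze_variances(np.atleast_1d(s2).ravel(), df)
    s2_post = s2_post.reshape(np.shape(ma))
    se2 = s2_post * (1.0 / na + 1.0 / nb)
    total_df = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        if math.isinf(total_df):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), total_df)
    zero_se = se2 == 0.0
    p = np.where(zero_se & (ma == mb), 1.0, p)
    p = np.where(zero_se & (ma != mb), _MIN_P, p)
    return np.clip(p, _MIN_P, 1.0)


def cluster_de_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "auto",
) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midranks for ties.

    ``method="auto"`` is exact by enumeration of all labelings when both
    groups have at most 8 observations and otherwise a normal approximation
    with tie correction and a 0.5 continuity correction; ``"exact"`` and
    ``"approx"`` force one route.
    """
    if method not in ("auto", "exact", "approx"):
        raise ParameterError(f"unknown method {method!r}")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least two observations")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, na = pooled.size, a.size
    w = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    dev = abs(w - mu)
    exact = method == "exact" or (
        method == "auto" and a.size <= 8 and b.size <= 8
    )
    if exact:
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n), na):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-12:
                extreme += 1
        return extreme / total
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1.0))
    var = a.size * b.size / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0.0:
        return 1.0
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    return float(np.clip(2.0 * stats.norm.sf(z), _MIN_P, 1.0))


Direction = Literal["up", "down"]


@dataclass(frozen=True)
class DifferentialSummary:
    """Outcome of the fold-change / FDR retention filter over one table."""

    measurements: tuple[OmicsMeasurement, ...]
    retained_flags: tuple[bool, ...]
    directions: tuple[Direction, ...]
    fold_threshold: float
    alpha: float

    @property
    def retained(self) -> list[OmicsMeasurement]:
        return [
            m for m, keep in zip(self.measurements, self.retained_flags) if keep
        ]

    @property
    def n_up(self) -> int:
        return sum(
            1
            for keep, d in zip(self.retained_flags, self.directions)
            if keep and d == "up"
        )

    @property
    def n_down(self) -> int:
        return sum(
            1
            for keep, d in zip(self.retained_flags, self.directions)
            if keep and d == "down"
        )


def filter_de(
    measurements: Sequence[OmicsMeasurement],
    fold_threshold: float,
    alpha: float,
) -> DifferentialSummary:
    """Retain features with |log2FC| >= log2(fold_threshold) and adj-p < alpha.

    The fold threshold applies symmetrically to both directions (a 1.25-fold
    increase and a 1/1.25-fold decrease are equally extreme); the significance
    boundary is strict.
    """
    if fold_threshold < 1.0:
        raise ParameterError("fold_threshold must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must lie in (0, 1)")
    log_thr = math.log2(fold_threshold)
    flags, dirs = [], []
    for m in measurements:
        flags.append(
            abs(m.log2_fold_change) >= log_thr and m.p_adjusted < alpha
        )
        dirs.append("up" if m.log2_fold_change >= 0 else "down")
    return DifferentialSummary(
        tuple(measurements), tuple(flags), tuple(dirs), fold_threshold, alpha
    )


def collapse_sites(
    site_measurements: Sequence[OmicsMeasurement],
) -> list[OmicsMeasurement]:
    """Collapse ubiquitin-site records to one protein-level record each.

    Each protein carries the statistics of its most significant site: minimum
    adjusted p, ties broken by larger |log2FC|, then lexicographic site id.
    Output is sorted by protein id; its length equals the number of distinct
    parent proteins.
    """
    by_protein: dict[str, list[OmicsMeasurement]] = {}
    for m in site_measurements:
        if m.layer is not Layer.UBIQUITIN_SITE or not m.parent_protein:
            raise FormatError(
                f"{m.feature_id}: collapse_sites needs ubiquitin_site records "
                "with parent_protein"
            )
        by_protein.setdefault(m.parent_protein, []).append(m)
    collapsed = []
    for protein in sorted(by_protein):
        best = min(
            by_protein[protein],
            key=lambda m: (
                m.p_adjusted,
                -abs(m.log2_fold_change),
                m.feature_id,
            ),
        )
        collapsed.append(
            OmicsMeasurement(
                feature_id=protein,
                layer=Layer.PROTEIN,
                log2_fold_change=best.log2_fold_change,
                p_raw=best.p_raw,
                p_adjusted=best.p_adjusted,
            )
        )
    return collapsed


@dataclass(frozen=True)
class ClusterCounts:
    """Per-gene counts of single-cell clusters with differential expression.

    ``mean_clusters`` is the cohort average of n_total over genes with at
    least one DE cluster (0.0 when no gene has any), the denominator of the
    prize and edge-cost scRNA multipliers.
    """

    table: pd.DataFrame  # index gene; columns n_up, n_down, n_total
    mean_clusters: float
    ranked_genes: tuple[str, ...]
    top_genes: tuple[str, ...]
    list_threshold: int = 10
    _lookup: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_lookup", self.table["n_total"].to_dict()
        )

    def n_total(self, gene: str) -> int:
        return int(self._lookup.get(gene, 0))

    def __contains__(self, gene: str) -> bool:
        return gene in self._lookup


def count_clusters_per_gene(
    matrix: ClusterDEMatrix,
    fold_threshold: float,
    alpha: float,
    list_threshold: int = 10,
) -> ClusterCounts:
    """Count, per gene, the clusters whose cell passes the retention filter.

    Also returns genes ranked by total count (descending, ties lexicographic)
    and the sub-list with more than ``list_threshold`` DE clusters.
    """
    if fold_threshold < 1.0:
        raise ParameterError("fold_threshold must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must lie in (0, 1)")
    log_thr = math.log2(fold_threshold)
    fc = matrix.log2fc.to_numpy(float)
    padj = matrix.padj.to_numpy(float)
    with np.errstate(invalid="ignore"):
        passing = (np.abs(fc) >= log_thr) & (padj < alpha)
        n_up = (passing & (fc > 0)).sum(axis=1)
        n_down = (passing & (fc < 0)).sum(axis=1)
    table = pd.DataFrame(
        {"n_up": n_up, "n_down": n_down, "n_total": n_up + n_down},
        index=matrix.log2fc.index,
    )
    nonzero = table["n_total"][table["n_total"] >= 1]
    mean_clusters = float(nonzero.mean()) if len(nonzero) else 0.0
    ranked = tuple(
        table.sort_index().sort_values(
            "n_total", ascending=False, kind="mergesort"
        ).index
    )
    top = tuple(g for g in ranked if table.at[g, "n_total"] > list_threshold)
    return ClusterCounts(table, mean_clusters, ranked, top, list_threshold)
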