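"""Nonparametric comparison machinery for smoothness records.

Smoothness values from gait signals are not normally distributed, so all
group comparisons are rank-based: the Kruskal–Wallis H test (tie-corrected,
chi-square approximation) with Dunn's z test and Bonferroni adjustment as
the post-hoc, and standard-deviation ranking for the metric-reliability
question. Three report builders mirror the study questions: complete
signal vs. per-stride values, per-cell SD ranking of the three metrics,
and sensor-location comparison on one metric.

Observations default to per-trial means (one value per trial per cell);
per-stride pooling is available where a finer unit is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InputError, ParameterError

__all__ = [
    "GroupedValues",
    "KWResult",
    "PairwiseResult",
    "kruskal_wallis",
    "posthoc_pairwise",
    "compare_complete_vs_stride",
    "variance_ranking",
    "compare_locations",
]

#: minimum pooled n for the chi-square approximation to be trustworthy
MIN_ASYMPTOTIC_N = 5


@dataclass
class GroupedValues:
    """Named groups of real observations for one factor."""

    factor: str
    groups: dict[str, np.ndarray]

    def __post_init__(self):
        self.groups = {k: np.asarray(v, float).ravel() for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise InputError("need at least 2 groups")
        for name, vals in self.groups.items():
            if len(vals) == 0:
                raise InputError(f"group {name!r} is empty")
            if not np.all(np.isfinite(vals)):
                raise InputError(f"group {name!r} contains non-finite values")

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())

    @property
    def small_sample(self) -> bool:
        return self.n_total < MIN_ASYMPTOTIC_N


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    tie_corrected: bool
    n_total: int
    small_sample: bool = False


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float     # Dunn z (or Mann-Whitney U)
    p_raw: float
    p_adjusted: float    # Bonferroni: min(1, p_raw × m)
    significant: bool
    mean_rank_diff: float = float("nan")


def kruskal_wallis(g: GroupedValues) -> KWResult:
    """Kruskal–Wallis H with tie correction; p from chi-square (k−1 df).

    Degenerate all-identical data give H = 0, p = 1 by convention.
    """
    values = list(g.groups.values())
    pooled = np.concatenate(values)
    df = len(values) - 1
    ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, df, 1.0, ties, g.n_total, g.small_sample)
    H, p = sstats.kruskal(*values)
    return KWResult(float(H), df, float(p), ties, g.n_total, g.small_sample)


def _dunn_pairs(g: GroupedValues, alpha: float) -> list[PairwiseResult]:
    names = list(g.groups)
    values = [g.groups[k] for k in names]
    pooled = np.concatenate(values)
    N = len(pooled)
    ranks = sstats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, vals in zip(names, values):
        mean_ranks[name] = ranks[start:start + len(vals)].mean()
        start += len(vals)
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = len(g.groups[a]), len(g.groups[b])
            se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
            diff = mean_ranks[a] - mean_ranks[b]
            z = diff / se if se > 0 else 0.0
            p = 2.0 * sstats.norm.sf(abs(z))
            p_adj = min(1.0, p * m)
            out.append(PairwiseResult(a, b, float(z), float(p), float(p_adj),
                                      p_adj < alpha, float(diff)))
    return out


def _mannwhitney_pairs(g: GroupedValues, alpha: float) -> list[PairwiseResult]:
    names = list(g.groups)
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            try:
                U, p = sstats.mannwhitneyu(g.groups[a], g.groups[b],
                                           alternative="two-sided")
            except ValueError:      # all values identical
                U, p = 0.0, 1.0
            p_adj = min(1.0, float(p) * m)
            out.append(PairwiseResult(a, b, float(U), float(p), p_adj, p_adj < alpha))
    return out


def posthoc_pairwise(g: GroupedValues, alpha: float = 0.05,
                     method: str = "dunn") -> list[PairwiseResult]:
    """Bonferroni-adjusted pairwise comparisons following a Kruskal–Wallis test.

    Dunn's rank-based z test (default) is the standard follow-up; pairwise
    Mann–Whitney is available via ``method="mannwhitney"``. With two groups
    this reduces to a single unadjusted comparison.
    """
    if method == "dunn":
        return _dunn_pairs(g, alpha)
    if method == "mannwhitney":
        return _mannwhitney_pairs(g, alpha)
    raise ParameterError(f"unknown post-hoc method {method!r}")


def _pool(df: pd.DataFrame, pooling: str) -> pd.DataFrame:
    """Reduce records to the observation unit entering the tests."""
    if pooling == "trial_mean":
        return (df.groupby(["subject", "trial", "metric", "segment",
                            "component", "scope"], as_index=False)["value"].mean())
    if pooling == "stride":
        return df.copy()
    raise ParameterError(f"unknown pooling {pooling!r}")


def compare_complete_vs_stride(records: pd.DataFrame, alpha: float = 0.05,
                               component: str = "magnitude",
                               pooling: str = "trial_mean") -> pd.DataFrame:
    """Complete-signal vs. per-stride smoothness, per metric per segment.

    For each (metric × segment) cell, group A holds the complete-scope
    values and group B the stride-scope values (per-trial means by
    default); the cell reports the Kruskal–Wallis H, p, the A−B mean-rank
    difference and a significance flag at ``alpha``. Cells missing a scope
    are reported as not computable (NaN statistics).
    """
    df = records[records["component"] == component]
    pooled = _pool(df, pooling)
    rows = []
    for (metric, segment), cell in pooled.groupby(["metric", "segment"]):
        a = cell.loc[cell["scope"] == "complete", "value"].to_numpy()
        b = cell.loc[cell["scope"] == "stride", "value"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            rows.append(dict(metric=metric, segment=segment, n_complete=len(a),
                             n_stride=len(b), H=np.nan, p=np.nan,
                             mean_rank_diff=np.nan, significant=False,
                             computable=False))
            continue
        g = GroupedValues("scope", {"complete": a, "stride": b})
        res = kruskal_wallis(g)
        pair = posthoc_pairwise(g, alpha)[0]
        rows.append(dict(metric=metric, segment=segment, n_complete=len(a),
                         n_stride=len(b), H=res.H, p=res.p,
                         mean_rank_diff=pair.mean_rank_diff,
                         significant=res.p < alpha, computable=True))
    return pd.DataFrame(rows)


@dataclass
class VarianceRanking:
    table: pd.DataFrame          # per-cell SD with within-cell metric rank
    winner: str                  # metric with rank 1 in the most cells
    wins: dict[str, int] = field(default_factory=dict)


def variance_ranking(records: pd.DataFrame, min_per_cell: int = 2) -> VarianceRanking:
    """Rank metrics by standard deviation per (segment × component × scope) cell.

    The most reliable metric is the one with the lowest SD in the most
    cells. Cells with fewer than ``min_per_cell`` observations are skipped.
    """
    grouped = (records.groupby(["metric", "segment", "component", "scope"])["value"]
               .agg(sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                    n="count").reset_index())
    grouped = grouped[grouped["n"] >= min_per_cell].dropna(subset=["sd"])
    if grouped.empty:
        raise InputError("no cell has enough observations for an SD ranking")
    grouped["rank"] = grouped.groupby(["segment", "component", "scope"])["sd"] \
        .rank(method="min")
    wins = (grouped[grouped["rank"] == 1].groupby("metric").size()
            .sort_values(ascending=False).to_dict())
    winner = next(iter(wins))
    return VarianceRanking(grouped, winner, wins)


def compare_locations(records: pd.DataFrame, metric: str = "SPARC",
                      scope: str = "stride", alpha: float = 0.05,
                      pooling: str = "trial_mean",
                      posthoc_method: str = "dunn") -> pd.DataFrame:
    """Compare sensor segments (foot/shank/thigh/hip) per signal component.

    Restricted to one metric (SPARC by default, the lowest-variance one).
    For each component, a Kruskal–Wallis test across segments is followed
    by Bonferroni-adjusted pairwise comparisons; the output has one row
    per component for the omnibus test (pair blank) and one per pair.
    """
    df = records[(records["metric"] == metric) & (records["scope"] == scope)]
    if df.empty:
        raise InputError(f"no records for metric={metric!r}, scope={scope!r}")
    pooled = _pool(df, pooling)
    rows = []
    for component, cell in pooled.groupby("component"):
        groups = {seg: sub["value"].to_numpy()
                  for seg, sub in cell.groupby("segment")}
        if len(groups) < 2:
            raise InputError(f"component {component!r}: need >= 2 sensor locations")
        g = GroupedValues("segment", groups)
        omnibus = kruskal_wallis(g)
        rows.append(dict(component=component, pair="", statistic=omnibus.H,
                         p=omnibus.p, p_adjusted=omnibus.p,
                         significant=omnibus.p < alpha))
        if len(groups) >= 3:
            for pr in posthoc_pairwise(g, alpha, posthoc_method):
                rows.append(dict(component=component,
                                 pair=f"{pr.group_a}-{pr.group_b}",
                                 statistic=pr.statistic, p=pr.p_raw,
                                 p_adjusted=pr.p_adjusted,
                                 significant=pr.significant))
    return pd.DataFrame(rows)
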