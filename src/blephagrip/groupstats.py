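"""Group comparisons of attachment performance.

Two pipelines mirror common practice for positive, right-skewed force data:

* :func:`kruskal_dunn` — Kruskal-Wallis rank-sum omnibus test with midrank tie
  correction, followed by Dunn's pairwise z tests adjusted by the
  Bonferroni-Holm step-down procedure (rank-based, so indifferent to log
  transformation);
* :func:`anova_tukey_log` — one-way ANOVA on log10-transformed values with
  Tukey HSD pairwise comparisons.

Effect sizes are reported as fold changes of back-transformed means, i.e.
ratios of geometric means (:func:`fold_change_backtransformed`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairwiseResult",
    "GroupComparison",
    "kruskal_dunn",
    "anova_tukey_log",
    "fold_change_backtransformed",
    "geometric_mean",
]


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus test plus adjusted pairwise comparisons and fold changes."""

    method: str
    groups: dict
    omnibus_statistic: float
    omnibus_df: tuple
    omnibus_p: float
    pairwise: list
    fold_changes: dict

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "omnibus_statistic": self.omnibus_statistic,
            "omnibus_df": list(self.omnibus_df),
            "omnibus_p": self.omnibus_p,
            "pairwise": [
                {
                    "pair": list(p.pair),
                    "statistic": p.statistic,
                    "p_raw": p.p_raw,
                    "p_adjusted": p.p_adjusted,
                }
                for p in self.pairwise
            ],
            "fold_changes": {f"{a}/{b}": v for (a, b), v in self.fold_changes.items()},
        }


def _check_groups(groups: Mapping[str, Sequence[float]], positive: bool) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=np.float64)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
        if positive and not np.all(arr > 0):
            raise ValueError(f"group {name!r} contains non-positive values")
        out[str(name)] = arr
    return out


def geometric_mean(values) -> float:
    arr = np.asarray(values, dtype=np.float64)
    if not np.all(arr > 0):
        raise ValueError("geometric mean requires positive values")
    return float(10 ** np.mean(np.log10(arr)))


def fold_change_backtransformed(group_a, group_b) -> float:
    """Ratio of back-transformed mean log10 values (geometric means)."""
    return geometric_mean(group_a) / geometric_mean(group_b)


def _fold_changes(groups: dict) -> dict:
    return {
        (a, b): fold_change_backtransformed(groups[a], groups[b])
        for a, b in combinations(groups, 2)
    }


def _dunn_pairwise(groups: dict) -> list[PairwiseResult]:
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # midranks
    mean_rank = {}
    start = 0
    for n in names:
        size = groups[n].size
        mean_rank[n] = ranks[start:start + size].mean()
        start += size
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    results = []
    raw_ps = []
    for a, b in combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        results.append((a, b, z, p))
        raw_ps.append(p)
    adj = multipletests(raw_ps, method="holm")[1]
    return [
        PairwiseResult(pair=(a, b), statistic=z, p_raw=p, p_adjusted=float(pa))
        for (a, b, z, p), pa in zip(results, adj)
    ]


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis omnibus test with Dunn/Holm post hoc comparisons.

    Degenerate case: if every observation is identical the rank variance is
    zero; H is reported as 0 with p = 1 and all pairwise p = 1.
    """
    g = _check_groups(groups, positive=False)
    pooled = np.concatenate(list(g.values()))
    if np.ptp(pooled) == 0:
        pairwise = [
            PairwiseResult(pair=(a, b), statistic=0.0, p_raw=1.0, p_adjusted=1.0)
            for a, b in combinations(g, 2)
        ]
        fold = {
            (a, b): 1.0 for a, b in combinations(g, 2)
        } if np.all(pooled > 0) else {}
        return GroupComparison("kruskal_dunn", g, 0.0, (len(g) - 1,), 1.0,
                               pairwise, fold)
    h, p = sps.kruskal(*g.values())
    fold = _fold_changes(g) if all(np.all(v > 0) for v in g.values()) else {}
    return GroupComparison(
        method="kruskal_dunn",
        groups=g,
        omnibus_statistic=float(h),
        omnibus_df=(len(g) - 1,),
        omnibus_p=float(p),
        pairwise=_dunn_pairwise(g),
        fold_changes=fold,
    )


def anova_tukey_log(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA on log10 values with Tukey HSD pairwise comparisons.

    Raises if any sample is non-positive (cannot be log-transformed).
    Identical groups yield F = 0 and all pairwise p = 1.
    """
    g = _check_groups(groups, positive=True)
    logs = {n: np.log10(v) for n, v in g.items()}
    pooled = np.concatenate(list(logs.values()))
    names = list(g)
    k = len(names)
    n_total = pooled.size

    if np.ptp(pooled) == 0:
        pairwise = [
            PairwiseResult(pair=(a, b), statistic=0.0, p_raw=1.0, p_adjusted=1.0)
            for a, b in combinations(names, 2)
        ]
        return GroupComparison("anova_tukey_log", g, 0.0, (k - 1, n_total - k),
                               1.0, pairwise, _fold_changes(g))

    f_stat, p = sps.f_oneway(*logs.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate([[n] * logs[n].size for n in names])
    tukey = pairwise_tukeyhsd(pooled, labels)
    pairwise = []
    for row in tukey.summary().data[1:]:
        a, b = str(row[0]), str(row[1])
        # Tukey p-values are already family-wise adjusted
        pairwise.append(
            PairwiseResult(pair=(a, b), statistic=float(row[2]),
                           p_raw=float(row[3]), p_adjusted=float(row[3]))
        )
    return GroupComparison(
        method="anova_tukey_log",
        groups=g,
        omnibus_statistic=float(f_stat),
        omnibus_df=(k - 1, n_total - k),
        omnibus_p=float(p),
        pairwise=pairwise,
        fold_changes=_fold_changes(g),
    )
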