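"""Tipping-point calls, dynamic network biomarkers and dark genes.

A time point T is called a critical state (tipping point) when the global
DNFE score both (i) increased over the previous time point in the mean and
(ii) differs significantly from the prior score level by a one-sample
t-test, S = sqrt(n) (mean(X) - x) / SD(X), of the per-case-sample scores at
T against the previous mean x (P < alpha). At a called tipping point the
top 5% of genes by mean local DNFE are the dynamic network biomarkers
(DNBs); DNB members whose expression shows no case-vs-reference difference
(Welch t-test P >= alpha) while their per-sample local DNFE does differ
from the previous time point (P < alpha) are the "dark genes" — network-
level actors invisible to differential expression.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import ExpressionMatrix

__all__ = [
    "ScoreSeries",
    "TippingCall",
    "DNBSet",
    "DarkGeneSet",
    "detect_tipping",
    "extract_dnbs",
    "find_dark_genes",
]


@dataclasses.dataclass
class ScoreSeries:
    """Per-time-point DNFE scores, globally and per gene.

    Attributes
    ----------
    time_points
        Ordered labels.
    sample_scores
        Per time point, the global score of each case sample (each case
        sample perturbs the reference set independently).
    sample_gene_scores
        Per time point, a genes x case-samples table of local scores.
    n_reference
        Size n of the reference set used for every perturbation.
    """

    time_points: list[str]
    sample_scores: dict[str, np.ndarray]
    sample_gene_scores: dict[str, pd.DataFrame]
    n_reference: int

    def mean_scores(self) -> pd.Series:
        return pd.Series(
            {t: float(np.mean(self.sample_scores[t])) for t in self.time_points},
            name="mean_dnfe",
        )

    def sd_scores(self) -> pd.Series:
        return pd.Series(
            {t: float(np.std(self.sample_scores[t], ddof=1))
             if len(self.sample_scores[t]) > 1 else 0.0
             for t in self.time_points},
            name="sd_dnfe",
        )

    def gene_scores(self) -> pd.DataFrame:
        """Mean local DNFE per gene per time point (the landscape table)."""
        return pd.DataFrame(
            {t: self.sample_gene_scores[t].mean(axis=1) for t in self.time_points}
        )


@dataclasses.dataclass(frozen=True)
class TippingCall:
    time_point: str
    passes_increase: bool
    t_stat: float
    p_value: float
    is_tipping: bool
    indeterminate: bool = False


@dataclasses.dataclass(frozen=True)
class DNBSet:
    time_point: str
    genes: list[str]
    quantile: float


@dataclasses.dataclass(frozen=True)
class DarkGeneSet:
    time_point: str
    genes: list[str]
    expression_p: dict[str, float]
    dnfe_p: dict[str, float]


def detect_tipping(series: ScoreSeries, alpha: float = 0.05,
                   prior: str = "previous") -> list[TippingCall]:
    """Scan the score series for critical states.

    For every time point after the first: condition (i) requires the mean
    score to exceed the previous time point's mean; condition (ii) requires
    the one-sample t-test of the case-sample scores against the prior mean
    (``prior='previous'``: the previous time point's mean; ``'pooled'``:
    the mean over all earlier time points) to reach P < alpha. A time point
    with a single case sample has no within-point SD and is marked
    indeterminate.
    """
    if len(series.time_points) < 2:
        raise ValueError("need at least 2 time points to detect a tipping point")
    if prior not in ("previous", "pooled"):
        raise ValueError("prior must be 'previous' or 'pooled'")
    calls: list[TippingCall] = []
    means = series.mean_scores()
    for idx in range(1, len(series.time_points)):
        t = series.time_points[idx]
        scores = np.asarray(series.sample_scores[t], dtype=float)
        if prior == "previous":
            x = means.iloc[idx - 1]
        else:
            pooled = np.concatenate(
                [series.sample_scores[u] for u in series.time_points[:idx]]
            )
            x = float(np.mean(pooled))
        increase = bool(means.iloc[idx] > means.iloc[idx - 1])
        if scores.size < 2:
            calls.append(TippingCall(t, increase, math.nan, math.nan,
                                     is_tipping=False, indeterminate=True))
            continue
        sd = scores.std(ddof=1)
        if sd == 0.0:
            stat = 0.0 if scores.mean() == x else math.inf
            p = 1.0 if scores.mean() == x else 0.0
        else:
            stat, p = scipy.stats.ttest_1samp(scores, popmean=x)
            stat, p = float(stat), float(p)
        calls.append(TippingCall(t, increase, stat, p,
                                 is_tipping=increase and p < alpha))
    return calls


def extract_dnbs(gene_scores: Mapping[str, float] | pd.Series,
                 quantile: float = 0.05,
                 time_point: str = "") -> DNBSet:
    """Top-quantile genes by local DNFE score at a called tipping point.

    Keeps ``ceil(quantile * m)`` genes, sorted by score descending with
    ties broken by gene ID, so the set is invariant to input order.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    items = sorted(dict(gene_scores).items(), key=lambda kv: (-kv[1], kv[0]))
    if not items:
        raise ValueError("no scored genes")
    k = math.ceil(quantile * len(items))
    return DNBSet(time_point, [g for g, _ in items[:k]], quantile)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample p-value; identical-constant groups give p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    _, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return 1.0 if math.isnan(p) else float(p)


def find_dark_genes(dnbs: DNBSet,
                    case_expr: ExpressionMatrix,
                    ref_expr: ExpressionMatrix,
                    dnfe_at: pd.DataFrame,
                    dnfe_prev: pd.DataFrame,
                    alpha: float = 0.05) -> DarkGeneSet:
    """DNB members that change in DNFE but not in expression.

    Per DNB gene, a Welch t-test compares case vs reference expression
    (``p_expr``) and another compares the per-case-sample local DNFE at the
    tipping point vs the previous time point (``p_dnfe``). Dark genes
    satisfy ``p_expr >= alpha`` and ``p_dnfe < alpha``.
    """
    if not dnbs.genes:
        raise ValueError("empty DNB set")
    case_idx = {g: i for i, g in enumerate(case_expr.gene_ids)}
    ref_idx = {g: i for i, g in enumerate(ref_expr.gene_ids)}
    genes, p_expr_of, p_dnfe_of = [], {}, {}
    for g in dnbs.genes:
        p_expr = _welch_p(case_expr.values[case_idx[g]], ref_expr.values[ref_idx[g]])
        p_dnfe = _welch_p(
            np.asarray(dnfe_at.loc[g], dtype=float),
            np.asarray(dnfe_prev.loc[g], dtype=float),
        )
        p_expr_of[g], p_dnfe_of[g] = p_expr, p_dnfe
        if p_expr >= alpha and p_dnfe < alpha:
            genes.append(g)
    return DarkGeneSet(dnbs.time_point, genes, p_expr_of, p_dnfe_of)
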