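"""Correlation-based sample outlier detection within experimental groups.

A sample that went wrong — degraded, mislabeled, badly injected — loses
correlation to its biological replicates.  Within each subject-sample-factor
(SSF) group, each sample's median correlation to its group partners is
transformed to a score log(1 - cor_median); samples whose score exceeds the
group's upper Tukey fence (Q3 + 1.5 IQR, high end only) are flagged.  The
evaluation harness measures, after removal, the fraction of features that
are differential across groups (one-way ANOVA F-test with Benjamini-Hochberg
adjustment).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.stats.multitest import multipletests

from .censorship import NotApplicableError, SampleGroups, validate_groups
from .matrix import AbundanceMatrix, CorrelationMatrixSet, pairwise_icikt

__all__ = [
    "OutlierReport",
    "median_group_correlation",
    "outlier_score_and_flag",
    "detect_outliers",
    "significant_fraction",
]

logger = logging.getLogger(__name__)

# 1 - cor is clamped here before the log; clamping can only lower a score,
# so it can never create a high-end outlier
_COR_CEILING = 1.0 - 1e-15


@dataclass(frozen=True)
class OutlierReport:
    """Per-sample outlier scores and flags.

    ``table`` columns: sample_id, group, median_correlation, score,
    is_outlier.  ``fences`` maps group -> upper fence used.  The score
    log(1 - cor_median) decreases monotonically in the median correlation,
    so only low-correlation samples can be flagged.
    """

    table: pd.DataFrame
    fences: dict[str, float]


def median_group_correlation(
    corr_set: CorrelationMatrixSet, groups: SampleGroups
) -> pd.Series:
    """Median of each sample's correlations to the other samples of its group.

    Undefined (NaN) cells are skipped.  Samples with fewer than 2 defined
    partners are excluded with a warning.
    """
    ids = list(corr_set.ids)
    label = {s: str(groups[s]) for s in ids if s in groups}
    missing = [s for s in ids if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    out = {}
    for i, s in enumerate(ids):
        partners = [
            corr_set.tau[i, j]
            for j, t in enumerate(ids)
            if j != i and label[t] == label[s] and not math.isnan(corr_set.tau[i, j])
        ]
        if len(partners) < 2:
            logger.warning(
                "sample %s excluded: fewer than 2 defined within-group partners", s
            )
            continue
        out[s] = float(np.median(partners))
    return pd.Series(out, name="median_correlation")


def outlier_score_and_flag(
    med_cors: pd.Series, groups: SampleGroups
) -> OutlierReport:
    """Score samples and flag high-end outliers per group.

    score = ln(1 - median_correlation); within each group samples whose
    score strictly exceeds Q3 + 1.5 IQR (quartiles by linear interpolation)
    are flagged.  Only the high end is fenced: an unusually *high*
    correlation is never an outlier here.
    """
    scores = np.log(1.0 - np.minimum(med_cors.to_numpy(dtype=float), _COR_CEILING))
    df = pd.DataFrame(
        {
            "sample_id": med_cors.index,
            "group": [str(groups[s]) for s in med_cors.index],
            "median_correlation": med_cors.to_numpy(dtype=float),
            "score": scores,
        }
    )
    fences: dict[str, float] = {}
    flags = np.zeros(len(df), dtype=bool)
    for g, sub in df.groupby("group"):
        q1, q3 = np.percentile(sub["score"], [25, 75])  # linear interpolation
        fence = q3 + 1.5 * (q3 - q1)
        fences[g] = float(fence)
        flags[sub.index[sub["score"] > fence]] = True
    df["is_outlier"] = flags
    return OutlierReport(table=df, fences=fences)


def detect_outliers(
    matrix: AbundanceMatrix,
    groups: SampleGroups,
    method: str = "icikt",
    perspective: str = "global",
    n_workers: int = 1,
) -> OutlierReport:
    """Full pipeline: sample-sample correlations -> median -> score -> flags."""
    if method == "icikt":
        corr_set = pairwise_icikt(
            matrix, axis="samples", perspective=perspective, n_workers=n_workers
        )
    else:
        from .matrix import baseline_correlations

        corr_set = baseline_correlations(matrix, method=method, axis="samples")
    med = median_group_correlation(corr_set, groups)
    return outlier_score_and_flag(med, groups)


def significant_fraction(
    matrix: AbundanceMatrix,
    groups: SampleGroups,
    removed: Iterable[str] = (),
    alpha: float = 0.05,
) -> float:
    """Fraction of features differential across groups after sample removal.

    Per feature, a one-way ANOVA F-test across the remaining groups (each
    needing >= 2 present values), Benjamini-Hochberg adjustment over the
    testable features, and the fraction with adjusted p <= alpha over ALL
    features.  The ordinary F-test is the evaluation harness here;
    moderated-variance statistics are out of scope.
    """
    removed = set(removed)
    sub = matrix.drop_samples(removed) if removed else matrix
    by_group = validate_groups(sub, {s: groups[s] for s in sub.sample_ids})
    if len(by_group) < 2:
        raise NotApplicableError("need >= 2 groups with remaining samples")
    data = sub.with_nan()
    pvals = np.full(sub.n_features, np.nan)
    col_idx = list(by_group.values())
    n_replicated = 0
    for i in range(sub.n_features):
        arms = []
        for cols in col_idx:
            v = data[i, cols]
            v = v[~np.isnan(v)]
            if v.size >= 2:
                arms.append(v)
        if len(arms) < 2:
            continue
        n_replicated += 1
        # a feature constant everywhere has no F statistic; it simply
        # cannot be called significant
        if len(set(np.concatenate(arms))) == 1:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero within-group variance -> F = inf
            pvals[i] = f_oneway(*arms).pvalue
    if n_replicated == 0:
        raise NotApplicableError("no feature has enough replication for the F-test")
    testable = ~np.isnan(pvals)
    if not testable.any():
        return 0.0
    adj = np.full_like(pvals, np.nan)
    adj[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    return float((adj[testable] <= alpha).sum() / sub.n_features)
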