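"""Diagnostics for whether missingness is consistent with left-censorship.

If missing values arise because analytes fall below the limit of detection,
then whenever a feature is missing in some samples of a group, its values in
the samples where it *is* present should sit low in those samples' intensity
distributions.  Two diagnostics exploit this:

- a binomial test counting how often such present values fall at or below
  their sample's median (:func:`left_censor_binomial_test`), and
- the relationship between a feature's median within-sample rank and the
  number of samples it is missing from (:func:`rank_missing_summary`):
  under left-censorship the two are negatively correlated, under random
  missingness they are unrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, kendalltau, rankdata
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix

__all__ = [
    "SampleGroups",
    "NotApplicableError",
    "BinomialCensorResult",
    "RankMissingSummary",
    "RankMissingCorrelation",
    "validate_groups",
    "left_censor_binomial_test",
    "left_censor_binomial_batch",
    "rank_missing_summary",
    "rank_missing_correlation",
]

# sample id -> combined subject-sample-factor (SSF) label
SampleGroups = Mapping[str, str]


class NotApplicableError(ValueError):
    """The diagnostic cannot be computed on this dataset.

    Raised e.g. when no feature has both missing and present values within
    any group — mirroring the exclusion of such datasets from analysis
    rather than returning a fabricated number.
    """


@dataclass(frozen=True)
class BinomialCensorResult:
    successes: int
    failures: int
    p_value: float

    @property
    def estimate(self) -> float:
        return self.successes / (self.successes + self.failures)


@dataclass(frozen=True)
class RankMissingSummary:
    """Per-(feature, group) rank records and per-n_missing aggregates.

    ``per_feature`` columns: feature_id, group, median_rank, n_missing.
    ``aggregates`` columns: n_missing, median_median_rank, min_median_rank.
    Ranks ascend with abundance (rank 1 = lowest present value).
    """

    per_feature: pd.DataFrame
    aggregates: pd.DataFrame


@dataclass(frozen=True)
class RankMissingCorrelation:
    median_rank_tau: float
    min_median_rank_tau: float


def validate_groups(matrix: AbundanceMatrix, groups: SampleGroups) -> dict[str, list[int]]:
    """Map each group label to the column indices of its samples."""
    missing = [s for s in matrix.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    out: dict[str, list[int]] = {}
    for j, s in enumerate(matrix.sample_ids):
        label = groups[s]
        if label == "" or label is None:
            raise ValueError(f"empty group label for sample {s!r}")
        out.setdefault(str(label), []).append(j)
    return out


def left_censor_binomial_test(
    matrix: AbundanceMatrix,
    groups: SampleGroups,
    alternative: str = "greater",
) -> BinomialCensorResult:
    """Exact binomial test for left-censorship against a 0.5 null.

    Within each group, each sample's median of present abundances is
    computed.  For every feature that is missing in at least one sample of
    the group (and present in at least one), each present value counts as a
    success if it is less than or equal to its sample's median, otherwise a
    failure.  Counts aggregate across groups into one exact binomial test.
    The default alternative is one-sided toward success (the direction
    left-censorship pushes); pass ``"two-sided"`` to test symmetrically.
    """
    data = matrix.with_nan()
    by_group = validate_groups(matrix, groups)
    successes = failures = 0
    for cols in by_group.values():
        sub = data[:, cols]
        present = ~np.isnan(sub)
        if not present.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sample columns
            medians = np.nanmedian(sub, axis=0)
        n_missing = (~present).sum(axis=1)
        eligible = (n_missing > 0) & (present.sum(axis=1) > 0)
        if not eligible.any():
            continue
        vals = sub[eligible]
        pres = present[eligible]
        below = vals <= medians[None, :]
        successes += int((below & pres).sum())
        failures += int((~below & pres).sum())
    total = successes + failures
    if total == 0:
        raise NotApplicableError(
            "no feature has both missing and present values within a group"
        )
    p = binomtest(successes, total, 0.5, alternative=alternative).pvalue
    return BinomialCensorResult(successes=successes, failures=failures, p_value=float(p))


def left_censor_binomial_batch(
    datasets: Sequence[tuple[AbundanceMatrix, SampleGroups]],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Run the binomial censorship test across datasets with BH adjustment.

    Datasets on which the test is not applicable get NaN rows; the
    Benjamini-Hochberg adjustment runs over the applicable p-values only.
    """
    rows = []
    for matrix, groups in datasets:
        try:
            r = left_censor_binomial_test(matrix, groups, alternative=alternative)
            rows.append((r.successes, r.failures, r.estimate, r.p_value))
        except NotApplicableError:
            rows.append((np.nan, np.nan, np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["successes", "failures", "estimate", "p_value"])
    df["p_adjusted"] = np.nan
    ok = df["p_value"].notna()
    if ok.any():
        df.loc[ok, "p_adjusted"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    return df


def rank_missing_summary(matrix: AbundanceMatrix, groups: SampleGroups) -> RankMissingSummary:
    """Median within-sample rank vs missing-sample count, per feature and group.

    Within each sample, present features are ranked by ascending abundance
    (average rank for exact ties).  Each feature's median rank across the
    group's samples where it is present is recorded together with the
    number of group samples it is missing from; aggregates report the
    median and minimum of median ranks per n_missing value.
    """
    data = matrix.with_nan()
    by_group = validate_groups(matrix, groups)
    records = []
    for label, cols in by_group.items():
        sub = data[:, cols]
        present = ~np.isnan(sub)
        ranks = np.full(sub.shape, np.nan)
        for k in range(sub.shape[1]):
            p = present[:, k]
            if p.any():
                ranks[p, k] = rankdata(sub[p, k], method="average")
        n_missing = (~present).sum(axis=1)
        med = np.full(sub.shape[0], np.nan)
        any_present = present.any(axis=1)
        med[any_present] = np.nanmedian(ranks[any_present], axis=1)
        for i in np.flatnonzero(any_present):
            records.append((matrix.feature_ids[i], label, float(med[i]), int(n_missing[i])))
    per_feature = pd.DataFrame(
        records, columns=["feature_id", "group", "median_rank", "n_missing"]
    )
    aggregates = (
        per_feature.groupby("n_missing")["median_rank"]
        .agg(median_median_rank="median", min_median_rank="min")
        .reset_index()
    )
    return RankMissingSummary(per_feature=per_feature, aggregates=aggregates)


def rank_missing_correlation(summary: RankMissingSummary) -> RankMissingCorrelation:
    """Kendall tau of (median rank, n_missing) and (min median rank, n_missing).

    Under left-censorship both correlations are negative; under random
    missingness they hover near zero.  Degenerate inputs (fewer than two
    distinct n_missing values, or constant ranks) are not correlatable.
    """
    agg = summary.aggregates
    if agg["n_missing"].nunique() < 2:
        raise NotApplicableError("need at least two distinct n_missing values")
    taus = []
    for col in ("median_median_rank", "min_median_rank"):
        if agg[col].nunique() < 2:
            raise NotApplicableError(f"{col} is constant; correlation undefined")
        taus.append(float(kendalltau(agg[col], agg["n_missing"]).statistic))
    return RankMissingCorrelation(median_rank_tau=taus[0], min_median_rank_tau=taus[1])
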