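"""All-pairs correlation over an abundance matrix.

Drives the pairwise ICI-Kt core over every unordered pair of samples (or
features), optionally rescales by the dataset-wide maximum attainable tau,
composites tau with completeness, and provides the baseline correlation
variants used for method comparison (pairwise-complete Kendall, Pearson
with/without zero replacement, log transforms).

Parallel execution is convenience-only: workers receive pair-index chunks
and results are reassembled by index, so output never depends on worker
count or scheduling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import kendalltau, pearsonr

from .core import UndefinedCorrelationError, ici_kt_fast

__all__ = [
    "AbundanceMatrix",
    "CorrelationMatrixSet",
    "pairwise_icikt",
    "composite_icikt_completeness",
    "baseline_correlations",
    "correlation_long_format",
    "long_format_to_set",
    "BASELINE_METHODS",
]

logger = logging.getLogger(__name__)

BASELINE_METHODS = (
    "kt_base",
    "pearson_base",
    "pearson_base_nozero",
    "pearson_log1p",
    "pearson_log",
)


@dataclass(frozen=True)
class AbundanceMatrix:
    """Feature-by-sample abundance matrix with an explicit missingness mask.

    Rows are metabolite features, columns are samples.  Cells under the mask
    carry no numeric meaning (the stored value there is arbitrary).
    """

    values: np.ndarray
    missing_mask: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.missing_mask, dtype=bool)
        if values.ndim != 2 or mask.shape != values.shape:
            raise ValueError("values must be 2-D with a mask of the same shape")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing_mask", mask)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(self.feature_ids) != values.shape[0]:
            raise ValueError("feature_ids length does not match row count")
        if len(self.sample_ids) != values.shape[1]:
            raise ValueError("sample_ids length does not match column count")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_nan(self) -> np.ndarray:
        """Dense float matrix with NaN in masked cells."""
        out = self.values.copy()
        out[self.missing_mask] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.with_nan(), index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        values = df.to_numpy(dtype=float)
        return cls(
            values=np.nan_to_num(values),
            missing_mask=np.isnan(values),
            feature_ids=tuple(str(i) for i in df.index),
            sample_ids=tuple(str(c) for c in df.columns),
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s not in drop]
        return AbundanceMatrix(
            values=self.values[:, keep],
            missing_mask=self.missing_mask[:, keep],
            feature_ids=self.feature_ids,
            sample_ids=tuple(self.sample_ids[i] for i in keep),
        )


@dataclass(frozen=True)
class CorrelationMatrixSet:
    """Symmetric tau / p-value / tau_max / completeness matrices with labels."""

    tau: np.ndarray
    p_value: np.ndarray
    tau_max: np.ndarray
    completeness: np.ndarray
    ids: tuple[str, ...]
    method_label: str = "icikt"
    perspective: str = "global"
    axis: str = "samples"
    scaled: bool = False

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("tau", "p_value", "tau_max", "completeness"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix shape {m.shape} != ({n}, {n})")
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError(f"{name} matrix is not symmetric")
            object.__setattr__(self, name, m)
        object.__setattr__(self, "ids", tuple(self.ids))

    def frame(self, stat: str = "tau") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, stat), index=list(self.ids), columns=list(self.ids))


def _axis_vectors(matrix: AbundanceMatrix, axis: str):
    data = matrix.with_nan()
    if axis == "samples":
        return [data[:, j] for j in range(matrix.n_samples)], matrix.sample_ids
    if axis == "features":
        return [data[i, :] for i in range(matrix.n_features)], matrix.feature_ids
    raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")


def _icikt_chunk(pairs, vectors, perspective):
    out = []
    for i, j in pairs:
        try:
            o = ici_kt_fast(vectors[i], vectors[j], perspective=perspective)
            out.append((i, j, o.tau, o.p_value, o.tau_max, o.completeness))
        except UndefinedCorrelationError:
            out.append((i, j, np.nan, np.nan, np.nan, np.nan))
    return out


def pairwise_icikt(
    matrix: AbundanceMatrix,
    axis: str = "samples",
    perspective: str = "global",
    scale_max: bool = False,
    n_workers: int = 1,
) -> CorrelationMatrixSet:
    """ICI-Kt over all unordered pairs along one axis of the matrix.

    Diagonal entries are computed, not assumed, so a vector correlated with
    itself reports its own completeness honestly.  Undefined pairs (e.g. all
    values tied after sentinel substitution) propagate as NaN cells with a
    warning, never as 0.  With ``scale_max`` the whole tau matrix is divided
    by the maximum tau_max over off-diagonal pairs; scaling changes the
    values a dataset reports and makes cross-dataset comparison invalid, so
    it defaults to off.
    """
    vectors, ids = _axis_vectors(matrix, axis)
    n = len(vectors)
    if n < 2:
        raise ValueError(f"need at least 2 vectors along axis {axis!r}")
    pairs = [(i, j) for i in range(n) for j in range(i, n)]
    if n_workers <= 1:
        results = _icikt_chunk(pairs, vectors, perspective)
    else:
        chunks = np.array_split(np.arange(len(pairs)), min(n_workers * 4, len(pairs)))
        parts = Parallel(n_jobs=n_workers)(
            delayed(_icikt_chunk)([pairs[k] for k in chunk], vectors, perspective)
            for chunk in chunks
            if chunk.size
        )
        results = [r for part in parts for r in part]

    mats = {k: np.full((n, n), np.nan) for k in ("tau", "p", "tmax", "comp")}
    for i, j, tau, p, tmax, comp in results:
        if np.isnan(tau):
            logger.warning("undefined correlation for pair (%s, %s)", ids[i], ids[j])
        for key, val in zip(("tau", "p", "tmax", "comp"), (tau, p, tmax, comp)):
            mats[key][i, j] = mats[key][j, i] = val

    scaled = False
    if scale_max:
        iu = np.triu_indices(n, 1)
        off = mats["tmax"][iu]
        if np.isnan(off).all():
            raise UndefinedCorrelationError("no defined tau_max value to scale by")
        mats["tau"] = mats["tau"] / np.nanmax(off)
        scaled = True

    return CorrelationMatrixSet(
        tau=mats["tau"],
        p_value=mats["p"],
        tau_max=mats["tmax"],
        completeness=mats["comp"],
        ids=ids,
        method_label="icikt",
        perspective=perspective,
        axis=axis,
        scaled=scaled,
    )


def composite_icikt_completeness(corr_set: CorrelationMatrixSet) -> np.ndarray:
    """Element-wise tau x completeness (the icikt_complete composite).

    Applied to the unscaled tau by convention: completeness modulates the
    observed correlation before any dataset-wide tau_max rescaling.
    """
    return corr_set.tau * corr_set.completeness


def _pairwise_complete_pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return np.nan
    x, y = a[ok], b[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(pearsonr(x, y).statistic)


def _pairwise_complete_kendall(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return np.nan
    res = kendalltau(a[ok], b[ok])
    return float(res.statistic)


def baseline_correlations(
    matrix: AbundanceMatrix, method: str, axis: str = "samples"
) -> CorrelationMatrixSet:
    """Comparison correlation variants, all pairwise-complete.

    - ``kt_base``: Kendall tau-b, missing left as NA, pairwise-complete.
    - ``pearson_base``: Pearson with missing replaced by zero first.
    - ``pearson_base_nozero``: Pearson with missing left as NA.
    - ``pearson_log1p``: Pearson on log(x + 1)-transformed values.
    - ``pearson_log``: Pearson on log(x); non-finite transforms (log of
      zero or of a negative value) become missing.

    The p_value and tau_max planes are NaN for these methods; completeness
    is reported from the original missingness pattern.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {BASELINE_METHODS}")
    vectors, ids = _axis_vectors(matrix, axis)
    n = len(vectors)
    if n < 2:
        raise ValueError("need at least 2 vectors")

    def transform(v: np.ndarray) -> np.ndarray:
        if method == "pearson_base":
            return np.nan_to_num(v)
        if method == "pearson_log1p":
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.log1p(v)
            out[~np.isfinite(out)] = np.nan
            return out
        if method == "pearson_log":
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.log(v)
            out[~np.isfinite(out)] = np.nan
            return out
        return v

    tvecs = [transform(v) for v in vectors]
    corr = _pairwise_complete_kendall if method == "kt_base" else _pairwise_complete_pearson

    tau = np.full((n, n), np.nan)
    comp = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            tau[i, j] = tau[j, i] = corr(tvecs[i], tvecs[j])
            c = 1.0 - (np.isnan(vectors[i]) | np.isnan(vectors[j])).mean()
            comp[i, j] = comp[j, i] = c
            if np.isnan(tau[i, j]):
                logger.warning("undefined %s for pair (%s, %s)", method, ids[i], ids[j])
    nanmat = np.full((n, n), np.nan)
    return CorrelationMatrixSet(
        tau=tau,
        p_value=nanmat,
        tau_max=nanmat,
        completeness=comp,
        ids=ids,
        method_label=method,
        axis=axis,
    )


def correlation_long_format(
    corr_set: CorrelationMatrixSet, include_diagonal: bool = False
) -> pd.DataFrame:
    """One row per unordered pair: (id_a, id_b, tau, p_value, tau_max, completeness)."""
    n = len(corr_set.ids)
    rows = []
    for i in range(n):
        for j in range(i if include_diagonal else i + 1, n):
            rows.append(
                {
                    "id_a": corr_set.ids[i],
                    "id_b": corr_set.ids[j],
                    "tau": corr_set.tau[i, j],
                    "p_value": corr_set.p_value[i, j],
                    "tau_max": corr_set.tau_max[i, j],
                    "completeness": corr_set.completeness[i, j],
                }
            )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "tau", "p_value", "tau_max", "completeness"])


def long_format_to_set(
    table: pd.DataFrame,
    ids: Sequence[str] | None = None,
    diagonal_default: float = 1.0,
    **labels,
) -> CorrelationMatrixSet:
    """Rebuild the symmetric matrix set from its long format (lossless).

    Pairs absent from the table stay NaN; diagonal cells absent from the
    table are filled with ``diagonal_default`` for tau / tau_max /
    completeness (p_value diagonal stays NaN) so the round trip of an
    off-diagonal-only table is still usable downstream.
    """
    if ids is None:
        ids = sorted(set(table["id_a"]) | set(table["id_b"]))
    index = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    mats = {k: np.full((n, n), np.nan) for k in ("tau", "p_value", "tau_max", "completeness")}
    for key in ("tau", "tau_max", "completeness"):
        np.fill_diagonal(mats[key], diagonal_default)
    for row in table.itertuples(index=False):
        i, j = index[row.id_a], index[row.id_b]
        for key in mats:
            mats[key][i, j] = mats[key][j, i] = getattr(row, key)
    return CorrelationMatrixSet(ids=tuple(ids), **mats, **labels)
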