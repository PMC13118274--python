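"""Pairwise information-content-informed Kendall-tau (ICI-Kt) correlation.

Left-censored missing values — measurements below an instrument's limit of
detection — are not missing at random: their absence says the true value is
small.  ICI-Kt folds that information into the Kendall tau-b correlation by
extending the concordant / discordant pair definitions so that a
present-vs-missing comparison carries ordering information (a missing value
ranks below every observed value, and two missing values tie).

Two perspectives are supported for points missing in *both* vectors:

``local``
    drop those x-y points entirely; appropriate when only the two vectors
    being compared matter.
``global``
    keep them and count them as ties in both variables, so every pair of
    samples drawn from the same feature set sees the same number of pair
    comparisons.

This module provides the exact O(n^2) rule-based census
(:func:`count_pairs_bruteforce`), the O(n log n) sentinel-substitution path
(:func:`ici_kt_fast`), the theoretical maximum tau given the tie structure
(:func:`tau_max`), the pairwise :func:`completeness` fraction, and the
tie-corrected Mann-Kendall p-value (:func:`mann_kendall_pvalue`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "PairCounts",
    "CorrelationOutcome",
    "UndefinedCorrelationError",
    "as_values_and_mask",
    "count_pairs_bruteforce",
    "tau_b_from_counts",
    "tau_max",
    "completeness",
    "mann_kendall_pvalue",
    "ici_kt_fast",
]


class UndefinedCorrelationError(ValueError):
    """The correlation is undefined for this input.

    Raised when a tau-b denominator vanishes (all values tied in one
    variable), when fewer than two x-y points survive removal of
    commonly-missing points under the local perspective, or when the
    Mann-Kendall variance is non-positive.  Matrix-level drivers catch this
    and propagate the cell as missing — never as a silent 0.
    """


@dataclass(frozen=True)
class PairCounts:
    """Exact integer census of all n(n-1)/2 point pairs of one vector pair.

    ``x_tie_sizes`` / ``y_tie_sizes`` record the multiplicities of tied-value
    groups (sizes > 1 only; missing entries form one shared lowest group) —
    these feed the tie-corrected Mann-Kendall variance.
    """

    n_concordant: int
    n_discordant: int
    n_xtie: int
    n_ytie: int
    n_tie_common: int
    n_tot: int
    x_tie_sizes: tuple[int, ...] = field(default=())
    y_tie_sizes: tuple[int, ...] = field(default=())

    @property
    def s_statistic(self) -> int:
        """Mann-Kendall S = n_concordant - n_discordant."""
        return self.n_concordant - self.n_discordant

    def __post_init__(self) -> None:
        counts = (
            self.n_concordant,
            self.n_discordant,
            self.n_xtie,
            self.n_ytie,
            self.n_tie_common,
            self.n_tot,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative pair count in {counts!r}")
        if self.n_tie_common > min(self.n_xtie, self.n_ytie):
            raise ValueError("common ties exceed per-variable ties")
        # pairs tied in x or y = n_xtie + n_ytie - n_tie_common
        tied_any = self.n_xtie + self.n_ytie - self.n_tie_common
        if self.n_concordant + self.n_discordant + tied_any != self.n_tot:
            raise ValueError("pair census does not partition the pair total")


@dataclass(frozen=True)
class CorrelationOutcome:
    """Full result of one ICI-Kt comparison."""

    tau: float
    p_value: float
    tau_max: float
    completeness: float
    counts: PairCounts
    n_effective: int


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------

def as_values_and_mask(x: Sequence[float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert a vector with missing entries to (values, missing_mask).

    Missing entries may be ``None`` or NaN; masked cells carry no numeric
    meaning downstream.  Infinite values are rejected: they have no rank
    interpretation here.
    """
    arr = np.asarray(
        [np.nan if v is None else v for v in x] if not isinstance(x, np.ndarray) else x,
        dtype=float,
    )
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    mask = np.isnan(arr)
    if np.isinf(arr).any():
        raise ValueError("infinite values are not supported")
    values = np.where(mask, 0.0, arr)  # placeholder under the mask
    return values, mask


def _check_pair(x, y):
    xv, xm = as_values_and_mask(x)
    yv, ym = as_values_and_mask(y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 2:
        raise ValueError("need at least 2 points")
    return xv, xm, yv, ym


def _apply_perspective(xv, xm, yv, ym, perspective: str):
    if perspective not in ("local", "global"):
        raise ValueError(f"unknown perspective {perspective!r}")
    if perspective == "local":
        keep = ~(xm & ym)
        if keep.sum() < 2:
            raise UndefinedCorrelationError(
                "fewer than 2 x-y points remain after removing commonly-missing points"
            )
        return xv[keep], xm[keep], yv[keep], ym[keep]
    return xv, xm, yv, ym


def _tie_sizes(values: np.ndarray, mask: np.ndarray) -> tuple[int, ...]:
    """Multiplicities (>1) of tied groups; all missing entries tie together."""
    sizes = []
    n_miss = int(mask.sum())
    if n_miss > 1:
        sizes.append(n_miss)
    if (~mask).any():
        _, counts = np.unique(values[~mask], return_counts=True)
        sizes.extend(int(c) for c in counts[counts > 1])
    return tuple(sorted(sizes))


# ---------------------------------------------------------------------------
# brute-force census (reference implementation)
# ---------------------------------------------------------------------------

def count_pairs_bruteforce(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    perspective: str = "local",
) -> PairCounts:
    """Classify every i<j pair by the extended concordance rules, in O(n^2).

    The eight concordant and eight discordant rules extend the classical
    definitions with cases such as ``x_i > x_j and y_i != NA, y_j = NA``
    (concordant) and ``x_i > x_j and y_i = NA, y_j != NA`` (discordant):
    within one coordinate a missing value orders below every observed value
    and ties with another missing value.  Pairs tied in x (including
    NA-vs-NA) increment ``n_xtie``, analogously for y; pairs tied in both
    increment ``n_tie_common``.

    Under the ``local`` perspective points missing in both vectors are
    removed first; under ``global`` they are retained as ties in both.
    """
    xv, xm, yv, ym = _check_pair(x, y)
    xv, xm, yv, ym = _apply_perspective(xv, xm, yv, ym, perspective)

    def rel(vi, vj, mi, mj):
        # pairwise ordering of one coordinate under the extended rules
        if mi and mj:
            return 0
        if mi:
            return -1
        if mj:
            return 1
        if vi > vj:
            return 1
        if vi < vj:
            return -1
        return 0

    n = xv.size
    n_c = n_d = n_xt = n_yt = n_both = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            cx = rel(xv[i], xv[j], xm[i], xm[j])
            cy = rel(yv[i], yv[j], ym[i], ym[j])
            if cx == 0:
                n_xt += 1
            if cy == 0:
                n_yt += 1
            if cx == 0 and cy == 0:
                n_both += 1
            elif cx != 0 and cy != 0:
                if cx == cy:
                    n_c += 1
                else:
                    n_d += 1
    return PairCounts(
        n_concordant=n_c,
        n_discordant=n_d,
        n_xtie=n_xt,
        n_ytie=n_yt,
        n_tie_common=n_both,
        n_tot=n * (n - 1) // 2,
        x_tie_sizes=_tie_sizes(xv, xm),
        y_tie_sizes=_tie_sizes(yv, ym),
    )


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

def tau_b_from_counts(counts: PairCounts) -> float:
    """Kendall tau-b from a pair census.

    tau_b = (n_c - n_d) / sqrt((n_tot - n_xtie) * (n_tot - n_ytie))
    """
    dx = counts.n_tot - counts.n_xtie
    dy = counts.n_tot - counts.n_ytie
    if dx <= 0 or dy <= 0:
        raise UndefinedCorrelationError(
            "tau-b denominator is zero: all values tied in one variable"
        )
    return counts.s_statistic / math.sqrt(dx) / math.sqrt(dy)


def tau_max(counts: PairCounts) -> float:
    """Largest tau-b achievable given the tie structure of the pair.

    tau_max = (n_tot - n_xtie - n_ytie + n_tie_common)
              / sqrt((n_tot - n_xtie) * (n_tot - n_ytie))

    Equals 1 when ties are absent or fully shared between the two vectors.
    Computed identically regardless of the sign of the observed correlation;
    dividing a dataset's tau values by the maximum tau_max over all pairs
    rescales them onto a common attainable ceiling.
    """
    dx = counts.n_tot - counts.n_xtie
    dy = counts.n_tot - counts.n_ytie
    if dx <= 0 or dy <= 0:
        raise UndefinedCorrelationError(
            "tau_max denominator is zero: all values tied in one variable"
        )
    num = counts.n_tot - counts.n_xtie - counts.n_ytie + counts.n_tie_common
    return num / math.sqrt(dx) / math.sqrt(dy)


def completeness(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> float:
    """Fraction of features missing in neither vector.

    (n_feat - N_missing_in_either) / n_feat, computed on the full vectors
    before any perspective-dependent removal.
    """
    xv, xm = as_values_and_mask(x)
    yv, ym = as_values_and_mask(y)
    if xv.size != yv.size:
        raise ValueError("length mismatch")
    if xv.size == 0:
        raise ValueError("empty input")
    return float((xv.size - (xm | ym).sum()) / xv.size)


def mann_kendall_pvalue(counts: PairCounts, n: int) -> float:
    """Two-sided Mann-Kendall p-value for S = n_c - n_d.

    Normal approximation z = S / sqrt(Var(S)) without continuity correction,
    with the tie-corrected variance

        Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5) - sum_u u(u-1)(2u+5)] / 18
                 + [sum_t t(t-1)(t-2)][sum_u u(u-1)(u-2)] / [9 n(n-1)(n-2)]
                 + [sum_t t(t-1)][sum_u u(u-1)] / [2 n(n-1)]

    where t and u run over the tied-group multiplicities of x and y.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    t = np.asarray(counts.x_tie_sizes, dtype=float)
    u = np.asarray(counts.y_tie_sizes, dtype=float)
    var = (
        n * (n - 1) * (2 * n + 5)
        - (t * (t - 1) * (2 * t + 5)).sum()
        - (u * (u - 1) * (2 * u + 5)).sum()
    ) / 18.0
    if n > 2:
        var += ((t * (t - 1) * (t - 2)).sum() * (u * (u - 1) * (u - 2)).sum()) / (
            9.0 * n * (n - 1) * (n - 2)
        )
    var += ((t * (t - 1)).sum() * (u * (u - 1)).sum()) / (2.0 * n * (n - 1))
    if var <= 0:
        raise UndefinedCorrelationError("Mann-Kendall variance is non-positive")
    z = counts.s_statistic / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# fast path: sentinel substitution + Knight-style inversion counting
# ---------------------------------------------------------------------------

_BLOCK = 64
_TRIU = np.triu_indices(_BLOCK, 1)


def _count_inversions(a: np.ndarray) -> int:
    """Count strict inversions (i<j, a[i]>a[j]) in O(n log n).

    Hybrid mergesort: base blocks of 64 are counted by a vectorized O(B^2)
    comparison, then sorted runs are merged bottom-up with searchsorted
    providing the cross-run inversion counts.  Padding with +inf adds no
    inversions.
    """
    n = a.size
    if n < 2:
        return 0
    pad = (-n) % _BLOCK
    if pad:
        a = np.concatenate([a, np.full(pad, np.inf)])
    blocks = a.reshape(-1, _BLOCK)
    gt = blocks[:, :, None] > blocks[:, None, :]
    inv = int(gt[:, _TRIU[0], _TRIU[1]].sum())
    arr = np.sort(blocks, axis=1).reshape(-1)
    width = _BLOCK
    total = arr.size
    while width < total:
        for start in range(0, total, 2 * width):
            left = arr[start : start + width]
            right = arr[start + width : start + 2 * width]
            if right.size == 0:
                continue
            # elements of the left run strictly greater than each right element
            inv += int((left.size - np.searchsorted(left, right, side="right")).sum())
            pos_r = np.arange(right.size) + np.searchsorted(left, right, side="right")
            pos_l = np.arange(left.size) + np.searchsorted(right, left, side="left")
            merged = np.empty(left.size + right.size)
            merged[pos_l] = left
            merged[pos_r] = right
            arr[start : start + 2 * width] = merged
        width *= 2
    return inv


def _run_pair_sums(boundaries: np.ndarray) -> int:
    """Sum of c*(c-1)/2 over run lengths delimited by boundary flags."""
    counts = np.diff(np.flatnonzero(boundaries))
    return int((counts * (counts - 1) // 2).sum())


def _pair_census_fast(xs: np.ndarray, ys: np.ndarray) -> tuple[int, int, int, int, int]:
    """Exact (n_tot, n_xtie, n_ytie, n_tie_common, S) via sorting."""
    n = xs.size
    n_tot = n * (n - 1) // 2
    order = np.lexsort((ys, xs))
    x_s = xs[order]
    y_s = ys[order]
    edge = np.empty(n + 1, dtype=bool)
    edge[0] = edge[-1] = True
    edge[1:-1] = x_s[1:] != x_s[:-1]
    n_xtie = _run_pair_sums(edge)
    joint = edge.copy()
    joint[1:-1] |= y_s[1:] != y_s[:-1]
    n_tie_common = _run_pair_sums(joint)
    y_sorted = np.sort(ys)
    edge[1:-1] = y_sorted[1:] != y_sorted[:-1]
    n_ytie = _run_pair_sums(edge)
    # with ties in x broken by y, inversions of y count exactly the
    # discordant "swaps"; ties contribute none
    dis = _count_inversions(y_s)
    s = (n_tot - n_xtie - n_ytie + n_tie_common) - 2 * dis
    return n_tot, n_xtie, n_ytie, n_tie_common, s


def ici_kt_fast(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    perspective: str = "local",
) -> CorrelationOutcome:
    """ICI-Kt correlation in O(n log n) with full pair census.

    Missing entries are replaced by a sentinel strictly smaller than every
    observed value across both vectors — an exact re-expression of the
    extended pair rules, since a missing value orders below all observed
    values and ties with other missing values.  tau-b is then computed by
    sorting plus mergesort exchange counting with tie corrections; the
    result equals ``tau_b_from_counts(count_pairs_bruteforce(x, y))``
    exactly, for both perspectives.  Also returns tau_max, the completeness
    fraction (computed on the full vectors) and the tie-corrected
    Mann-Kendall p-value.
    """
    xv, xm, yv, ym = _check_pair(x, y)
    comp = float((xv.size - (xm | ym).sum()) / xv.size)
    xv, xm, yv, ym = _apply_perspective(xv, xm, yv, ym, perspective)
    n = xv.size

    any_obs = (~xm).any() or (~ym).any()
    if any_obs:
        min_obs = min(
            xv[~xm].min() if (~xm).any() else np.inf,
            yv[~ym].min() if (~ym).any() else np.inf,
        )
        sentinel = min_obs - 1.0 - abs(min_obs) * 1e-6
    else:
        sentinel = 0.0  # everything missing: all tied, caught below
    xs = np.where(xm, sentinel, xv)
    ys = np.where(ym, sentinel, yv)

    n_tot, n_xtie, n_ytie, n_tie_common, s = _pair_census_fast(xs, ys)
    ncd = n_tot - n_xtie - n_ytie + n_tie_common
    counts = PairCounts(
        n_concordant=(ncd + s) // 2,
        n_discordant=(ncd - s) // 2,
        n_xtie=n_xtie,
        n_ytie=n_ytie,
        n_tie_common=n_tie_common,
        n_tot=n_tot,
        x_tie_sizes=_tie_sizes(xv, xm),
        y_tie_sizes=_tie_sizes(yv, ym),
    )
    tau = tau_b_from_counts(counts)  # raises UndefinedCorrelationError if degenerate
    return CorrelationOutcome(
        tau=tau,
        p_value=mann_kendall_pvalue(counts, n),
        tau_max=tau_max(counts),
        completeness=comp,
        counts=counts,
        n_effective=n,
    )
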