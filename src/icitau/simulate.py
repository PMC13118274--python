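"""Synthetic abundance data emulating mass-spectrometry intensity profiles.

All generators draw base intensities from a log-normal distribution
(meanlog 1, sdlog 0.5 on the natural-log scale), which matches the
log-like intensity distributions typical of MS metabolomics data.  On top
of that base the module builds:

- a *perfect* pair: two sorted copies of the same draw, one with uniform
  noise re-sorted, so Kendall correlation is exactly +1 (or -1 when the
  second vector is sorted descending);
- an *outlier* variant replacing the noise of a few high-end points with a
  larger log-normal component;
- a *realistic* pair: the base plus independent normal noise (sd 0.2) in
  each vector, giving an ICI-Kt around 0.90;
- left-censoring operators (intensity cutoff, per-sample dynamic-range
  censoring) and random-missingness operators;
- a 100-sample log10-scale cohort for dynamic-range experiments, with a
  half-minimum imputation partner.

Every generator is a pure function of its parameters and the random seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import AbundanceMatrix

__all__ = [
    "SimulationSpec",
    "gen_perfect_pair",
    "add_outliers",
    "insert_low_missing",
    "gen_realistic_pair",
    "censor_by_cutoff",
    "censor_random",
    "gen_lod_cohort",
    "censor_dynamic_range",
    "half_min_impute",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Default parameters of the simulated datasets.

    meanlog / sdlog parameterize the log-normal base on the natural-log
    scale; noise_range is the uniform noise added to the perfect pair;
    noise_sd is the normal noise of the realistic pair and the cohort;
    outlier draws come from log-normal(outlier_meanlog, outlier_sdlog).
    """

    n: int = 1000
    meanlog: float = 1.0
    sdlog: float = 0.5
    noise_range: tuple[float, float] = (-0.5, 0.5)
    noise_sd: float = 0.2
    outlier_fraction: float = 0.005
    outlier_meanlog: float = 1.2
    outlier_sdlog: float = 0.1


DEFAULT_SPEC = SimulationSpec()


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_perfect_pair(
    seed, spec: SimulationSpec = DEFAULT_SPEC, direction: str = "positive"
) -> tuple[np.ndarray, np.ndarray]:
    """Perfectly rank-correlated pair (tau exactly +1 or -1).

    x is a sorted log-normal draw; y adds uniform noise to x and is then
    re-sorted so the rank correlation stays exact while the values differ.
    For ``negative``, y is the negated re-sorted copy, making the pair a
    true linear mirror: both the Kendall and Pearson correlations of the
    uncensored negative pair are -1 (up to the noise, for Pearson), so
    deviations under censoring are measured from a genuine -1 baseline.
    """
    if spec.n < 2:
        raise ValueError("need n >= 2")
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    rng = _rng(seed)
    x = np.sort(rng.lognormal(mean=spec.meanlog, sigma=spec.sdlog, size=spec.n))
    noise = rng.uniform(*spec.noise_range, size=spec.n)
    y = np.sort(x + noise)
    if direction == "negative":
        y = -y
    return x, y


def add_outliers(
    x: np.ndarray,
    y: np.ndarray,
    seed,
    fraction: float = DEFAULT_SPEC.outlier_fraction,
    spec: SimulationSpec = DEFAULT_SPEC,
    direction: str = "positive",
) -> tuple[np.ndarray, np.ndarray]:
    """Replace the noise of the highest-intensity points with outlier noise.

    For the chosen fraction of points at the high end of x, the uniform
    noise is replaced by uniform + log-normal(outlier_meanlog,
    outlier_sdlog) draws; y is then re-sorted so rank correlation is
    preserved while the value distortion remains.
    """
    n = x.size
    n_out = int(fraction * n)
    if fraction > 0 and n_out < 1:
        warnings.warn("fraction * n < 1: no outlier points inserted", stacklevel=2)
    if n_out < 1:
        return x.copy(), y.copy()
    rng = _rng(seed)
    idx = np.arange(n - n_out, n)  # high end of the sorted base
    y_pos = np.sort(-y) if direction == "negative" else np.sort(y)
    y_pos[idx] = x[idx] + rng.uniform(*spec.noise_range, size=n_out) + rng.lognormal(
        mean=spec.outlier_meanlog, sigma=spec.outlier_sdlog, size=n_out
    )
    y_pos = np.sort(y_pos)
    return x.copy(), -y_pos if direction == "negative" else y_pos


def insert_low_missing(
    x: np.ndarray,
    y: np.ndarray,
    n_missing: int,
    seed,
    target: str = "y",
) -> tuple[np.ndarray, np.ndarray]:
    """Set ``n_missing`` randomly chosen low-end entries of ONE vector to NaN.

    Indices are sampled without replacement from the positions of the
    lowest half of the target vector's values (value-based, so a
    descending-sorted negative-direction vector is censored at its own low
    end).  Only one vector of the pair receives missingness per call;
    n_missing must stay below half the vector length.
    """
    n = x.size
    if n_missing >= n / 2:
        raise ValueError(f"n_missing={n_missing} must be below n/2={n / 2:g}")
    if target not in ("x", "y"):
        raise ValueError("target must be 'x' or 'y'")
    x, y = x.copy(), y.copy()
    if n_missing == 0:
        return x, y
    vec = x if target == "x" else y
    pool = np.argsort(vec, kind="stable")[: n // 2]
    idx = _rng(seed).choice(pool, size=n_missing, replace=False)
    vec[idx] = np.nan
    return x, y


def gen_realistic_pair(
    seed, spec: SimulationSpec = DEFAULT_SPEC
) -> tuple[np.ndarray, np.ndarray]:
    """Two statistical samples: a log-normal base and a noised copy.

    x is the log-normal base draw; y adds N(0, noise_sd) noise to it.  At
    the default parameters the pair's ICI-Kt correlation is near 0.90
    before any censoring.
    """
    rng = _rng(seed)
    x = rng.lognormal(mean=spec.meanlog, sigma=spec.sdlog, size=spec.n)
    y = x + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return x, y


def censor_by_cutoff(
    x: np.ndarray, y: np.ndarray, cutoff: float, impute_zero: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Left-censor both vectors: values below ``cutoff`` become missing.

    With ``impute_zero`` the censored values are set to 0 instead of NaN
    (the zero-replacement comparison variant).
    """
    fill = 0.0 if impute_zero else np.nan
    x, y = x.astype(float).copy(), y.astype(float).copy()
    x[x < cutoff] = fill
    y[y < cutoff] = fill
    return x, y


def censor_random(
    x: np.ndarray, y: np.ndarray, n_positions: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Set ``n_positions`` uniformly random cells of the 2 x n matrix to NaN."""
    n = x.size
    if n_positions > 2 * n:
        raise ValueError(f"n_positions={n_positions} exceeds 2n={2 * n}")
    pair = np.vstack([x, y]).astype(float)
    if n_positions:
        flat = _rng(seed).choice(2 * n, size=n_positions, replace=False)
        pair[np.unravel_index(flat, pair.shape)] = np.nan
    return pair[0], pair[1]


def gen_lod_cohort(
    seed,
    n_samples: int = 100,
    spec: SimulationSpec = DEFAULT_SPEC,
) -> AbundanceMatrix:
    """Cohort of noisy replicate samples on the log10 intensity scale.

    A single log-normal base sample is perturbed with independent normal
    noise (sd ``noise_sd``) on the log scale for each of ``n_samples``
    samples; intensities are then expressed in log10 units so one unit is
    one order of magnitude of dynamic range.
    """
    rng = _rng(seed)
    log_base = rng.normal(spec.meanlog, spec.sdlog, size=spec.n)
    data = np.empty((spec.n, n_samples))
    for j in range(n_samples):
        noisy = log_base + rng.normal(0.0, spec.noise_sd, size=spec.n)
        data[:, j] = np.log10(np.exp(noisy))
    width = len(str(spec.n))
    return AbundanceMatrix(
        values=data,
        missing_mask=np.zeros_like(data, dtype=bool),
        feature_ids=tuple(f"feature_{i + 1:0{width}d}" for i in range(spec.n)),
        sample_ids=tuple(f"sample_{j + 1:03d}" for j in range(n_samples)),
    )


def censor_dynamic_range(
    cohort: AbundanceMatrix, max_level: float, seed
) -> AbundanceMatrix:
    """Per-sample left-censoring with a random detection floor.

    Each sample's censoring value is its own minimum plus a uniform(0,
    ``max_level``) draw; values below it become missing.  Levels 0.5, 1 and
    1.5 (log10 units) represent low, medium and high variability of the
    dynamic range across samples.
    """
    if max_level < 0:
        raise ValueError("max_level must be non-negative")
    rng = _rng(seed)
    data = cohort.with_nan()
    mask = cohort.missing_mask.copy()
    floors = np.nanmin(data, axis=0) + rng.uniform(0.0, max_level, size=cohort.n_samples)
    with np.errstate(invalid="ignore"):
        mask |= data < floors[None, :]
    return AbundanceMatrix(
        values=np.nan_to_num(data),
        missing_mask=mask,
        feature_ids=cohort.feature_ids,
        sample_ids=cohort.sample_ids,
    )


def half_min_impute(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace every missing cell with half the global observed minimum."""
    if matrix.missing_mask.all():
        raise ValueError("cannot impute an all-missing matrix")
    fill = 0.5 * matrix.values[~matrix.missing_mask].min()
    values = matrix.values.copy()
    values[matrix.missing_mask] = fill
    return AbundanceMatrix(
        values=values,
        missing_mask=np.zeros_like(matrix.missing_mask),
        feature_ids=matrix.feature_ids,
        sample_ids=matrix.sample_ids,
    )
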