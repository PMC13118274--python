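"""Feature-feature networks from correlations, and annotation partitioning.

A feature-feature correlation matrix is transformed to partial correlations
(each entry conditioned on all other features), the extreme tails of the
partial-correlation distribution become candidate edges, negative weights
are dropped, and the resulting positive-weight network is scored against
named feature sets (pathway-style annotations) with a modularity-like
partitioning ratio Q: networks whose strong edges stay inside annotation
sets score high, networks whose edges cross between sets score low (Q can
go below 0, and above 1 when annotations overlap).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .censorship import NotApplicableError

__all__ = [
    "AnnotationSets",
    "WeightedEdgeList",
    "PartialCorrelationResult",
    "PartitionResult",
    "partial_correlations",
    "select_edges",
    "partition_ratio",
]

logger = logging.getLogger(__name__)

# annotation id -> set of feature ids (features may belong to several)
AnnotationSets = Mapping[str, frozenset[str] | set[str]]


@dataclass(frozen=True)
class WeightedEdgeList:
    """Undirected positive-weight edges in canonical (a < b) order."""

    edges: pd.DataFrame  # columns: feature_a, feature_b, weight
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        e = self.edges
        if list(e.columns) != ["feature_a", "feature_b", "weight"]:
            raise ValueError("edges must have columns feature_a, feature_b, weight")
        if (e["feature_a"] == e["feature_b"]).any():
            raise ValueError("self-edges are not allowed")
        if (e["weight"] <= 0).any():
            raise ValueError("all retained edge weights must be positive")

    @property
    def total_weight(self) -> float:
        return float(self.edges["weight"].sum())


@dataclass(frozen=True)
class PartialCorrelationResult:
    """Partial-correlation matrix plus the shrinkage that produced it."""

    matrix: np.ndarray
    shrinkage: float


@dataclass(frozen=True)
class PartitionResult:
    """Per-annotation weight sums and the partitioning ratio Q."""

    per_annotation: pd.DataFrame  # columns: annotation, within_sum, outer_sum
    annotated_total: float
    q_ratio: float


def partial_correlations(
    corr: np.ndarray | pd.DataFrame,
    shrinkage: float | None = None,
    condition_target: float = 1e4,
) -> PartialCorrelationResult:
    """Partial correlations from a (possibly singular) correlation matrix.

    Returns p_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) with diagonal 1,
    where Omega is the inverse of the shrinkage-regularized matrix
    (1 - lambda) C + lambda I.  When features outnumber samples C is
    singular, so unless ``shrinkage`` is given, lambda is chosen as the
    smallest value in [0, 1) that caps the condition number of the shrunk
    matrix at ``condition_target`` (closed form from the extreme
    eigenvalues).  Undefined cells are imputed to 0 before inversion (with
    a log message).
    """
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.nan_to_num(C), np.nan_to_num(C.T)):
        raise ValueError("correlation matrix must be symmetric")
    C = C.copy()
    bad = np.isnan(C)
    if bad.any():
        logger.info("imputing %d undefined correlation cells to 0", int(bad.sum()))
        C[bad] = 0.0
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0

    eigval, eigvec = np.linalg.eigh(C)
    lo, hi = eigval[0], eigval[-1]
    if shrinkage is None:
        if lo > 0 and hi / lo <= condition_target:
            lam = 0.0
        else:
            # solve ((1-l)hi + l) / ((1-l)lo + l) = condition_target for l
            lam = (hi - condition_target * lo) / (hi - condition_target * lo + condition_target - 1.0)
            lam = float(np.clip(lam, 0.0, 1.0 - 1e-12))
    else:
        if not 0.0 <= shrinkage < 1.0:
            raise ValueError("shrinkage must be in [0, 1)")
        lam = float(shrinkage)
    inv_eig = 1.0 / ((1.0 - lam) * eigval + lam)
    omega = (eigvec * inv_eig) @ eigvec.T
    d = np.sqrt(np.diag(omega))
    pcorr = -omega / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    pcorr = (pcorr + pcorr.T) / 2.0
    return PartialCorrelationResult(matrix=pcorr, shrinkage=lam)


def select_edges(
    pcorr: np.ndarray | pd.DataFrame,
    node_ids: Sequence[str] | None = None,
    tail_fraction: float = 0.025,
) -> WeightedEdgeList:
    """Keep the distribution tails of the off-diagonal values as edges.

    Entries at or beyond the empirical ``tail_fraction`` and
    ``1 - tail_fraction`` quantiles of the off-diagonal distribution are
    selected (ties at a threshold are included, deterministically), then
    non-positive weights are dropped.  Edge weight = the partial
    correlation value.
    """
    if isinstance(pcorr, pd.DataFrame):
        if node_ids is None:
            node_ids = [str(c) for c in pcorr.columns]
        pcorr = pcorr.to_numpy(dtype=float)
    n = pcorr.shape[0]
    if node_ids is None:
        node_ids = [f"feature_{i}" for i in range(n)]
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    iu = np.triu_indices(n, 1)
    vals = pcorr[iu]
    finite = np.isfinite(vals)
    if finite.sum() < 1.0 / tail_fraction:
        warnings.warn(
            "fewer off-diagonal entries than 1/tail_fraction; quantiles are noisy",
            stacklevel=2,
        )
    lo = np.quantile(vals[finite], tail_fraction)
    hi = np.quantile(vals[finite], 1.0 - tail_fraction)
    keep = finite & ((vals <= lo) | (vals >= hi)) & (vals > 0)
    edges = pd.DataFrame(
        {
            "feature_a": [node_ids[i] for i in iu[0][keep]],
            "feature_b": [node_ids[j] for j in iu[1][keep]],
            "weight": vals[keep],
        }
    )
    # canonical a < b ordering
    swap = edges["feature_a"] > edges["feature_b"]
    edges.loc[swap, ["feature_a", "feature_b"]] = edges.loc[
        swap, ["feature_b", "feature_a"]
    ].to_numpy()
    return WeightedEdgeList(edges=edges, nodes=tuple(node_ids))


def partition_ratio(
    edges: WeightedEdgeList,
    annotations: AnnotationSets,
    count_both_directions: bool = True,
) -> PartitionResult:
    """Modularity-style partitioning ratio Q of a weighted network.

    With *annotated* = the summed weight of edges touching any annotated
    feature, and per annotation i: within_i = weight of edges with both
    endpoints in i; outer_i = weight of edges with one endpoint in i and
    the other in a different annotation (each crossing edge counts once
    from each side by default; ``count_both_directions=False`` counts it
    only from its canonical start node):

        Q = sum_i [ within_i / annotated - (outer_i / annotated)^2 ]

    Q is invariant to uniform rescaling of the weights.  For disjoint
    single-label annotations Q lies in [-2, 1]; overlapping annotation sets
    widen the range.
    """
    ann = {str(k): frozenset(v) for k, v in annotations.items()}
    if not ann or all(len(v) == 0 for v in ann.values()):
        raise ValueError("annotations must contain at least one nonempty set")
    universe = frozenset().union(*ann.values())
    e = edges.edges
    a_in = e["feature_a"].isin(universe).to_numpy()
    b_in = e["feature_b"].isin(universe).to_numpy()
    w = e["weight"].to_numpy(dtype=float)
    annotated = float(w[a_in | b_in].sum())
    if annotated == 0:
        raise NotApplicableError("no edge touches an annotated feature; Q is undefined")
    rows = []
    q = 0.0
    a_ids = e["feature_a"].to_numpy()
    b_ids = e["feature_b"].to_numpy()
    for name, members in ann.items():
        a_m = np.fromiter((x in members for x in a_ids), bool, len(a_ids))
        b_m = np.fromiter((x in members for x in b_ids), bool, len(b_ids))
        within = float(w[a_m & b_m].sum())
        cross_from_a = a_m & ~b_m & b_in
        cross_from_b = b_m & ~a_m & a_in
        if count_both_directions:
            outer = float(w[cross_from_a].sum() + w[cross_from_b].sum())
        else:
            outer = float(w[cross_from_a].sum())
        rows.append((name, within, outer))
        q += within / annotated - (outer / annotated) ** 2
    per_annotation = pd.DataFrame(rows, columns=["annotation", "within_sum", "outer_sum"])
    return PartitionResult(per_annotation=per_annotation, annotated_total=annotated, q_ratio=q)
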