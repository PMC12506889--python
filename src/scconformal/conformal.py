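"""Conformal prediction sets for cell-type annotation.

Given softmax scores from any :class:`~scconformal.classifiers.SoftmaxModel`,
this module computes non-conformity scores on the calibration cells at their
true labels, then, for each query cell and each candidate type, a conformal
p-value

    p_k = (1 + #{calibration scores in group(c_k) >= s(x, c_k)}) / (|group| + 1)

and the prediction set C(x) = {c_k : p_k >= alpha}, which covers the true
type with probability at least 1 - alpha under exchangeability.

Three non-conformity functions are supported:

* THR — 1 minus the softmax score of the candidate class; efficient sets but
  may return empty sets (a conformal rejection).
* APS — mass of classes ranked strictly above the candidate plus a uniform
  share u of the candidate's own mass (randomized; u := 1 gives the
  conservative deterministic variant).
* RAPS — APS plus a rank penalty eta * (rank - kappa)+ discouraging deep,
  noisy sets.

Calibration pools ("taxonomies"):

* standard — one pool; marginal coverage.
* classwise — one pool per class (Mondrian); class-conditional coverage,
  valuable under class imbalance but unstable for very rare classes.
* cluster — k-means on quantile embeddings of the per-class score
  distributions groups similar classes into shared pools; a compromise
  between the two.  Classes with too few calibration scores fall into a
  null cluster calibrated marginally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "NonconformityConfig", "TaxonomyConfig", "ConformalCalibrator",
    "PredictionSetResult", "score_thr", "score_aps", "score_raps",
    "nonconformity_matrix", "calibrate", "cluster_classes",
    "pvalue_matrix", "predict_sets", "force_label",
]

NULL_CLUSTER = -1


@dataclass
class NonconformityConfig:
    """Which non-conformity score to use and its knobs.

    ``eta`` (regularization weight) and ``kappa`` (rank offset) apply to RAPS
    only; ``randomized`` controls the uniform u term of APS/RAPS.
    """

    kind: str = "THR"  # THR | APS | RAPS
    eta: float = 0.01
    kappa: int = 1
    randomized: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("THR", "APS", "RAPS"):
            raise ValueError(f"unknown non-conformity kind {self.kind!r}")
        if self.eta < 0 or self.kappa < 0:
            raise ValueError("eta and kappa must be non-negative")


@dataclass
class TaxonomyConfig:
    """Calibration-pool taxonomy: standard, classwise, or cluster."""

    kind: str = "standard"  # standard | classwise | cluster
    n_clusters: Optional[int] = None
    cluster_quantiles: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9)
    min_class_cal: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "classwise", "cluster"):
            raise ValueError(f"unknown taxonomy kind {self.kind!r}")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        q = np.asarray(self.cluster_quantiles, dtype=float)
        if np.any(q <= 0) or np.any(q >= 1) or np.any(np.diff(q) <= 0):
            raise ValueError("cluster_quantiles must be strictly increasing in (0,1)")


# ---------------------------------------------------------------------------
# Non-conformity scores
# ---------------------------------------------------------------------------

def _check_simplex(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 1:
        probs = probs[None, :]
    if probs.size and (np.any(probs < -1e-9)
                       or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6)):
        raise ValueError("probability rows must lie on the simplex")
    return probs


def _ranks_desc(probs: np.ndarray) -> np.ndarray:
    """0-based rank of every class under descending softmax score, ties
    broken stably by class index."""
    order = np.argsort(-probs, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(probs.shape[0])[:, None]
    ranks[rows, order] = np.arange(probs.shape[1])[None, :]
    return ranks


def _aps_matrix(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
    """APS score of every (cell, candidate class) pair with one shared u per
    cell: mass strictly above the candidate plus u times its own mass."""
    order = np.argsort(-probs, axis=1, kind="stable")
    rows = np.arange(probs.shape[0])[:, None]
    sorted_probs = probs[rows, order]
    cum_above_sorted = np.cumsum(sorted_probs, axis=1) - sorted_probs
    cum_above = np.empty_like(probs)
    cum_above[rows, order] = cum_above_sorted
    return cum_above + u[:, None] * probs


def score_thr(prob_row: np.ndarray, class_index: int) -> float:
    """Threshold non-conformity: 1 - softmax score of the candidate class."""
    probs = _check_simplex(prob_row)
    return float(1.0 - probs[0, class_index])


def score_aps(prob_row: np.ndarray, class_index: int, u: float) -> float:
    """Adaptive non-conformity: cumulative mass of strictly higher-ranked
    classes plus ``u`` times the candidate's own mass."""
    probs = _check_simplex(prob_row)
    return float(_aps_matrix(probs, np.asarray([u]))[0, class_index])


def score_raps(prob_row: np.ndarray, class_index: int, u: float,
               eta: float = 0.01, kappa: int = 1) -> float:
    """Regularized APS: APS plus eta * (rank - kappa)+ with 1-based rank."""
    probs = _check_simplex(prob_row)
    aps = _aps_matrix(probs, np.asarray([u]))[0, class_index]
    rank = int(_ranks_desc(probs)[0, class_index]) + 1
    return float(aps + eta * max(0, rank - kappa))


def nonconformity_matrix(probs: np.ndarray, nc: NonconformityConfig,
                         u: Optional[np.ndarray] = None) -> np.ndarray:
    """Scores of every (cell, candidate class) pair under ``nc``.

    ``u`` holds one uniform draw per cell (shared across candidate classes);
    ignored for THR, replaced by 1 when ``nc.randomized`` is false.
    """
    probs = _check_simplex(probs)
    n, K = probs.shape
    if nc.kind == "THR":
        return 1.0 - probs
    if u is None or not nc.randomized:
        u = np.ones(n)
    u = np.asarray(u, dtype=float)
    S = _aps_matrix(probs, u)
    if nc.kind == "RAPS":
        S = S + nc.eta * np.maximum(0, _ranks_desc(probs) + 1 - nc.kappa)
    return S


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class ConformalCalibrator:
    """Per-group sorted calibration scores plus the class -> group map."""

    nc: NonconformityConfig
    tax: TaxonomyConfig
    label_space: List[str]
    group_of_class: np.ndarray         # group id per class index
    group_scores: Dict[int, np.ndarray]  # group id -> sorted score array

    def __post_init__(self) -> None:
        for g, s in self.group_scores.items():
            if len(s) == 0:
                raise ValueError(f"calibration group {g} is empty")


def calibrate(probs_cal: np.ndarray, labels_cal: Sequence[str],
              nc: NonconformityConfig, tax: TaxonomyConfig,
              label_space: Optional[List[str]] = None) -> ConformalCalibrator:
    """Build the calibrator from calibration softmax scores and true labels.

    Each calibration cell contributes its non-conformity score at its TRUE
    class; scores are then pooled by taxonomy.  For APS/RAPS with
    ``randomized=True`` one uniform u is drawn per calibration cell
    (seeded by ``nc.seed``).
    """
    probs_cal = _check_simplex(probs_cal)
    labels_cal = np.asarray(labels_cal, dtype=object)
    if label_space is None:
        label_space = sorted(set(labels_cal))
    if probs_cal.shape[1] != len(label_space):
        raise ValueError("probability columns do not match the label space")
    class_index = {c: k for k, c in enumerate(label_space)}
    unknown = set(labels_cal) - set(label_space)
    if unknown:
        raise ValueError(f"calibration labels outside label space: {sorted(unknown)}")
    y_idx = np.array([class_index[c] for c in labels_cal])

    rng = np.random.default_rng(nc.seed)
    u = rng.uniform(size=len(labels_cal)) if nc.randomized else None
    S = nonconformity_matrix(probs_cal, nc, u)
    true_scores = S[np.arange(len(y_idx)), y_idx]

    K = len(label_space)
    counts = np.bincount(y_idx, minlength=K)
    scores_by_class = {k: true_scores[y_idx == k] for k in range(K)}

    if tax.kind == "standard":
        group_of_class = np.zeros(K, dtype=int)
    elif tax.kind == "classwise":
        thin = [label_space[k] for k in range(K) if counts[k] < 2]
        if thin:
            raise ValueError(
                f"classwise taxonomy needs >= 2 calibration cells per class; "
                f"too few for {thin}")
        unstable = [label_space[k] for k in range(K) if counts[k] < tax.min_class_cal]
        if unstable:
            warnings.warn(
                f"classwise calibration may be unstable for rare classes "
                f"(< {tax.min_class_cal} calibration cells): {unstable}")
        group_of_class = np.arange(K, dtype=int)
    else:  # cluster
        assignment = cluster_classes(
            {label_space[k]: scores_by_class[k] for k in range(K)}, tax)
        group_of_class = np.array([assignment[c] for c in label_space], dtype=int)

    group_scores: Dict[int, np.ndarray] = {}
    for g in np.unique(group_of_class):
        if g == NULL_CLUSTER:
            # null cluster: rare classes calibrated marginally over all scores
            pooled = true_scores
        else:
            members = np.isin(y_idx, np.flatnonzero(group_of_class == g))
            pooled = true_scores[members]
        group_scores[int(g)] = np.sort(pooled)
    return ConformalCalibrator(nc=nc, tax=tax, label_space=list(label_space),
                               group_of_class=group_of_class,
                               group_scores=group_scores)


def cluster_classes(scores_by_class: Dict[str, np.ndarray],
                    tax: TaxonomyConfig) -> Dict[str, int]:
    """Group classes with similar score distributions by k-means on their
    quantile embeddings.

    Each class with at least ``tax.min_class_cal`` calibration scores is
    embedded as the vector of its score quantiles at
    ``tax.cluster_quantiles``; k-means (seeded) with
    ``tax.n_clusters`` clusters (default: one cluster per four embeddable
    classes) partitions the embeddings.  Classes below the threshold map to
    the null cluster, which is calibrated marginally.
    """
    names = sorted(scores_by_class)
    embeddable = [c for c in names if len(scores_by_class[c]) >= tax.min_class_cal]
    n_emb = len(embeddable)
    if n_emb == 0:
        return {c: NULL_CLUSTER for c in names}
    n_clusters = tax.n_clusters if tax.n_clusters is not None else max(1, n_emb // 4)
    if n_clusters > n_emb:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds the {n_emb} embeddable classes")
    q = np.asarray(tax.cluster_quantiles, dtype=float)
    emb = np.vstack([np.quantile(scores_by_class[c], q) for c in embeddable])
    km = KMeans(n_clusters=n_clusters, random_state=tax.seed, n_init=10)
    cluster_ids = km.fit_predict(emb)
    assignment = {c: NULL_CLUSTER for c in names}
    assignment.update({c: int(g) for c, g in zip(embeddable, cluster_ids)})
    return assignment


# ---------------------------------------------------------------------------
# Prediction sets
# ---------------------------------------------------------------------------

@dataclass
class PredictionSetResult:
    """Per-query-cell label sets and per-class conformal p-values."""

    label_space: List[str]
    pvalues: np.ndarray        # (n_cells, K), entries in (0, 1]
    set_mask: np.ndarray       # (n_cells, K) boolean, p >= alpha
    alpha: float
    probs: np.ndarray          # softmax scores used (for tie-breaking)

    @property
    def set_sizes(self) -> np.ndarray:
        return self.set_mask.sum(axis=1)

    @property
    def empty_mask(self) -> np.ndarray:
        """Empty sets are conformal rejections: no type meets the
        confidence requirement."""
        return self.set_sizes == 0

    def sets(self) -> List[List[str]]:
        return [[self.label_space[k] for k in np.flatnonzero(row)]
                for row in self.set_mask]


def pvalue_matrix(calibrator: ConformalCalibrator, probs_query: np.ndarray,
                  seed: Optional[int] = None) -> np.ndarray:
    """Per-cell per-class conformal p-values.

    Each query cell's score is recomputed as if its label were each candidate
    class in turn and ranked among that class's calibration group; APS/RAPS
    draw ONE u per query cell, shared across candidate classes, so the score
    profile across classes stays internally consistent.
    """
    probs_query = _check_simplex(probs_query)
    n, K = probs_query.shape
    if K != len(calibrator.label_space):
        raise ValueError("probability columns do not match the calibrator")
    rng = np.random.default_rng(calibrator.nc.seed if seed is None else seed)
    u = rng.uniform(size=n) if calibrator.nc.randomized else None
    S = nonconformity_matrix(probs_query, calibrator.nc, u)
    P = np.empty_like(S)
    for k in range(K):
        g = int(calibrator.group_of_class[k])
        cal = calibrator.group_scores[g]
        m = len(cal)
        count_ge = m - np.searchsorted(cal, S[:, k], side="left")
        P[:, k] = (1.0 + count_ge) / (m + 1.0)
    return P


def predict_sets(calibrator: ConformalCalibrator, probs_query: np.ndarray,
                 alpha: float, seed: Optional[int] = None) -> PredictionSetResult:
    """Prediction sets C(x) = {c_k : p_k >= alpha}.

    Nested in alpha: a smaller alpha can only enlarge every set.  Empty sets
    are permitted and flagged as rejections.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0,1]")
    probs_query = _check_simplex(probs_query)
    P = pvalue_matrix(calibrator, probs_query, seed=seed)
    return PredictionSetResult(label_space=list(calibrator.label_space),
                               pvalues=P, set_mask=P >= alpha, alpha=alpha,
                               probs=probs_query)


def force_label(result: PredictionSetResult):
    """Collapse each set to the single type with the highest p-value.

    Ties break by higher softmax score, then class order.  Cells whose set
    was empty still receive the argmax label but are flagged
    (``forced_under_rejection``).
    """
    n, K = result.pvalues.shape
    # lexsort keys (last = primary): p-value desc, softmax desc, class index asc
    choice = np.empty(n, dtype=int)
    for i in range(n):
        order = np.lexsort((np.arange(K), -result.probs[i], -result.pvalues[i]))
        choice[i] = order[0]
    labels = np.asarray([result.label_space[k] for k in choice], dtype=object)
    return labels, result.empty_mask.copy()
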