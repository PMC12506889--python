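"""Conformal out-of-distribution (novel cell type) detection.

A query cell whose true type is absent from the reference label space breaks
the exchangeability assumption behind conformal prediction sets, so such
cells must be removed before annotation.  Detection is framed as a hypothesis
test of "this cell was drawn from the reference distribution": an
autoencoder trained on the proper training set supplies an anomaly score
(mean squared reconstruction error), and the calibration set turns the score
into a conformal p-value

    p = (1 + #{calibration scores >= s}) / (n_cal + 1),

which is super-uniform under the null.  Thresholding p <= alpha_o therefore
controls the expected false positive rate at alpha_o, regardless of the
autoencoder's quality; the autoencoder only determines power.

The same p-values double as an exchangeability diagnostic: under
exchangeability they are uniform on (0, 1], and any low-p excess signals
OOD cells, batch effects, or other covariate shift.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats
from sklearn.neural_network import MLPRegressor

from .datamodel import CPM_LOG2, CellDataset

__all__ = [
    "AutoencoderConfig", "AutoencoderModel", "AnomalyCalibration",
    "DetectorDecision", "fit_autoencoder", "reconstruction_scores",
    "calibrate_detector", "conformal_pvalue", "select_alpha_o", "flag_ood",
    "exchangeability_diagnostic",
]


@dataclass
class AutoencoderConfig:
    """Symmetric autoencoder hyperparameters.

    ``hidden`` is the encoder's intermediate width and ``latent`` the
    bottleneck dimension q (must satisfy q < number of genes); the decoder
    mirrors the encoder.  Adam, lr 1e-3, at most 300 epochs with patience 15
    on validation reconstruction MSE.
    """

    hidden: int = 128
    latent: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 300
    patience: int = 15
    l2: float = 1e-4
    seed: int = 0


@dataclass
class AutoencoderModel:
    backend: MLPRegressor
    gene_ids: np.ndarray
    config: AutoencoderConfig
    # per-gene standardization fitted on the training pool; the network works
    # in standardized space, scores are computed in the original units
    feat_mean: np.ndarray = None
    feat_sd: np.ndarray = None
    fitted: bool = True
    history: dict = field(default_factory=dict)


@dataclass
class AnomalyCalibration:
    """Sorted calibration anomaly scores — the detector's null reference."""

    scores: np.ndarray
    n_cal: int = 0

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        self.n_cal = len(self.scores)
        if self.n_cal < 1:
            raise ValueError("calibration requires at least one score")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("calibration scores must be finite and non-negative")


@dataclass
class DetectorDecision:
    pvalues: np.ndarray
    alpha_o: float
    flags: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(self.flags, self.pvalues <= self.alpha_o):
            raise ValueError("flags must equal (pvalue <= alpha_o)")


def fit_autoencoder(train: CellDataset, val: CellDataset,
                    config: AutoencoderConfig = AutoencoderConfig()) -> AutoencoderModel:
    """Train the reconstruction autoencoder on in-distribution cells only.

    Held-out (OOD) classes must have been removed upstream — the training
    pool must be clean of outliers for reconstruction error to rank them as
    anomalous.  Early stopping tracks validation MSE; deterministic given
    ``config.seed``.
    """
    p = train.n_genes
    if config.latent >= p:
        raise ValueError(f"latent dim q={config.latent} must be < n_genes p={p}")
    if train.layer_state != CPM_LOG2:
        raise ValueError("autoencoder expects cpm_log2 data")
    net = MLPRegressor(
        hidden_layer_sizes=(config.hidden, config.latent, config.hidden),
        activation="relu",
        solver="adam",
        alpha=config.l2,
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size,
        random_state=config.seed,
        max_iter=1,
    )
    rng = np.random.default_rng(config.seed)
    mean = train.matrix.mean(axis=0)
    sd = train.matrix.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = (train.matrix - mean) / sd
    Xval = (val.matrix - mean) / sd
    n = len(X)
    best, best_state, since_best = np.inf, None, 0
    hist = {"train_mse": [], "val_mse": []}
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            net.batch_size = len(sel)
            net.partial_fit(X[sel], X[sel])
        train_mse = float(np.mean((net.predict(X) - X) ** 2))
        val_mse = float(np.mean((net.predict(Xval) - Xval) ** 2))
        hist["train_mse"].append(train_mse)
        hist["val_mse"].append(val_mse)
        if val_mse < best - 1e-10:
            best, since_best = val_mse, 0
            best_state = (copy.deepcopy(net.coefs_), copy.deepcopy(net.intercepts_))
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        net.coefs_, net.intercepts_ = best_state
    return AutoencoderModel(backend=net, gene_ids=train.gene_ids,
                            config=config, feat_mean=mean, feat_sd=sd,
                            history=hist)


def reconstruction_scores(model: AutoencoderModel, cells: CellDataset) -> np.ndarray:
    """Per-cell anomaly score: mean squared reconstruction error (>= 0)."""
    if cells.n_cells == 0:
        return np.zeros(0)
    if list(cells.gene_ids) != list(model.gene_ids):
        raise ValueError("gene space differs from the autoencoder's training genes")
    Z = (cells.matrix - model.feat_mean) / model.feat_sd
    recon = model.backend.predict(Z) * model.feat_sd + model.feat_mean
    return np.mean((recon - cells.matrix) ** 2, axis=1)


def calibrate_detector(model: AutoencoderModel, cal: CellDataset) -> AnomalyCalibration:
    return AnomalyCalibration(scores=reconstruction_scores(model, cal))


def conformal_pvalue(calib: AnomalyCalibration, s_new) -> np.ndarray:
    """Conformal p-value(s) for new anomaly score(s).

    p = (1 + #{i : s_i >= s_new}) / (n_cal + 1), ties counted with >= ;
    always in (0, 1].  Accepts a scalar or an array (vectorized via binary
    search on the sorted calibration scores).
    """
    s = np.atleast_1d(np.asarray(s_new, dtype=float))
    if not np.all(np.isfinite(s)):
        raise ValueError("anomaly scores must be finite")
    n = calib.n_cal
    count_ge = n - np.searchsorted(calib.scores, s, side="left")
    p = (1.0 + count_ge) / (n + 1.0)
    return p if np.ndim(s_new) else float(p[0])


def select_alpha_o(pvalues: np.ndarray, method: str = "fixed",
                   fixed_value: Optional[float] = 0.15,
                   grid: Optional[np.ndarray] = None,
                   purity_target: float = 0.5) -> float:
    """Choose the detector's decision threshold alpha_o.

    ``fixed`` returns ``fixed_value`` (the fallback used when sample sizes
    are too small for data-driven selection).  ``auto`` is an excess-mass
    heuristic: under pure exchangeability the p-value CDF is F(t) <= t, so
    e(t) = max(0, F_hat(t) - t) estimates the mass of anomalous cells below
    t.  The threshold returned is the largest grid point at which the excess
    accounts for at least ``purity_target`` of the flagged mass
    (e(t)/F_hat(t) >= purity_target), falling back to the grid minimum when
    no point qualifies — i.e. flag only where low p-values are enriched
    beyond the uniform baseline.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any(pvalues <= 0) or np.any(pvalues > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        return float(fixed_value)
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if grid is None:
        grid = np.arange(0.01, 0.51, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alpha_o grid is empty")
    grid = np.sort(grid)
    best = float(grid[0])
    for t in grid:
        F = np.mean(pvalues <= t)
        if F <= 0:
            continue
        excess = max(0.0, F - t)
        if excess / F >= purity_target:
            best = max(best, float(t))
    return best


def flag_ood(calib: AnomalyCalibration, scores: np.ndarray,
             alpha_o: float) -> DetectorDecision:
    """Flag cells with conformal p-value <= alpha_o as out-of-distribution.

    The expected fraction of in-distribution cells flagged is bounded by
    alpha_o under exchangeability.  Flagged cells are meant to be excluded
    from downstream annotation.
    """
    if not (0.0 <= alpha_o <= 1.0):
        raise ValueError("alpha_o must lie in [0,1]")
    p = conformal_pvalue(calib, np.asarray(scores, dtype=float))
    p = np.atleast_1d(p)
    return DetectorDecision(pvalues=p, alpha_o=alpha_o, flags=p <= alpha_o)


@dataclass
class ExchangeabilityReport:
    ks_statistic: float
    ks_pvalue: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    max_excess_mass: float


def exchangeability_diagnostic(pvalues: np.ndarray,
                               n_bins: int = 10) -> ExchangeabilityReport:
    """Diagnose departures of detector p-values from uniformity.

    Under exchangeability the conformal p-values are (discretely) uniform;
    a Kolmogorov-Smirnov statistic against U[0,1], a histogram, and the
    maximal excess mass sup_t max(0, F_hat(t) - t) summarize any violation.
    Purely diagnostic — decisions are never altered.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("no p-values supplied")
    ks = stats.kstest(pvalues, "uniform")
    counts, edges = np.histogram(pvalues, bins=n_bins, range=(0.0, 1.0))
    tgrid = np.linspace(0.01, 0.99, 99)
    Fhat = np.searchsorted(np.sort(pvalues), tgrid, side="right") / pvalues.size
    excess = float(np.max(np.maximum(0.0, Fhat - tgrid)))
    return ExchangeabilityReport(
        ks_statistic=float(ks.statistic), ks_pvalue=float(ks.pvalue),
        histogram_counts=counts, histogram_edges=edges,
        max_excess_mass=excess,
    )
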