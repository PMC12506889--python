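"""Metrics and the leave-one-cell-type-out (LOCO) evaluation harness.

Annotation quality is summarized by empirical coverage (fraction of query
cells whose true type lies in the prediction set), the class coverage gap
(mean absolute deviation of per-class coverage from the nominal 1 - alpha),
and the average prediction-set size.  The detector is summarized by
power / FPR / FDR against OOD ground truth.

The LOCO harness removes designated cell types from the reference while
keeping them in the query as OOD truth, then runs the full pipeline —
normalize, split, fit classifier and autoencoder, flag OOD, annotate the
unflagged cells — once per seed.  Flagged cells receive no prediction set
and are excluded from the coverage/size denominators; OOD cells that evade
the detector count as uncovered (their type is not in the label space),
which is exactly how undetected novelty erodes the coverage guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import ood as oodmod
from .conformal import (NonconformityConfig, PredictionSetResult,
                        TaxonomyConfig, calibrate, predict_sets)
from .datamodel import CellDataset, make_splits
from .preprocessing import normalize_cpm_log2

__all__ = ["MetricsReport", "ExperimentConfig", "coverage", "covgap",
           "avg_set_size", "detector_metrics", "run_loco_experiment",
           "reports_to_frame"]


@dataclass
class MetricsReport:
    coverage: float
    covgap: float
    avg_set_size: float
    per_class_coverage: Dict[str, float]
    power: float
    fpr: float
    fdr: float
    n_query: int
    alpha: float
    alpha_o: Optional[float]
    nc_kind: str
    taxonomy: str
    seed: int


def coverage(sets: PredictionSetResult, truth: Sequence[str]) -> float:
    """Fraction of query cells whose true label lies in their set.  Labels
    outside the calibrated label space can never be covered."""
    truth = np.asarray(truth, dtype=object)
    if len(truth) != sets.set_mask.shape[0]:
        raise ValueError("truth length does not match the prediction sets")
    index = {c: k for k, c in enumerate(sets.label_space)}
    hit = np.zeros(len(truth), dtype=bool)
    for i, y in enumerate(truth):
        k = index.get(y)
        hit[i] = bool(sets.set_mask[i, k]) if k is not None else False
    return float(hit.mean()) if len(truth) else 0.0


def per_class_coverage(sets: PredictionSetResult,
                       truth: Sequence[str]) -> Dict[str, float]:
    truth = np.asarray(truth, dtype=object)
    out = {}
    index = {c: k for k, c in enumerate(sets.label_space)}
    for c in sets.label_space:
        members = np.flatnonzero(truth == c)
        if len(members):
            out[c] = float(sets.set_mask[members, index[c]].mean())
    return out


def covgap(sets: PredictionSetResult, truth: Sequence[str], alpha: float) -> float:
    """Mean over classes of |per-class coverage - (1 - alpha)|; classes
    absent from the query are excluded with a warning."""
    pcc = per_class_coverage(sets, truth)
    absent = sorted(set(sets.label_space) - set(pcc))
    if absent:
        warnings.warn(f"classes absent from query excluded from covgap: {absent}")
    if not pcc:
        raise ValueError("no query cells belong to any calibrated class")
    return float(np.mean([abs(v - (1.0 - alpha)) for v in pcc.values()]))


def avg_set_size(sets: PredictionSetResult) -> float:
    if sets.set_mask.shape[0] == 0:
        raise ValueError("no query cells: average set size undefined")
    return float(sets.set_sizes.mean())


def detector_metrics(flags: np.ndarray, truth_ood: np.ndarray) -> Tuple[float, float, float]:
    """(power, FPR, FDR) of the OOD flags against ground truth.

    power = flagged OOD / OOD; FPR = flagged ID / ID; FDR = flagged ID /
    flagged.  Degenerate denominators yield 0 by convention.
    """
    flags = np.asarray(flags, dtype=bool)
    truth_ood = np.asarray(truth_ood, dtype=bool)
    if flags.shape != truth_ood.shape:
        raise ValueError("flags and truth must have equal length")
    n_ood = int(truth_ood.sum())
    n_id = int((~truth_ood).sum())
    n_flag = int(flags.sum())
    tp = int((flags & truth_ood).sum())
    fp = int((flags & ~truth_ood).sum())
    power = tp / n_ood if n_ood else 0.0
    fpr = fp / n_id if n_id else 0.0
    fdr = fp / n_flag if n_flag else 0.0
    return float(power), float(fpr), float(fdr)


@dataclass
class ExperimentConfig:
    """One LOCO pipeline configuration (the per-seed randomness lives in the
    split and model seeds derived from each run's seed)."""

    alpha: float = 0.1
    nc: NonconformityConfig = field(default_factory=NonconformityConfig)
    tax: TaxonomyConfig = field(default_factory=TaxonomyConfig)
    classifier: str = "multinomial_logistic"  # or "mlp"
    mlp_config: Optional[clf.TrainingConfig] = None
    detector: bool = True
    ae_config: Optional[oodmod.AutoencoderConfig] = None
    alpha_o: Optional[float] = 0.1            # None -> automatic selection
    test_frac: float = 0.10
    val_frac: float = 0.15
    cal_frac_of_train: float = 0.40


def _fit_classifier(train: CellDataset, val: CellDataset,
                    config: ExperimentConfig, seed: int) -> clf.SoftmaxModel:
    if config.classifier == "mlp":
        mcfg = config.mlp_config or clf.TrainingConfig()
        mcfg = clf.TrainingConfig(**{**mcfg.__dict__, "seed": seed})
        return clf.fit_mlp(train, val, mcfg)
    return clf.fit_baseline(train, kind=config.classifier)


def run_single(ref: CellDataset, query: CellDataset,
               heldout_types: Sequence[str], config: ExperimentConfig,
               seed: int) -> MetricsReport:
    """One pass of the LOCO pipeline at one seed."""
    heldout = set(heldout_types)
    if ref.labels is None or query.labels is None:
        raise ValueError("reference and query must carry labels for evaluation")
    missing = heldout - set(ref.labels)
    if missing:
        raise ValueError(f"held-out types absent from reference: {sorted(missing)}")
    if heldout - set(query.labels):
        warnings.warn("held-out type absent from query: no OOD truth to measure")

    keep = np.flatnonzero(~np.isin(ref.labels, list(heldout)))
    ref_id = ref.subset_cells(keep)
    if ref_id.layer_state == "raw_counts":
        ref_id = normalize_cpm_log2(ref_id)
    if query.layer_state == "raw_counts":
        query_n = normalize_cpm_log2(query)
    else:
        query_n = query

    plan = make_splits(ref_id, config.test_frac, config.val_frac,
                       config.cal_frac_of_train, seed=seed)
    train = ref_id.subset_cells(plan.train_idx)
    val = ref_id.subset_cells(plan.val_idx)
    cal = ref_id.subset_cells(plan.cal_idx)

    model = _fit_classifier(train, val, config, seed)

    truth_ood = ~np.isin(query_n.labels, model.label_space)
    alpha_o_used = None
    if config.detector:
        ae_cfg = config.ae_config or oodmod.AutoencoderConfig()
        ae_cfg = oodmod.AutoencoderConfig(**{**ae_cfg.__dict__, "seed": seed})
        ae = oodmod.fit_autoencoder(train, val, ae_cfg)
        det_cal = oodmod.calibrate_detector(ae, cal)
        scores = oodmod.reconstruction_scores(ae, query_n)
        pvals = oodmod.conformal_pvalue(det_cal, scores)
        if config.alpha_o is None:
            alpha_o_used = oodmod.select_alpha_o(pvals, method="auto")
        else:
            alpha_o_used = float(config.alpha_o)
        decision = oodmod.flag_ood(det_cal, scores, alpha_o_used)
        flags = decision.flags
    else:
        flags = np.zeros(query_n.n_cells, dtype=bool)

    power, fpr, fdr = detector_metrics(flags, truth_ood)

    unflagged = np.flatnonzero(~flags)
    annotate = query_n.subset_cells(unflagged)
    probs_cal = clf.predict_proba(model, cal)
    nc = NonconformityConfig(**{**config.nc.__dict__, "seed": seed})
    tax = TaxonomyConfig(**{**config.tax.__dict__, "seed": seed})
    calibrator = calibrate(probs_cal, cal.labels, nc, tax,
                           label_space=model.label_space)
    probs_query = clf.predict_proba(model, annotate)
    sets = predict_sets(calibrator, probs_query, config.alpha, seed=seed + 1)

    truth_unflagged = np.asarray(annotate.labels, dtype=object)
    cov = coverage(sets, truth_unflagged)
    id_mask = np.isin(truth_unflagged, model.label_space)
    # OOD labels are outside the label space, so they never enter per-class terms
    gap = covgap(sets, truth_unflagged, config.alpha) \
        if id_mask.any() else float("nan")
    size = avg_set_size(sets) if len(unflagged) else float("nan")
    pcc = per_class_coverage(sets, truth_unflagged)
    return MetricsReport(
        coverage=cov, covgap=gap, avg_set_size=size, per_class_coverage=pcc,
        power=power, fpr=fpr, fdr=fdr, n_query=len(unflagged),
        alpha=config.alpha, alpha_o=alpha_o_used, nc_kind=config.nc.kind,
        taxonomy=config.tax.kind, seed=seed)


def run_loco_experiment(ref: CellDataset, query: CellDataset,
                        heldout_types: Sequence[str],
                        config: ExperimentConfig = ExperimentConfig(),
                        n_seeds: int = 20,
                        base_seed: int = 0) -> List[MetricsReport]:
    """Repeat the LOCO pipeline over ``n_seeds`` seeds (splits and model
    seeds re-randomized, data held fixed) and return one report per seed."""
    return [run_single(ref, query, heldout_types, config, seed=base_seed + s)
            for s in range(n_seeds)]


def reports_to_frame(reports: List[MetricsReport]) -> pd.DataFrame:
    """Tidy long-format table, one row per seed."""
    rows = []
    for r in reports:
        d = {k: v for k, v in r.__dict__.items() if k != "per_class_coverage"}
        rows.append(d)
    return pd.DataFrame(rows)
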