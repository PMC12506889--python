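"""Negative-binomial scRNA-seq simulator with known ground truth.

Every distribution-free guarantee the package makes (coverage, detector FPR,
power) is exercised on data from this module, so the generator states its
world explicitly: cells of class c have NB counts with per-gene mean
``baseline_mean`` boosted by ``signature_fold`` on that class's signature
genes, a single global NB dispersion, an optional per-gene multiplicative
log-normal batch shift applied to query means only, and optional
out-of-distribution classes present in the query but absent from the
reference.  Counts are deterministic given the seed.

Defaults emulate a small, well-separated atlas: 5 cell types with disjoint
20-gene signatures (fold change 5) over 300 genes, 600 reference and 400
query cells per type — uniform class proportions so that reference and query
are exchangeable by construction when no shift and no OOD class is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .datamodel import CellDataset

__all__ = ["ClassSpec", "SimulationConfig", "default_config", "loco_config",
           "generate_pair", "make_imbalanced_fixture"]


@dataclass
class ClassSpec:
    name: str
    n_ref: int
    n_query: int
    signature_genes: Sequence[int]
    signature_fold: float = 5.0


@dataclass
class SimulationConfig:
    n_genes: int = 300
    classes: List[ClassSpec] = field(default_factory=list)
    baseline_mean: float = 1.0
    nb_dispersion: float = 2.0       # NB shape theta: var = mu + mu^2/theta
    batch_shift_sd: float = 0.0      # per-gene log-normal shift on query means
    ood_classes: Tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("n_genes, baseline_mean, nb_dispersion must be positive")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        for c in self.classes:
            idx = np.asarray(c.signature_genes, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_genes):
                raise ValueError(f"signature genes of {c.name!r} out of gene range")
            if c.signature_fold < 1:
                raise ValueError(f"signature_fold of {c.name!r} must be >= 1")
        unknown = set(self.ood_classes) - set(names)
        if unknown:
            raise ValueError(f"ood_classes not among classes: {sorted(unknown)}")


def default_config(seed: int = 0, n_query_per_class: int = 400,
                   n_ref_per_class: int = 600, batch_shift_sd: float = 0.0,
                   ood_classes: Tuple[str, ...] = ()) -> SimulationConfig:
    """The 5-class exchangeable fixture used throughout the test battery."""
    sig_size, n_genes = 20, 300
    classes = [
        ClassSpec(name=f"type_{i}", n_ref=n_ref_per_class,
                  n_query=n_query_per_class,
                  signature_genes=list(range(i * sig_size, (i + 1) * sig_size)),
                  signature_fold=5.0)
        for i in range(5)
    ]
    return SimulationConfig(n_genes=n_genes, classes=classes,
                            batch_shift_sd=batch_shift_sd,
                            ood_classes=ood_classes, seed=seed)


def loco_config(seed: int = 0, heldout: Tuple[str, ...] = ("type_4",),
                n_query_per_class: int = 400,
                n_ref_per_class: int = 600) -> SimulationConfig:
    """Leave-one-cell-type-out world: 5 symmetric classes with broad,
    clearly distinct 40-gene signatures (fold 5) and the held-out types
    marked OOD (absent from the reference, retained in the query).

    The wider signatures make a held-out type transcriptomically distinct
    enough for reconstruction error to separate it — the premise of the
    detector's power checks; symmetric signatures keep library sizes equal
    across classes so per-cell normalization does not mask the novelty.
    """
    sig_size, n_genes = 40, 300
    classes = [
        ClassSpec(name=f"type_{i}", n_ref=n_ref_per_class,
                  n_query=n_query_per_class,
                  signature_genes=list(range(i * sig_size, (i + 1) * sig_size)),
                  signature_fold=5.0)
        for i in range(5)
    ]
    return SimulationConfig(n_genes=n_genes, classes=classes,
                            ood_classes=tuple(heldout), seed=seed)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               theta: float) -> np.ndarray:
    # NB(mu, theta): var = mu + mu^2/theta
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p).astype(float)


def generate_pair(cfg: SimulationConfig):
    """Generate ``(reference, query)`` :class:`CellDataset` pairs.

    Reference excludes ``cfg.ood_classes``; the query includes them with
    truth labels retained (for evaluation only — a real query is unlabeled).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shift = np.exp(rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_genes)) \
        if cfg.batch_shift_sd > 0 else np.ones(cfg.n_genes)

    def class_mean(c: ClassSpec) -> np.ndarray:
        mu = np.full(cfg.n_genes, cfg.baseline_mean)
        idx = np.asarray(c.signature_genes, dtype=int)
        mu[idx] *= c.signature_fold
        return mu

    ref_rows, ref_labels = [], []
    query_rows, query_labels = [], []
    for c in cfg.classes:
        mu = class_mean(c)
        if c.name not in cfg.ood_classes and c.n_ref > 0:
            ref_rows.append(_nb_sample(rng, np.tile(mu, (c.n_ref, 1)),
                                       cfg.nb_dispersion))
            ref_labels += [c.name] * c.n_ref
        if c.n_query > 0:
            query_rows.append(_nb_sample(rng, np.tile(mu * shift, (c.n_query, 1)),
                                         cfg.nb_dispersion))
            query_labels += [c.name] * c.n_query
    if not ref_rows or not query_rows:
        raise ValueError("configuration generates an empty reference or query")

    genes = np.asarray([f"gene_{j}" for j in range(cfg.n_genes)], dtype=object)
    ref = CellDataset(
        matrix=np.vstack(ref_rows),
        cell_ids=np.asarray([f"ref_{i}" for i in range(len(ref_labels))], dtype=object),
        gene_ids=genes, labels=np.asarray(ref_labels, dtype=object))
    query = CellDataset(
        matrix=np.vstack(query_rows),
        cell_ids=np.asarray([f"query_{i}" for i in range(len(query_labels))], dtype=object),
        gene_ids=genes, labels=np.asarray(query_labels, dtype=object))
    return ref, query


def make_imbalanced_fixture(seed: int = 0):
    """Severely imbalanced atlas plus a query-only OOD class.

    Reference class sizes (2000, 1500, 1000, 300, 80) mimic the typical
    single-cell situation where major types have thousands of cells and a
    minority type a few dozen.  The 80-cell minority ("mast") additionally
    carries a weaker signature (fold 2.5) that overlaps the fourth class's
    signature — rare types are usually also the transcriptomically subtler
    ones — which is what makes a single marginal calibration pool undercover
    it while per-class (Mondrian) calibration does not.  The OOD class
    ("schwann") appears only in the query.
    """
    sig = 20
    classes = [
        ClassSpec("B_cell", 2000, 500, list(range(0, sig)), 5.0),
        ClassSpec("T_cell", 1500, 375, list(range(sig, 2 * sig)), 5.0),
        ClassSpec("NK_cell", 1000, 250, list(range(2 * sig, 3 * sig)), 5.0),
        ClassSpec("dendritic", 300, 150, list(range(3 * sig, 4 * sig)), 5.0),
        # minority: weak signature, half shared with dendritic
        ClassSpec("mast", 80, 100,
                  list(range(3 * sig + 10, 4 * sig)) + list(range(4 * sig, 4 * sig + 10)),
                  2.5),
        ClassSpec("schwann", 0, 150, list(range(5 * sig, 6 * sig)), 6.0),
    ]
    cfg = SimulationConfig(n_genes=300, classes=classes,
                           ood_classes=("schwann",), seed=seed)
    return generate_pair(cfg)
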