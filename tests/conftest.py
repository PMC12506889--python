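"""Shared fixtures: small synthetic worlds and a fitted baseline pipeline."""

import numpy as np
import pytest

import scconformal as sc


@pytest.fixture(scope="session")
def small_pair():
    """Small exchangeable 5-class reference/query pair, raw counts."""
    return sc.generate_pair(sc.default_config(
        seed=11, n_ref_per_class=150, n_query_per_class=100))


@pytest.fixture(scope="session")
def small_pipeline(small_pair):
    """Normalized pair + split plan + fitted logistic baseline + softmax
    scores on calibration and query cells."""
    ref, query = small_pair
    refn = sc.normalize_cpm_log2(ref)
    qn = sc.normalize_cpm_log2(query)
    plan = sc.make_splits(refn, seed=3)
    train = refn.subset_cells(plan.train_idx)
    cal = refn.subset_cells(plan.cal_idx)
    model = sc.fit_baseline(train)
    return {
        "refn": refn, "qn": qn, "plan": plan, "train": train, "cal": cal,
        "model": model,
        "probs_cal": sc.predict_proba(model, cal),
        "probs_query": sc.predict_proba(model, qn),
    }


@pytest.fixture
def tiny_dataset():
    """3 cells x 4 genes, two classes, hand-enumerable."""
    return sc.CellDataset(
        matrix=np.array([[1.0, 0.0, 2.0, 3.0],
                         [0.0, 1.0, 1.0, 0.0],
                         [4.0, 2.0, 0.0, 1.0]]),
        cell_ids=np.array(["cellA", "cellB", "cellC"], dtype=object),
        gene_ids=np.array(["g1", "g2", "g3", "g4"], dtype=object),
        labels=np.array(["T", "B", "T"], dtype=object),
    )


def random_simplex(rng, n, K):
    return rng.dirichlet(np.ones(K), size=n)
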