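import numpy as np
import pytest

from endoscore import ExpressionMatrix, SurvivalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_matrix(rng):
    """8 genes x 6 samples of continuous values, fixed seed."""
    genes = [f"G{i}" for i in range(8)]
    samples = [f"S{j}" for j in range(6)]
    return ExpressionMatrix(genes, samples, rng.normal(size=(8, 6)))


def make_records(times, events, prefix="s"):
    return [SurvivalRecord(f"{prefix}{i}", float(t), int(e))
            for i, (t, e) in enumerate(zip(times, events))]


@pytest.fixture
def toy_records():
    """Three events at times 1, 2, 3, no censoring."""
    return make_records([1, 2, 3], [1, 1, 1])


def roc_auc(scores, labels):
    """Rank-based AUC of `scores` for predicting boolean `labels`."""
    from scipy.stats import rankdata
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    r = rankdata(scores)
    n1, n0 = labels.sum(), (~labels).sum()
    return (r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
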