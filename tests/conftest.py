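"""Shared fixtures: parsed/encoded surrogate data sets and trained models.

The expensive end-to-end pipeline run (20,000 surrogate constructs ->
simulated sort-seq reads -> quantification -> CNN + lasso training) is built
once per session and shared by the model-property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import aptazyme as az
from aptazyme import facs_seq, models


@pytest.fixture(scope="session")
def scaffold_fx() -> az.Scaffold:
    return az.Scaffold.load_default()


@pytest.fixture(scope="session")
def aptamers_fx():
    return az.load_aptamers()


def _prepare(df: pd.DataFrame, scaffold: az.Scaffold, labels: np.ndarray):
    """Fold/parse/encode a loop table; returns dict with aligned arrays."""
    parsed = [az.analyze(a, b, scaffold) for a, b in zip(df["loop1"], df["loop2"])]
    keep = [i for i, p in enumerate(parsed) if not p.misfolded]
    ok = [parsed[i] for i in keep]
    X, mask, kept, skipped = az.batch_encode(ok)
    idx = np.asarray(keep)[kept]
    return {
        "df": df.iloc[idx].reset_index(drop=True),
        "parsed": [ok[i] for i in kept],
        "X": X,
        "y": np.asarray(labels)[idx],
        "keys": [ok[i].key for i in kept],
        "n_misfolded": len(parsed) - len(keep),
    }


@pytest.fixture(scope="session")
def small_data(scaffold_fx):
    """~2,000 parsed + encoded surrogate constructs with deterministic labels."""
    df = az.generate_training_set(2500, az.SurrogateSpec(), seed=42)
    return _prepare(df, scaffold_fx, df["activity"].to_numpy())


@pytest.fixture(scope="session")
def small_cnn(small_data):
    """A quickly trained CNN used where only *a* working model is needed."""
    cfg = models.RegressorConfig(epochs=15, seed=3)
    return models.train_cnn(small_data["X"], small_data["y"], cfg)


@pytest.fixture(scope="session")
def pipeline(scaffold_fx):
    """Full synthetic-data closure at n = 20,000.

    surrogate generate -> simulate 8-bin reads (depth 500, sigma 0.4) ->
    quantify (batched censored-normal ML) -> fold/parse/encode -> 75/25 split
    -> train CNN and lasso on the *measured* labels; a second CNN/lasso pair
    is trained on the noiseless surrogate labels for signal-recovery checks.
    """
    n = 20_000
    spec = az.SurrogateSpec()
    df = az.generate_training_set(n, spec, seed=11)
    reads = az.simulate_facs_reads(df["activity"], facs_seq.DEFAULT_SCHEME,
                                   depth=500, sigma=0.4, seed=12,
                                   sequences=df["loop1"] + "_" + df["loop2"])
    fitted = az.fit_activities(reads, facs_seq.DEFAULT_SCHEME)
    fitted, n_removed = az.filter_min_reads(fitted)
    assert len(fitted) == n and n_removed == 0  # depth 500 >> threshold
    df = df.assign(measured=fitted["mean"].to_numpy())

    prep = _prepare(df, scaffold_fx, df["measured"].to_numpy())
    y_meas = prep["y"]
    y_true = prep["df"]["activity"].to_numpy()
    tr, te = az.evaluation.split_indices(len(y_meas), 0.75, seed=13)

    cfg = models.RegressorConfig(seed=7)
    X = prep["X"]
    out = dict(prep)
    out.update(
        train_idx=tr, test_idx=te, y_true=y_true,
        cnn_meas=models.train_cnn(X[tr], y_meas[tr], cfg),
        lasso_meas=models.train_baseline("lasso", X[tr], y_meas[tr], seed=7),
        cnn_true=models.train_cnn(X[tr], y_true[tr], cfg),
        lasso_true=models.train_baseline("lasso", X[tr], y_true[tr], seed=7),
    )
    return out
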