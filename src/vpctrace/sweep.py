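"""Kernel-size sweep: train and evaluate a grid of time-series specs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import evaluate
from .modelspec import build_ts_model
from .pipeline import to_multi_input
from .train import TrainConfig, train


def _inputs_for(spec, x):
    return to_multi_input(x) if spec.mode == "multi_input" else x


def sweep(specs: list, datasets: dict, config: TrainConfig | None = None,
          n_boot: int = 0) -> pd.DataFrame:
    """Train/evaluate every spec; one row per spec, Table-style columns.

    ``datasets`` maps partition -> (x, y) with x of shape (n, 1250, 12).
    Each spec gets a fresh seed derived from the base seed and its grid
    index.  Per-spec failures are recorded in the ``error`` column
    without aborting the sweep.
    """
    if not specs:
        raise ValueError("empty spec grid")
    config = config or TrainConfig()
    rows = []
    for i, spec in enumerate(specs):
        row = {
            "mode": spec.mode,
            "kernel_size": spec.blocks[0].kernel_size,
            "accuracy": np.nan, "auc": np.nan,
            "sensitivity": np.nan, "specificity": np.nan,
            "error": "",
        }
        try:
            seed = config.seed + i
            model = build_ts_model(spec, seed=seed)
            cfg = TrainConfig(
                learning_rate=config.learning_rate, epochs=config.epochs,
                batch_size=config.batch_size,
                early_stopping_patience=config.early_stopping_patience,
                seed=seed,
            )
            xt, yt = datasets["train"]
            xv, yv = datasets["validation"]
            train(model, _inputs_for(spec, xt), yt,
                  _inputs_for(spec, xv), yv, cfg)
            xe, ye = datasets["test"]
            scores = model.predict_proba(_inputs_for(spec, xe))[:, 1]
            rep = evaluate(scores, ye, positive_label=1, n_boot=n_boot, seed=seed)
            row.update(accuracy=rep.accuracy, auc=rep.auc,
                       sensitivity=rep.sensitivity, specificity=rep.specificity)
        except Exception as e:  # keep sweeping; report the failure inline
            row["error"] = str(e)
        rows.append(row)
    return pd.DataFrame(rows)
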