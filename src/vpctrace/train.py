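"""Mini-batch training loop with early stopping.

Protocol defaults: Adam at learning rate 0.0011,
categorical cross-entropy, batch size 32, up to 400 epochs, early
stopping on validation loss with patience 250 and best-weights
restoration.  The loop is deterministic under its seed (single-threaded
NumPy): shuffling and dropout both draw from seeded generators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, softmax_xent


@dataclass
class TrainConfig:
    learning_rate: float = 0.0011
    epochs: int = 400
    batch_size: int = 32
    early_stopping_patience: int = 250
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stopping_patience > self.epochs:
            raise ValueError("patience cannot exceed the epoch budget")


def _n_samples(x) -> int:
    return x[0].shape[0] if isinstance(x, list) else x.shape[0]


def _take(x, idx):
    return [xi[idx] for xi in x] if isinstance(x, list) else x[idx]


def _eval_loss_acc(model, x, y, batch_size: int) -> tuple:
    n = _n_samples(x)
    losses, correct = 0.0, 0
    for i in range(0, n, batch_size):
        xb, yb = _take(x, slice(i, i + batch_size)), y[i:i + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = softmax_xent(logits, yb)
        losses += loss * len(yb)
        correct += int((logits.argmax(axis=1) == yb).sum())
    return losses / n, correct / n


def train(model, x_train, y_train, x_val=None, y_val=None,
          config: TrainConfig | None = None) -> dict:
    """Train ``model`` in place; returns the per-epoch history.

    ``x_*`` is an array for single-input models or a list of 12 per-lead
    arrays for the multi-input model; ``y_*`` are integer class labels
    (1 = VPC).  Early stopping monitors validation loss when a validation
    set is given (training loss otherwise) and restores the best state.
    """
    config = config or TrainConfig()
    if _n_samples(x_train) == 0:
        raise ValueError("empty training set")
    has_val = x_val is not None and _n_samples(x_val) > 0
    y_train = np.asarray(y_train, dtype=int)
    if has_val:
        y_val = np.asarray(y_val, dtype=int)

    opt = Adam(model.parameters(), model.gradients(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_loss = np.inf
    best_state = model.get_state()
    best_epoch = 0
    n = _n_samples(x_train)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = _take(x_train, idx), y_train[idx]
            logits = model.forward(xb, train=True)
            loss, grad = softmax_xent(logits, yb)
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(yb)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        history["train_loss"].append(ep_loss / n)
        history["train_acc"].append(ep_correct / n)

        if has_val:
            vl, va = _eval_loss_acc(model, x_val, y_val, config.batch_size)
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            monitored = vl
        else:
            monitored = history["train_loss"][-1]

        if monitored < best_loss:
            best_loss = monitored
            best_state = model.get_state()
            best_epoch = epoch
        elif epoch - best_epoch >= max(config.early_stopping_patience, 1):
            break

    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    return history
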