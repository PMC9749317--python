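"""Glue between synthetic cohorts, the digitizer and the model inputs."""

from __future__ import annotations

import numpy as np

from .condition import FilterConfig, digitize
from .preprocess import resize_for_image_model
from .waveform import VPC_LABEL


def labels_of(records: list) -> np.ndarray:
    """Integer labels (1 = VPC) in record order."""
    return np.array([1 if r.label == VPC_LABEL else 0 for r in records], dtype=int)


def records_to_signal_tensors(records: list,
                              filter_config: FilterConfig | None = None) -> np.ndarray:
    """Digitize each record's image into the (n, 1250, 12) model input."""
    out = [digitize(r.image, layout=r.image.layout, filter_config=filter_config).values
           for r in records]
    return np.stack(out, axis=0)


def records_to_image_tensors(records: list) -> np.ndarray:
    """Preprocess each record's image into the (n, 256, 512, 3) input.

    Stored as float32: a cohort of hundreds of records otherwise costs
    gigabytes for no accuracy benefit.
    """
    return np.stack(
        [resize_for_image_model(r.image).pixels.astype(np.float32) for r in records],
        axis=0)


def to_multi_input(x: np.ndarray) -> list:
    """Split an (n, 1250, 12) tensor into 12 per-lead (n, 1250, 1) inputs."""
    return [x[:, :, j:j + 1] for j in range(x.shape[2])]


def partition_arrays(x, y: np.ndarray, records: list, assignment) -> dict:
    """Slice model inputs by a SplitAssignment into train/validation/test."""
    idx_of = {r.record_id: i for i, r in enumerate(records)}
    out = {}
    for part in ("train", "validation", "test"):
        idx = np.array([idx_of[rid] for rid in assignment.records(part)], dtype=int)
        xb = [xi[idx] for xi in x] if isinstance(x, list) else x[idx]
        out[part] = (xb, y[idx])
    return out
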