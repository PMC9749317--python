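"""End-to-end experiment drivers: cohort -> digitize -> split -> train ->
evaluate, for each of the three model families."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import EvalReport, evaluate
from .modelspec import (
    ImageModelSpec,
    build_image_model,
    build_ts_model,
    default_ts_spec,
    kernel_size_grid,
    tiny_ts_spec,
)
from .pipeline import (
    labels_of,
    partition_arrays,
    records_to_image_tensors,
    records_to_signal_tensors,
    to_multi_input,
)
from .split import split_by_patient
from .sweep import sweep as _sweep
from .train import TrainConfig, train as _train

FAMILIES = ("image", "ts-single", "ts-multi")


def run_family(records: list, family: str, kernel_size: int = 7,
               tiny: bool = True, epochs: int = 60, batch_size: int = 32,
               target_val: int = 50, target_test: int = 100,
               seed: int = 0, n_boot: int = 0,
               patience: int | None = None) -> tuple[EvalReport, dict]:
    """Train one family on rendered records; report held-out test metrics.

    Returns ``(report, history)``.  ``tiny`` selects the CPU-sized
    architectures; epochs default to a budget suited to the strongly
    separable synthetic cohorts rather than the full clinical protocol.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    roster = pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "patient_id": [r.patient_id for r in records],
        "label": [r.label for r in records],
    })
    assignment = split_by_patient(roster, target_val, target_test, seed=seed)
    y = labels_of(records)

    if family == "image":
        x = records_to_image_tensors(records)
        backbone = "TINY" if tiny else "VGG16"
        model = build_image_model(ImageModelSpec(backbone_id=backbone), seed=seed)
    else:
        x = records_to_signal_tensors(records)
        mode = "single_input" if family == "ts-single" else "multi_input"
        spec = (tiny_ts_spec(mode, kernel_size) if tiny
                else default_ts_spec(mode, kernel_size))
        model = build_ts_model(spec, seed=seed)
        if mode == "multi_input":
            x = to_multi_input(x)

    parts = partition_arrays(x, y, records, assignment)
    cfg = TrainConfig(
        epochs=epochs, batch_size=batch_size, seed=seed,
        early_stopping_patience=min(250, epochs) if patience is None else patience,
    )
    history = _train(model, *parts["train"], *parts["validation"], cfg)
    x_test, y_test = parts["test"]
    scores = model.predict_proba(x_test)[:, 1]
    report = evaluate(scores, y_test, positive_label=1, n_boot=n_boot, seed=seed)
    return report, history


def run_three_families(records: list, seed: int = 0, target_val: int = 50,
                       target_test: int = 100, n_boot: int = 0,
                       epochs: dict | None = None) -> dict:
    """Train and evaluate all three TINY families on one cohort.

    Digitization, image preprocessing and the patient-disjoint split are
    computed once and shared.  ``epochs`` maps family -> epoch budget;
    defaults are sized for strongly separable synthetic cohorts (the
    image model converges in around a dozen epochs there, the 1-D models
    in a few dozen).  Returns family -> EvalReport.
    """
    epochs = epochs or {"image": 12, "ts-single": 30, "ts-multi": 20}
    roster = pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "patient_id": [r.patient_id for r in records],
        "label": [r.label for r in records],
    })
    assignment = split_by_patient(roster, target_val, target_test, seed=seed)
    y = labels_of(records)
    x_ts = records_to_signal_tensors(records)
    x_img = records_to_image_tensors(records)

    reports = {}
    for family in FAMILIES:
        if family == "image":
            model = build_image_model(ImageModelSpec(backbone_id="TINY"), seed=seed)
            x = x_img
        else:
            mode = "single_input" if family == "ts-single" else "multi_input"
            model = build_ts_model(tiny_ts_spec(mode), seed=seed)
            x = to_multi_input(x_ts) if mode == "multi_input" else x_ts
        parts = partition_arrays(x, y, records, assignment)
        n_ep = epochs[family]
        cfg = TrainConfig(epochs=n_ep, early_stopping_patience=n_ep, seed=seed)
        _train(model, *parts["train"], *parts["validation"], cfg)
        x_test, y_test = parts["test"]
        scores = model.predict_proba(x_test)[:, 1]
        reports[family] = evaluate(scores, y_test, positive_label=1,
                                   n_boot=n_boot, seed=seed)
    return reports


def sweep_records(records: list, sizes, modes, epochs: int = 40,
                  tiny: bool = True, target_val: int = 50,
                  target_test: int = 100, seed: int = 0) -> pd.DataFrame:
    """Kernel-size sweep over time-series specs on rendered records."""
    roster = pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "patient_id": [r.patient_id for r in records],
        "label": [r.label for r in records],
    })
    assignment = split_by_patient(roster, target_val, target_test, seed=seed)
    x = records_to_signal_tensors(records)
    y = labels_of(records)
    parts = partition_arrays(x, y, records, assignment)
    datasets = {k: parts[k] for k in ("train", "validation", "test")}
    specs = []
    for mode in modes:
        base = tiny_ts_spec(mode) if tiny else default_ts_spec(mode)
        specs.extend(kernel_size_grid(mode, sizes, base=base))
    cfg = TrainConfig(epochs=epochs, early_stopping_patience=min(250, epochs),
                      seed=seed)
    return _sweep(specs, datasets, cfg)


def _load_cohort_dir(cohort_dir: str) -> list:
    """Rehydrate records (images + labels) from a saved cohort directory."""
    import os

    from PIL import Image

    from .layout import LEAD_NAMES, default_layout
    from .render import EcgImage, SyntheticRecord
    from .waveform import LeadSignalSet

    manifest = pd.read_csv(os.path.join(cohort_dir, "manifest.csv"))
    layout = default_layout()
    records = []
    for _, row in manifest.iterrows():
        png = os.path.join(cohort_dir, f"{row.record_id}.png")
        pixels = np.asarray(Image.open(png).convert("RGB"))
        npz = os.path.join(cohort_dir, f"{row.record_id}.npz")
        truth = None
        masks = np.zeros(pixels.shape[:2], dtype=np.uint8)
        rows = np.zeros((layout.n_subimages, layout.traces_per_subimage,
                         layout.columns_per_subimage), dtype=int)
        if os.path.exists(npz):
            with np.load(npz) as z:
                truth = LeadSignalSet(data=z["leads"], rate_hz=500.0,
                                      lead_names=list(LEAD_NAMES), rhythm=z["rhythm"])
                masks = z["truth_masks"]
                rows = z["trace_rows"]
        records.append(SyntheticRecord(
            record_id=row.record_id, patient_id=row.patient_id, label=row.label,
            image=EcgImage(pixels=pixels, layout=layout, source_id=row.record_id),
            truth=truth, truth_masks=masks, trace_rows=rows,
            trace_ids=np.full(pixels.shape[:2], -1, dtype=np.int16),
        ))
    return records


def run_family_on_cohort_dir(cohort_dir: str, family: str, **kw) -> EvalReport:
    records = _load_cohort_dir(cohort_dir)
    report, _ = run_family(records, family, **kw)
    return report


def sweep_on_cohort_dir(cohort_dir: str, sizes, modes, epochs: int = 40,
                        target_val: int = 50, target_test: int = 100,
                        seed: int = 0) -> pd.DataFrame:
    records = _load_cohort_dir(cohort_dir)
    return sweep_records(records, sizes, modes, epochs=epochs,
                         target_val=target_val, target_test=target_test, seed=seed)
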