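"""Synthetic labelled cohorts with patient-level record grouping.

A cohort mimics the clinical situation the classifier is meant for: some
patients contribute several printouts, every printout of a patient shares
the patient's label, and within-patient recordings are more alike than
between-patient ones (waveform parameters are drawn once per patient,
only noise is redrawn per record).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .layout import LeadLayout, default_layout
from .render import SyntheticRecord, render_ecg_image
from .waveform import NOR_LABEL, VPC_LABEL, WaveformParams, generate_waveform


@dataclass
class CohortRanges:
    """Per-patient sampling ranges (uniform) for waveform parameters.

    Defaults describe a resting adult cohort with light acquisition noise;
    ``class_effect_size`` is the fixed magnitude of the VPC-class
    morphology perturbation.
    """

    heart_rate_bpm: tuple = (55.0, 95.0)
    p_amp: tuple = (0.10, 0.20)
    qrs_amp: tuple = (0.85, 1.15)
    t_amp: tuple = (0.20, 0.40)
    qrs_width_s: tuple = (0.07, 0.10)
    p_width_s: tuple = (0.08, 0.10)
    t_width_s: tuple = (0.14, 0.18)
    baseline_wander_amp: tuple = (0.02, 0.08)
    noise_sd: tuple = (0.015, 0.030)
    class_effect_size: float = 1.0


def _draw_patient_params(rng: np.random.Generator, ranges: CohortRanges,
                         label: str) -> WaveformParams:
    kw = {}
    for f in dataclasses.fields(ranges):
        if f.name == "class_effect_size":
            continue
        lo, hi = getattr(ranges, f.name)
        kw[f.name] = rng.uniform(lo, hi)
    return WaveformParams(class_label=label, class_effect_size=ranges.class_effect_size, **kw)


def generate_cohort(
    n_patients: int,
    records_per_patient: tuple = (1, 1),
    class_balance: float = 0.5,
    params_ranges: CohortRanges | None = None,
    seed: int = 0,
    layout: LeadLayout | None = None,
    duration_s: float = 2.5,
    rate_hz: float = 500.0,
) -> list[SyntheticRecord]:
    """Generate a labelled cohort of rendered records.

    ``class_balance`` is the VPC-patient proportion; patient class counts
    are allocated deterministically as ``round(n_patients * balance)``.
    ``records_per_patient`` is an inclusive integer range.  The same seed
    reproduces the cohort byte for byte.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be at least 2")
    if not (0 < class_balance < 1):
        raise ValueError("class_balance must be in (0, 1)")
    n_vpc = int(round(n_patients * class_balance))
    if n_vpc == 0 or n_vpc == n_patients:
        raise ValueError(
            f"class_balance {class_balance} leaves a class empty for {n_patients} patients"
        )
    lo, hi = records_per_patient
    if not (1 <= lo <= hi):
        raise ValueError("records_per_patient must be an increasing range starting at >= 1")
    ranges = params_ranges or CohortRanges()
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)

    labels = np.array([VPC_LABEL] * n_vpc + [NOR_LABEL] * (n_patients - n_vpc))
    rng.shuffle(labels)

    records: list[SyntheticRecord] = []
    for p in range(n_patients):
        patient_id = f"P{p:05d}"
        label = str(labels[p])
        params = _draw_patient_params(rng, ranges, label)
        n_rec = int(rng.integers(lo, hi + 1))
        for k in range(n_rec):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            signals = generate_waveform(
                params, duration_s=duration_s, rate_hz=rate_hz, rng_seed=rec_seed,
                n_rhythm_segments=layout.n_subimages,
            )
            rec = render_ecg_image(
                signals, layout=layout,
                record_id=f"{patient_id}R{k}", patient_id=patient_id, label=label,
                rng_seed=rec_seed,
            )
            rec.meta["params"] = params
            records.append(rec)
    return records


def cohort_manifest(records: list[SyntheticRecord],
                    image_dir: str | None = None) -> pd.DataFrame:
    """Manifest table: record_id, patient_id, label (+ paths if saved)."""
    rows = []
    for r in records:
        row = {"record_id": r.record_id, "patient_id": r.patient_id, "label": r.label}
        if image_dir is not None:
            row["image_path"] = f"{image_dir}/{r.record_id}.png"
            row["truth_path"] = f"{image_dir}/{r.record_id}.npz"
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(records: list[SyntheticRecord], out_dir) -> pd.DataFrame:
    """Write images (PNG), ground truth (NPZ) and the manifest CSV."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for r in records:
        Image.fromarray(r.image.pixels).save(os.path.join(out_dir, f"{r.record_id}.png"))
        np.savez_compressed(
            os.path.join(out_dir, f"{r.record_id}.npz"),
            leads=r.truth.data,
            rhythm=r.truth.rhythm if r.truth.rhythm is not None else np.zeros(0),
            truth_masks=r.truth_masks,
            trace_rows=r.trace_rows,
        )
    manifest = cohort_manifest(records, image_dir=str(out_dir))
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
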