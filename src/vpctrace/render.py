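"""Render a 12-lead signal set as a red-grid ECG printout raster.

The renderer is the ground-truth oracle for the digitization pipeline: it
records which pixels belong to grid, trace and background and the exact
pen row drawn for every trace in every pixel column, so extraction
accuracy can be scored pixel for pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import LeadLayout, default_layout
from .waveform import LeadSignalSet

# truth_masks codes
MASK_BACKGROUND = 0
MASK_GRID = 1
MASK_TRACE = 2

DEFAULT_GRID_COLOR = (240, 170, 170)
DEFAULT_TRACE_COLOR = (10, 10, 10)

MINOR_GRID_SPACING = 5
MAJOR_GRID_SPACING = 25


@dataclass
class EcgImage:
    """RGB raster of a printout plus its layout metadata."""

    pixels: np.ndarray          # (H, W, 3) uint8
    layout: LeadLayout
    source_id: str = ""

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("EcgImage pixels must be H x W x 3")


@dataclass
class SyntheticRecord:
    """A rendered record with its full ground truth.

    ``trace_rows[s, t, c]`` is the pen-center row drawn for trace ``t`` of
    sub-image ``s`` at column ``c`` (after band clipping).  ``truth_masks``
    classifies every pixel as background / grid / trace; ``trace_ids``
    gives, for trace pixels, the flat trace index ``s * traces + t`` that
    drew them (-1 elsewhere; overlaps keep the first writer).
    """

    record_id: str
    patient_id: str
    label: str
    image: EcgImage
    truth: LeadSignalSet
    truth_masks: np.ndarray
    trace_rows: np.ndarray
    trace_ids: np.ndarray
    clipped: bool = False
    meta: dict = field(default_factory=dict)


def _resample_to_columns(signal: np.ndarray, n_cols: int) -> np.ndarray:
    src = np.arange(signal.shape[0])
    pos = np.linspace(0, signal.shape[0] - 1, n_cols)
    return np.interp(pos, src, signal)


def trace_column_rows(signal: np.ndarray, baseline_row: int, px_per_unit: float,
                      n_cols: int) -> np.ndarray:
    """Pen-center rows for a trace: baseline - round(px_per_unit * amplitude).

    Rows grow downward, so positive amplitude yields a smaller row index.
    """
    cols = _resample_to_columns(np.asarray(signal, dtype=float), n_cols)
    return baseline_row - np.round(px_per_unit * cols).astype(int)


def pen_column_spans(rows: np.ndarray, line_width_px: int = 1) -> np.ndarray:
    """Inclusive [low, high] row span inked in each column for one trace.

    Consecutive samples are joined like a continuous pen stroke: the
    vertical run between neighbours is split at the midpoint, each half
    drawn in its own column.  Extra ``line_width_px`` thickens the stroke
    symmetrically (rounding the extra pixel downward).
    """
    n = rows.shape[0]
    spans = np.stack([rows, rows], axis=1)  # (n, 2) low/high
    for c in range(1, n):
        m = (rows[c - 1] + rows[c]) // 2
        spans[c - 1, 0] = min(spans[c - 1, 0], m)
        spans[c - 1, 1] = max(spans[c - 1, 1], m)
        spans[c, 0] = min(spans[c, 0], m)
        spans[c, 1] = max(spans[c, 1], m)
    extra = max(int(line_width_px) - 1, 0)
    spans[:, 0] -= extra // 2
    spans[:, 1] += extra - extra // 2
    return spans


def render_ecg_image(
    signals: LeadSignalSet,
    layout: LeadLayout | None = None,
    grid_color: tuple = DEFAULT_GRID_COLOR,
    trace_color: tuple = DEFAULT_TRACE_COLOR,
    line_width_px: int = 1,
    rng_seed: int = 0,
    record_id: str = "synthetic",
    patient_id: str = "synthetic",
    label: str = "NOR",
) -> SyntheticRecord:
    """Draw ``signals`` as a printout image with per-pixel ground truth.

    The grid is periodic (minor lines every 5 px in ``grid_color``, major
    lines every 25 px in a darker shade of it); traces are drawn on top in
    ``trace_color``.  A trace excursion leaving its vertical band is
    clipped to the band and the record is flagged ``clipped``.
    """
    layout = layout or default_layout()
    if tuple(grid_color) == tuple(trace_color):
        raise ValueError("grid_color and trace_color must differ")
    H, W = layout.image_height, layout.image_width
    n_cols = layout.columns_per_subimage
    img = np.full((H, W, 3), 255, dtype=np.uint8)
    masks = np.full((H, W), MASK_BACKGROUND, dtype=np.uint8)
    trace_ids = np.full((H, W), -1, dtype=np.int16)

    major = tuple(max(c - 40, 0) for c in grid_color)
    for step, color in ((MINOR_GRID_SPACING, grid_color), (MAJOR_GRID_SPACING, major)):
        img[::step, :, :] = color
        img[:, ::step, :] = color
    masks[::MINOR_GRID_SPACING, :] = MASK_GRID
    masks[:, ::MINOR_GRID_SPACING] = MASK_GRID

    n_traces = layout.traces_per_subimage
    trace_rows = np.zeros((layout.n_subimages, n_traces, n_cols), dtype=int)
    clipped = False
    rhythm = signals.rhythm
    seg_len = signals.n_samples

    for s in range(layout.n_subimages):
        col0 = s * n_cols
        for t in range(n_traces):
            lead = layout.lead_at(s, t)
            if lead is None:
                if rhythm is None:
                    continue
                sig = rhythm[s * seg_len:(s + 1) * seg_len]
            else:
                sig = signals.lead(lead)
            baseline = layout.trace_baseline_rows[t]
            rows = trace_column_rows(sig, baseline, layout.px_per_unit_amplitude, n_cols)
            top, bottom = layout.trace_band(t)
            if rows.min() < top or rows.max() > bottom - 1:
                clipped = True
                rows = np.clip(rows, top, bottom - 1)
            trace_rows[s, t] = rows
            spans = pen_column_spans(rows, line_width_px)
            spans = np.clip(spans, 0, H - 1)
            tid = s * n_traces + t
            for c in range(n_cols):
                lo, hi = spans[c]
                col = col0 + c
                img[lo:hi + 1, col, :] = trace_color
                masks[lo:hi + 1, col] = MASK_TRACE
                seg = trace_ids[lo:hi + 1, col]
                seg[seg < 0] = tid

    image = EcgImage(pixels=img, layout=layout, source_id=record_id)
    return SyntheticRecord(
        record_id=record_id,
        patient_id=patient_id,
        label=label,
        image=image,
        truth=signals,
        truth_masks=masks,
        trace_rows=trace_rows,
        trace_ids=trace_ids,
        clipped=clipped,
    )
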