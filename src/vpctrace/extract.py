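"""Trace extraction: binary mask -> per-lead raw sample sequences.

The mask is cut vertically into four sub-images (time quarters), each
pixel column is scanned for ink, ink runs are grouped to the four traces
crossing the column, and grouped rows are assembled into baseline-
subtracted amplitude series of exactly ``columns_per_subimage`` samples
per lead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .layout import LeadLayout, default_layout
from .preprocess import TraceMask


@dataclass
class RawLeadSeries:
    """One lead's pixel-unit amplitudes (up = positive), one per column."""

    lead_name: str
    samples: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def split_subimages(mask: TraceMask, layout: LeadLayout | None = None) -> list:
    """Cut the mask vertically into four sub-images.

    With a layout, boundaries are the layout's fixed quarter positions
    mapped through the mask's crop offset.  Without one, boundaries are
    detected as the deepest ink-density valleys near the quarter marks.
    Returns ``[(submask, col_offset), ...]`` with offsets in mask
    coordinates; the slices partition the used width.
    """
    pixels = mask.pixels
    W = pixels.shape[1]
    if W < 4:
        raise ValueError(f"mask too narrow to hold 4 sub-images (width {W})")
    if layout is not None:
        off = mask.crop_offset[1]
        bounds = [s * layout.columns_per_subimage - off for s in range(layout.n_subimages + 1)]
        bounds = [min(max(b, 0), W) for b in bounds]
    else:
        density = uniform_filter1d((pixels > 0).sum(axis=0).astype(float), size=9)
        bounds = [0]
        for s in range(1, 4):
            center = W * s // 4
            half = max(W // 16, 1)
            lo, hi = max(center - half, 1), min(center + half, W - 1)
            bounds.append(lo + int(np.argmin(density[lo:hi])))
        bounds.append(W)
    n_nonempty = sum(1 for a, b in zip(bounds[:-1], bounds[1:]) if b - a > 0)
    if n_nonempty < 4:
        raise ValueError(f"found only {n_nonempty} sub-image segments, expected 4")
    return [(pixels[:, a:b], a) for a, b in zip(bounds[:-1], bounds[1:])]


def scan_columns(submask: np.ndarray) -> list:
    """Per column, the sorted foreground row indices (empty list = gap)."""
    submask = np.asarray(submask)
    rows_idx, cols_idx = np.nonzero(submask.T != 0)  # rows_idx are columns here
    out = [np.empty(0, dtype=int) for _ in range(submask.shape[1])]
    if rows_idx.size:
        starts = np.searchsorted(rows_idx, np.arange(submask.shape[1] + 1))
        for c in range(submask.shape[1]):
            out[c] = cols_idx[starts[c]:starts[c + 1]]
    return out


def _runs(rows: np.ndarray, run_gap_px: int) -> list:
    """Split sorted rows into runs; a jump larger than run_gap_px starts a new run."""
    if rows.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(rows) > run_gap_px) + 1
    return np.split(rows, breaks)


def group_traces(scan: list, baselines, run_gap_px: int = 3,
                 track: bool = True) -> np.ndarray:
    """Assign each column's ink runs to the four traces crossing it.

    Runs (vertical pen strokes) are assigned to the nearest trace
    reference row — the trace's previously assigned row when tracking, its
    static baseline otherwise; ties go to the upper trace.  Several runs
    mapping to one trace are merged by pixel-weighted centroid; a trace
    with no run gets NaN for that column.

    Returns an array of shape (n_traces, n_columns).
    """
    baselines = np.asarray(baselines, dtype=float)
    if not np.all(np.diff(baselines) > 0):
        raise ValueError("baselines must be strictly increasing")
    n_traces = baselines.shape[0]
    n_cols = len(scan)
    out = np.full((n_traces, n_cols), np.nan)
    refs = baselines.copy()
    for c in range(n_cols):
        runs = _runs(np.asarray(scan[c]), run_gap_px)
        if not runs:
            continue
        acc_w = np.zeros(n_traces)
        acc_sum = np.zeros(n_traces)
        for run in runs:
            centroid = float(run.mean())
            t = int(np.argmin(np.abs(refs - centroid)))  # argmin ties -> upper trace
            acc_w[t] += run.size
            acc_sum[t] += run.size * centroid
        got = acc_w > 0
        out[got, c] = acc_sum[got] / acc_w[got]
        if track:
            refs[got] = out[got, c]
    return out


def _fill_gaps(values: np.ndarray) -> np.ndarray:
    """Linear interpolation of interior NaNs; edge gaps hold the nearest value."""
    values = values.astype(float)
    known = np.flatnonzero(~np.isnan(values))
    if known.size == 0:
        raise ValueError("trace lost: no samples recovered")
    idx = np.arange(values.shape[0])
    return np.interp(idx, known, values[known])


def assemble_leads(grouped_per_sub: list, layout: LeadLayout | None = None,
                   row_offset: int = 0, max_missing_frac: float = 0.5) -> tuple:
    """Convert grouped rows into named amplitude series.

    Amplitude is ``baseline_row - row`` (sign-flipped so upward deflection
    is positive), in pixel units.  Missing columns are filled by linear
    interpolation (edges held).  Returns ``(leads, rhythm)`` where
    ``leads`` is a dict of 12 ``RawLeadSeries`` and ``rhythm`` is the
    concatenated long-lead-II series.

    ``row_offset`` maps layout baseline rows into mask coordinates (the
    mask's crop row offset).
    """
    layout = layout or default_layout()
    if len(grouped_per_sub) != layout.n_subimages:
        raise ValueError("one grouped array per sub-image is required")
    leads: dict = {}
    rhythm_parts = []
    for s, grouped in enumerate(grouped_per_sub):
        for t in range(layout.traces_per_subimage):
            vals = grouped[t]
            missing = np.isnan(vals).mean()
            name = layout.lead_at(s, t)
            if missing > max_missing_frac:
                label = name or "rhythm II"
                raise ValueError(
                    f"trace lost: lead {label} missing in {missing:.0%} of columns"
                )
            baseline = layout.trace_baseline_rows[t] - row_offset
            amp = baseline - _fill_gaps(vals)
            if name is None:
                rhythm_parts.append(amp)
            else:
                leads[name] = RawLeadSeries(lead_name=name, samples=amp)
    rhythm = np.concatenate(rhythm_parts) if rhythm_parts else None
    return leads, rhythm


def extract_mask(mask: TraceMask, layout: LeadLayout | None = None,
                 run_gap_px: int = 3) -> tuple:
    """Full extraction: split -> scan -> group -> assemble."""
    layout = layout or default_layout()
    subs = split_subimages(mask, layout)
    row_off = mask.crop_offset[0]
    baselines = [b - row_off for b in layout.trace_baseline_rows]
    grouped = [group_traces(scan_columns(sub), baselines, run_gap_px=run_gap_px)
               for sub, _ in subs]
    return assemble_leads(grouped, layout, row_offset=row_off)
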