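"""Geometry of a standard 12-lead ECG printout.

A printout is a 3x4 panel: four vertical sub-images (time quarters of the
strip, 250 pixel columns each) stacked with four traces per sub-image —
three of the twelve standard leads plus the continuous long-lead-II rhythm
strip along the bottom row.  Every pixel column therefore crosses exactly
four traces, which is what the column-scanning extractor relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

LEAD_NAMES = [
    "I", "II", "III",
    "aVR", "aVL", "aVF",
    "V1", "V2", "V3",
    "V4", "V5", "V6",
]

RHYTHM_LEAD = "II"

# lead name -> (sub-image index, trace row) for the conventional 3x4 panel
_DEFAULT_LEAD_ORDER = {
    "I": (0, 0), "II": (0, 1), "III": (0, 2),
    "aVR": (1, 0), "aVL": (1, 1), "aVF": (1, 2),
    "V1": (2, 0), "V2": (2, 1), "V3": (2, 2),
    "V4": (3, 0), "V5": (3, 1), "V6": (3, 2),
}


@dataclass
class LeadLayout:
    """Placement of the 12 leads and rhythm strip on the printout raster.

    Attributes
    ----------
    n_subimages:
        Vertical cuts of the strip; each holds ``columns_per_subimage``
        pixel columns.
    columns_per_subimage:
        Pixel columns per sub-image; one column per drawn sample.
    traces_per_subimage:
        Traces crossing each column (3 leads + rhythm strip).
    lead_order:
        Lead name -> (sub-image index, trace row).
    trace_baseline_rows:
        Resting (zero-amplitude) pixel row of each trace, top to bottom.
    px_per_unit_amplitude:
        Vertical pixels per unit of signal amplitude.  Rows grow downward,
        so positive amplitude moves the pen to a *smaller* row index.
    segment_duration_s:
        Seconds of signal shown per sub-image.
    """

    n_subimages: int = 4
    columns_per_subimage: int = 250
    traces_per_subimage: int = 4
    lead_order: dict = field(default_factory=lambda: dict(_DEFAULT_LEAD_ORDER))
    trace_baseline_rows: tuple = (32, 96, 160, 224)
    px_per_unit_amplitude: float = 25.0
    segment_duration_s: float = 2.5
    image_height: int = 256

    def __post_init__(self):
        rows = self.trace_baseline_rows
        if list(rows) != sorted(rows) or len(set(rows)) != len(rows):
            raise ValueError("trace baseline rows must be strictly increasing")
        if len(rows) != self.traces_per_subimage:
            raise ValueError("one baseline row per trace is required")
        mapped = set(self.lead_order)
        if mapped != set(LEAD_NAMES):
            missing = set(LEAD_NAMES) - mapped
            raise ValueError(f"lead_order must map all 12 leads; missing {sorted(missing)}")
        if self.px_per_unit_amplitude <= 0:
            raise ValueError("px_per_unit_amplitude must be positive")
        if self.segment_duration_s <= 0:
            raise ValueError("segment_duration_s must be positive")

    @property
    def image_width(self) -> int:
        return self.n_subimages * self.columns_per_subimage

    @property
    def rhythm_trace_row(self) -> int:
        return self.traces_per_subimage - 1

    def trace_band(self, trace_row: int) -> tuple[int, int]:
        """Half-open [top, bottom) row band owned by a trace.

        Bands meet at midpoints between consecutive baselines; the first
        and last bands extend to the image edges.
        """
        rows = self.trace_baseline_rows
        top = 0 if trace_row == 0 else (rows[trace_row - 1] + rows[trace_row]) // 2
        if trace_row == len(rows) - 1:
            bottom = self.image_height
        else:
            bottom = (rows[trace_row] + rows[trace_row + 1]) // 2
        return top, bottom

    def lead_at(self, subimage: int, trace_row: int) -> str | None:
        """Lead shown at a panel position; None for the rhythm-strip row."""
        if trace_row == self.rhythm_trace_row:
            return None
        for name, (s, t) in self.lead_order.items():
            if (s, t) == (subimage, trace_row):
                return name
        raise ValueError(f"no lead mapped at sub-image {subimage}, row {trace_row}")


def default_layout() -> LeadLayout:
    return LeadLayout()
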