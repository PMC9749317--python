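"""Trace extraction: splitting, scanning, grouping, lead assembly."""

import numpy as np
import pytest

from vpctrace import (
    assemble_leads,
    group_traces,
    scan_columns,
    split_subimages,
)
from vpctrace.extract import extract_mask
from vpctrace.layout import LEAD_NAMES
from vpctrace.preprocess import TraceMask, binarize_invert, remove_grid
from vpctrace.render import MASK_TRACE, pen_column_spans


def _mask(pixels, offset=(0, 0)):
    return TraceMask(pixels=pixels.astype(np.uint8) * 255, crop_offset=offset)


def test_split_uniform_layout_partitions(layout):
    mask = _mask(np.zeros((256, 1000)))
    mask.pixels[100, :] = 255
    subs = split_subimages(mask, layout)
    assert [off for _, off in subs] == [0, 250, 500, 750]
    assert all(sub.shape == (256, 250) for sub, _ in subs)


def test_split_respects_crop_offset(layout):
    mask = _mask(np.zeros((256, 990)), offset=(0, 10))
    subs = split_subimages(mask, layout)
    assert [off for _, off in subs] == [0, 240, 490, 740]


def test_split_detects_valleys_without_layout():
    pixels = np.zeros((50, 400))
    for s in range(4):
        pixels[25, s * 100 + 3:(s + 1) * 100 - 3] = 1  # blank separators
    subs = split_subimages(_mask(pixels), layout=None)
    offsets = [off for _, off in subs]
    for s, off in enumerate(offsets[1:], start=1):
        assert abs(off - 100 * s) <= 5


def test_split_too_narrow_errors(layout):
    with pytest.raises(ValueError, match="sub-image"):
        split_subimages(_mask(np.ones((10, 3))), layout)


def test_split_truth_pixels_land_in_owning_slice(clean_record, layout):
    mask = _mask(clean_record.truth_masks == MASK_TRACE)
    subs = split_subimages(mask, layout)
    n_traces = layout.traces_per_subimage
    for s, (sub, off) in enumerate(subs):
        ids = clean_record.trace_ids[:, off:off + sub.shape[1]]
        owned = ids[ids >= 0] // n_traces
        assert (owned == s).all()


def test_scan_single_line():
    pixels = np.zeros((20, 7))
    pixels[11] = 1
    scan = scan_columns(_mask(pixels).pixels)
    assert all(list(c) == [11] for c in scan)


def test_scan_two_lines_sorted():
    pixels = np.zeros((20, 5))
    pixels[[4, 15]] = 1
    scan = scan_columns(_mask(pixels).pixels)
    assert all(list(c) == [4, 15] for c in scan)


def test_scan_gap_column_empty():
    pixels = np.zeros((10, 3))
    pixels[5, [0, 2]] = 1
    scan = scan_columns(_mask(pixels).pixels)
    assert list(scan[1]) == []


def test_scan_sine_matches_rasterization_oracle():
    rows = (40 + np.round(25 * np.sin(np.linspace(0, 6 * np.pi, 250)))).astype(int)
    spans = pen_column_spans(rows)
    pixels = np.zeros((80, 250))
    for c, (lo, hi) in enumerate(spans):
        pixels[lo:hi + 1, c] = 1
    scan = scan_columns(_mask(pixels).pixels)
    for c in range(250):
        assert abs(np.median(scan[c]) - rows[c]) <= 1


def test_group_flat_lines_recover_baselines():
    baselines = [10, 30, 50, 70]
    pixels = np.zeros((80, 40))
    for b in baselines:
        pixels[b] = 1
    grouped = group_traces(scan_columns(_mask(pixels).pixels), baselines)
    for t, b in enumerate(baselines):
        assert (grouped[t] == b).all()


def test_group_missing_traces_marked():
    baselines = [10, 30, 50, 70]
    pixels = np.zeros((80, 4))
    pixels[31] = 1  # ink only near baseline 2
    grouped = group_traces(scan_columns(_mask(pixels).pixels), baselines)
    assert (grouped[1] == 31).all()
    assert np.isnan(grouped[[0, 2, 3]]).all()


def test_group_tie_goes_to_upper_trace():
    baselines = [10, 20]
    pixels = np.zeros((40, 2))
    pixels[15] = 1  # equidistant between the two baselines
    grouped = group_traces(scan_columns(_mask(pixels).pixels), baselines, track=False)
    assert (grouped[0] == 15).all()
    assert np.isnan(grouped[1]).all()


def test_group_tracked_assignment_through_overlap():
    """Two traces crossing briefly: tracking keeps >= 99% of columns on the
    correct trace (controlled overlap in < 5% of columns)."""
    n = 250
    t = np.linspace(0, 2 * np.pi, n)
    true_rows = np.stack([
        np.round(40 + 30 * np.sin(t)).astype(int),       # swings into band 2
        np.full(n, 75, dtype=int),
        np.round(160 + 10 * np.sin(3 * t)).astype(int),
        np.full(n, 224, dtype=int),
    ])
    pixels = np.zeros((256, n))
    for r in range(4):
        for c, (lo, hi) in enumerate(pen_column_spans(true_rows[r])):
            pixels[lo:hi + 1, c] = 1
    grouped = group_traces(scan_columns(_mask(pixels).pixels), [40, 75, 160, 224])
    correct = 0
    for r in range(4):
        correct += np.sum(np.abs(grouped[r] - true_rows[r]) <= 2)
    assert correct / (4 * n) >= 0.99


def test_assemble_flat_trace_is_zero(layout):
    grouped = [np.tile(np.array(layout.trace_baseline_rows, float)[:, None], (1, 250))
               for _ in range(4)]
    leads, rhythm = assemble_leads(grouped, layout)
    for name in LEAD_NAMES:
        assert leads[name].n_samples == 250
        np.testing.assert_allclose(leads[name].samples, 0.0)
    np.testing.assert_allclose(rhythm, 0.0)


def test_assemble_interpolates_interior_gap(layout):
    grouped = []
    for _ in range(4):
        g = np.tile(np.array(layout.trace_baseline_rows, float)[:, None], (1, 250))
        grouped.append(g)
    # lead I (sub 0, trace 0): amplitudes 2 then gap then 4
    grouped[0][0, :] = layout.trace_baseline_rows[0] - 2.0
    grouped[0][0, 100] = np.nan
    grouped[0][0, 101:] = layout.trace_baseline_rows[0] - 4.0
    leads, _ = assemble_leads(grouped, layout)
    assert leads["I"].samples[100] == pytest.approx(3.0)


def test_assemble_edge_gap_holds_nearest(layout):
    grouped = [np.tile(np.array(layout.trace_baseline_rows, float)[:, None], (1, 250))
               for _ in range(4)]
    grouped[0][0, :] = layout.trace_baseline_rows[0] - 5.0
    grouped[0][0, :3] = np.nan
    leads, _ = assemble_leads(grouped, layout)
    np.testing.assert_allclose(leads["I"].samples[:3], 5.0)


def test_assemble_mostly_missing_lead_errors(layout):
    grouped = [np.tile(np.array(layout.trace_baseline_rows, float)[:, None], (1, 250))
               for _ in range(4)]
    grouped[1][2, :130] = np.nan  # aVF missing in 52% of columns
    with pytest.raises(ValueError, match="trace lost"):
        assemble_leads(grouped, layout)


def test_full_extraction_round_trip(clean_record, layout):
    """Per-lead Pearson r between extracted pixel series and the rendered
    ground truth (resampled to 250 columns) is >= 0.99 on noise-free input."""
    gray = remove_grid(clean_record.image)
    mask = binarize_invert(gray)
    leads, _ = extract_mask(mask, layout)
    for name in LEAD_NAMES:
        truth = clean_record.truth.lead(name)
        tr = np.interp(np.linspace(0, truth.size - 1, 250),
                       np.arange(truth.size), truth)
        r = np.corrcoef(leads[name].samples, tr)[0, 1]
        assert r >= 0.99, f"lead {name}: r={r:.4f}"


def test_extraction_deterministic(clean_record, layout):
    mask = binarize_invert(remove_grid(clean_record.image))
    a, ra = extract_mask(mask, layout)
    b, rb = extract_mask(mask, layout)
    for name in LEAD_NAMES:
        np.testing.assert_array_equal(a[name].samples, b[name].samples)
    np.testing.assert_array_equal(ra, rb)
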