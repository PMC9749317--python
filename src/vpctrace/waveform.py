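"""Synthetic sinus-rhythm waveform generator.

Each lead is a P-QRS-T template train (sums of Gaussian deflections placed
relative to each R peak) scaled by a fixed per-lead amplitude table, plus
optional baseline wander and white noise.  Records labelled VPC receive a
deterministic, smooth morphology perturbation — a low-frequency deflection
adjacent to the QRS complex and a slight QRS widening, both scaled by
``class_effect_size`` — so that the two classes are statistically
separable from sinus-rhythm morphology alone, without rendering an actual
ectopic beat.  This emulates the premise that VPC-prone hearts leave
subtle signatures in their sinus beats; it is a statistical stand-in, not
a physiological model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .layout import LEAD_NAMES, RHYTHM_LEAD

VPC_LABEL = "VPC"
NOR_LABEL = "NOR"

# Fixed per-lead scaling of the shared template (deterministic by design;
# signs follow the usual lead polarities, aVR and V1 predominantly negative).
LEAD_SCALE = {
    "I": 0.70, "II": 1.00, "III": 0.45,
    "aVR": -0.75, "aVL": 0.40, "aVF": 0.80,
    "V1": -0.55, "V2": 0.85, "V3": 1.05,
    "V4": 1.10, "V5": 0.95, "V6": 0.75,
}


@dataclass
class WaveformParams:
    """Knobs of one record's waveform.

    Amplitudes are in arbitrary display units (the pipeline normalizes
    amplitude away); widths and the heart period are in seconds.
    """

    heart_rate_bpm: float = 70.0
    p_amp: float = 0.15
    qrs_amp: float = 1.0
    t_amp: float = 0.30
    qrs_width_s: float = 0.08
    p_width_s: float = 0.09
    t_width_s: float = 0.16
    baseline_wander_amp: float = 0.0
    noise_sd: float = 0.0
    class_label: str = NOR_LABEL
    class_effect_size: float = 1.0

    def __post_init__(self):
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        for name in ("qrs_width_s", "p_width_s", "t_width_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.qrs_width_s >= 60.0 / self.heart_rate_bpm:
            raise ValueError("qrs_width_s must be shorter than the beat period")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.baseline_wander_amp < 0:
            raise ValueError("baseline_wander_amp must be nonnegative")
        if self.class_effect_size < 0:
            raise ValueError("class_effect_size must be nonnegative")
        if self.class_label not in (VPC_LABEL, NOR_LABEL):
            raise ValueError(f"class_label must be {VPC_LABEL!r} or {NOR_LABEL!r}")


@dataclass
class LeadSignalSet:
    """12 named leads sampled at ``rate_hz`` plus the long rhythm strip."""

    data: np.ndarray          # (n_samples, 12)
    rate_hz: float
    lead_names: list
    rhythm: np.ndarray | None = None   # lead II over the full strip duration

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def lead(self, name: str) -> np.ndarray:
        return self.data[:, self.lead_names.index(name)]


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _template(t: np.ndarray, params: WaveformParams) -> np.ndarray:
    """One-lead unit template over time axis ``t`` (seconds)."""
    period = 60.0 / params.heart_rate_bpm
    effect = params.class_effect_size if params.class_label == VPC_LABEL else 0.0
    # VPC-prone records: slightly wider QRS plus a low-frequency hump on the
    # ST segment, both proportional to the effect size.
    qrs_sigma = (params.qrs_width_s / 4.0) * (1.0 + 0.25 * effect)
    out = np.zeros_like(t)
    n_beats = int(np.floor(t[-1] / period)) + 2
    for k in range(n_beats):
        r = (k + 0.5) * period
        out += params.p_amp * _gauss(t, r - 0.16, params.p_width_s / 2.5)
        out += -0.15 * params.qrs_amp * _gauss(t, r - 0.028, 0.012)
        out += params.qrs_amp * _gauss(t, r, qrs_sigma)
        out += -0.20 * params.qrs_amp * _gauss(t, r + 0.030, 0.014)
        out += params.t_amp * _gauss(t, r + 0.25, params.t_width_s / 2.5)
        if effect > 0:
            out += 0.25 * effect * params.qrs_amp * _gauss(t, r + 0.10, 0.025)
    return out


def generate_waveform(
    params: WaveformParams,
    duration_s: float = 2.5,
    rate_hz: float = 500.0,
    rng_seed: int = 0,
    n_rhythm_segments: int = 4,
) -> LeadSignalSet:
    """Generate the 12 leads plus the long-lead-II rhythm strip.

    Parameters
    ----------
    params:
        Morphology, rate, noise and class settings.
    duration_s, rate_hz:
        Length and sampling rate of each lead (defaults 2.5 s at 500 Hz,
        i.e. 1250 samples per lead).
    rng_seed:
        Seeds noise, wander phases and wander frequencies; identical seeds
        give identical output.
    n_rhythm_segments:
        The rhythm strip spans this many ``duration_s`` windows (one per
        printed sub-image).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    base = _template(t, params)

    data = np.empty((n, 12))
    for j, name in enumerate(LEAD_NAMES):
        sig = LEAD_SCALE[name] * base
        if params.baseline_wander_amp > 0:
            f = rng.uniform(0.2, 0.6)
            phi = rng.uniform(0, 2 * np.pi)
            sig = sig + params.baseline_wander_amp * np.sin(2 * np.pi * f * t + phi)
        else:
            rng.uniform(size=2)  # keep the stream aligned across noise settings
        if params.noise_sd > 0:
            sig = sig + rng.normal(0.0, params.noise_sd, n)
        data[:, j] = sig

    n_r = n_rhythm_segments * n
    t_r = np.arange(n_r) / rate_hz
    rhythm = LEAD_SCALE[RHYTHM_LEAD] * _template(t_r, params)
    if params.baseline_wander_amp > 0:
        f = rng.uniform(0.2, 0.6)
        phi = rng.uniform(0, 2 * np.pi)
        rhythm = rhythm + params.baseline_wander_amp * np.sin(2 * np.pi * f * t_r + phi)
    else:
        rng.uniform(size=2)
    if params.noise_sd > 0:
        rhythm = rhythm + rng.normal(0.0, params.noise_sd, n_r)

    return LeadSignalSet(data=data, rate_hz=rate_hz, lead_names=list(LEAD_NAMES), rhythm=rhythm)


def as_vpc(params: WaveformParams, effect_size: float | None = None) -> WaveformParams:
    """Copy of ``params`` labelled VPC (optionally overriding effect size)."""
    eff = params.class_effect_size if effect_size is None else effect_size
    return replace(params, class_label=VPC_LABEL, class_effect_size=eff)
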