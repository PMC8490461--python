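"""Unipolar electrogram analysis.

Local activation at an extracellular electrode appears as a sharp negative
deflection ("downstroke").  This module blanks stimulation artifacts, measures
downstroke amplitude/duration, extracts the electrical local activation time
eLAT_SG (time of the steepest negative slope, from the Savitzky-Golay
derivative), and applies a quantitative channel-exclusion rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import MetricsError, TraceError
from .optical import sg_window_samples

@dataclass
class ElectrogramTrace:
    electrode_id: int
    samples: np.ndarray  # mV
    sampling_rate: float  # Hz
    stimulus_times: list[float] = field(default_factory=list)  # ms
    blanked_intervals: list[tuple[float, float]] = field(default_factory=list)  # ms

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise TraceError("sampling_rate must be positive")
        dur = len(self.samples) * self.dt_ms
        for ts in self.stimulus_times:
            if not (0 <= ts <= dur):
                raise TraceError(f"stimulus time {ts} ms outside the record (0..{dur:.1f} ms)")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_ms


@dataclass
class ElectrogramMetrics:
    electrode_id: int
    downstroke_amplitude: float | None  # mV (magnitude)
    downstroke_duration: float | None  # ms
    max_negative_slope: float | None  # mV/ms (magnitude)
    elat_sg: float | None  # ms
    downstroke_interval: tuple[float, float] | None = None  # ms (local max -> trough)
    excluded: bool = False
    exclusion_reason: str | None = None


def blank_stimulus_artifact(trace: ElectrogramTrace, window_ms: float) -> ElectrogramTrace:
    """Replace +-window around each stimulus by linear interpolation.

    The blanked spans are recorded on the returned trace so downstream
    detection can ignore them.  A window covering the whole record is refused.
    """
    if window_ms < 0:
        raise TraceError("blanking window must be >= 0")
    if not trace.stimulus_times or window_ms == 0:
        return trace
    y = trace.samples.copy()
    n = len(y)
    dt = trace.dt_ms
    if 2 * window_ms >= n * dt:
        raise TraceError("blanking window covers the entire record")
    blanked = list(trace.blanked_intervals)
    for ts in trace.stimulus_times:
        i0 = int(np.floor((ts - window_ms) / dt))
        i1 = int(np.ceil((ts + window_ms) / dt))
        i0c, i1c = max(i0, 0), min(i1, n - 1)
        if i0c >= i1c:
            continue
        y[i0c : i1c + 1] = np.linspace(y[i0c], y[i1c], i1c - i0c + 1)
        blanked.append((i0c * dt, i1c * dt))
    return ElectrogramTrace(
        electrode_id=trace.electrode_id,
        samples=y,
        sampling_rate=trace.sampling_rate,
        stimulus_times=list(trace.stimulus_times),
        blanked_intervals=blanked,
    )


def _noise_sd(y: np.ndarray) -> float:
    # robust SD from first differences (flat-noise assumption)
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def compute_egm_metrics(
    trace: ElectrogramTrace,
    beat_window: tuple[float, float] | None = None,
    sg_window: int | None = None,
    sg_order: int = 2,
    noise_factor: float = 4.0,
    default_half_window_ms: float = 40.0,
) -> ElectrogramMetrics:
    """Quantify one beat's downstroke.

    The downstroke is the maximal peak-to-trough negative deflection in the
    beat window: amplitude = preceding local max - trough (mV), duration =
    time between them, and eLAT_SG = time of the Savitzky-Golay derivative
    minimum inside the downstroke (ties -> earliest).
    """
    y = trace.samples
    t = trace.times_ms
    dt = trace.dt_ms
    if sg_window is None:
        sg_window = sg_window_samples(trace.sampling_rate, 1.0, sg_order, len(y))
    if beat_window is None:
        # center the default window on the steepest negative slope of the
        # whole record -- the most activation-like deflection
        d_full = savgol_filter(y, min(sg_window, len(y) - (1 - len(y) % 2)), sg_order, deriv=1, delta=dt)
        ctr = int(np.argmin(d_full))
        beat_window = (t[ctr] - default_half_window_ms, t[ctr] + default_half_window_ms)
    i0 = max(0, int(np.floor(beat_window[0] / dt)))
    i1 = min(len(y) - 1, int(np.ceil(beat_window[1] / dt)))
    if i1 - i0 < 4:
        raise MetricsError("beat window too short")
    seg = y[i0 : i1 + 1]
    tseg = t[i0 : i1 + 1]

    trough_idx = int(np.argmin(seg))
    peak_idx = int(np.argmax(seg[: trough_idx + 1])) if trough_idx > 0 else 0
    amplitude = float(seg[peak_idx] - seg[trough_idx])
    noise = _noise_sd(seg)
    # the peak-to-trough range of n pure-noise samples is ~2*sqrt(2 ln n)*SD;
    # require the deflection to clear that expected range with margin
    n_seg = len(seg)
    range_thresh = noise * max(noise_factor, 3.0 * np.sqrt(2.0 * np.log(max(n_seg, 3))))
    if amplitude <= range_thresh or trough_idx == peak_idx:
        return ElectrogramMetrics(
            electrode_id=trace.electrode_id,
            downstroke_amplitude=None, downstroke_duration=None,
            max_negative_slope=None, elat_sg=None,
            excluded=True, exclusion_reason="no downstroke",
        )
    duration = float(tseg[trough_idx] - tseg[peak_idx])

    if sg_window is None:
        sg_window = sg_window_samples(trace.sampling_rate, 1.0, sg_order, len(seg))
    if sg_window > len(seg):
        raise MetricsError("SG window longer than the beat window")
    deriv = savgol_filter(seg, sg_window, sg_order, deriv=1, delta=dt)
    sl = slice(peak_idx, trough_idx + 1)
    rel = int(np.argmin(deriv[sl]))  # argmin returns the earliest tie
    elat = float(tseg[peak_idx + rel])
    max_neg = float(-deriv[peak_idx + rel])

    ds_int = (float(tseg[peak_idx]), float(tseg[trough_idx]))
    excluded = False
    reason = None
    for b0, b1 in trace.blanked_intervals:
        if ds_int[0] <= b1 and b0 <= ds_int[1]:
            excluded, reason = True, "artifact overlap"
            break
    return ElectrogramMetrics(
        electrode_id=trace.electrode_id,
        downstroke_amplitude=amplitude,
        downstroke_duration=duration,
        max_negative_slope=max_neg,
        elat_sg=elat,
        downstroke_interval=ds_int,
        excluded=excluded,
        exclusion_reason=reason,
    )


def segment_beats(
    trace: ElectrogramTrace,
    half_window_ms: float = 40.0,
    sg_order: int = 2,
) -> list[tuple[float, float]]:
    """Beat windows after each stimulus (if known) or around the single
    steepest-negative-slope deflection of the record."""
    if trace.stimulus_times:
        return [(ts, ts + 2 * half_window_ms) for ts in trace.stimulus_times]
    w = sg_window_samples(trace.sampling_rate, 1.0, sg_order, len(trace.samples))
    d = savgol_filter(trace.samples, w, sg_order, deriv=1, delta=trace.dt_ms)
    ctr = float(trace.times_ms[int(np.argmin(d))])
    return [(ctr - half_window_ms, ctr + half_window_ms)]


def exclude_bad_channels(
    metrics_by_channel: dict[int, list[ElectrogramMetrics]],
    min_valid_fraction: float = 0.5,
) -> dict[int, str]:
    """Channel-level exclusion report.

    A channel is excluded when at least half of its beats lack a usable
    downstroke (amplitude below the noise criterion) or when its downstroke
    overlaps a blanked stimulation-artifact interval in at least half of the
    beats.  Returns ``{electrode_id: reason}`` for the excluded channels.
    """
    report: dict[int, str] = {}
    for ch, beats in metrics_by_channel.items():
        if not beats:
            raise MetricsError(f"channel {ch}: no beats analyzed")
        n = len(beats)
        n_nods = sum(1 for m in beats if m.excluded and m.exclusion_reason == "no downstroke")
        n_art = sum(1 for m in beats if m.excluded and m.exclusion_reason == "artifact overlap")
        if n_nods >= min_valid_fraction * n:
            report[ch] = "no downstroke"
        elif n_art >= min_valid_fraction * n:
            report[ch] = "artifact overlap"
    return report
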