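"""Optical action-potential analysis.

Per-fiber fluorescence traces are extracted from camera frame stacks through
an extraction mask (5x5 pixel block per fiber, central 3x3 averaged), drift
corrected by polynomial fitting, and quantified per detected action potential:
fractional fluorescence change (dF/F), maximal upstroke velocity from the
Savitzky-Golay derivative of the amplitude-normalized AP (%APA/ms), AP
durations at chosen repolarization levels, signal-to-noise ratio against a
50 ms resting window, and the two optical local-activation-time definitions
(oLAT_50%: 50% upstroke crossing; oLAT_SG: peak of the SG derivative).

Time convention: sample ``i`` lies at ``t = i * 1000 / sampling_rate`` ms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import MetricsError, TraceError

BLOCK = 5  # pixels per fiber footprint (square)
CORE = 3  # central sub-block actually averaged


class SpatialFilter(str, Enum):
    MEAN = "mean"
    GAUSSIAN = "gaussian"


class ShapeClass(str, Enum):
    SHAPE1 = "shape1"  # foot potential then fast rise
    SHAPE2 = "shape2"  # uniform single-phase rise
    SHAPE3 = "shape3"  # fast initial phase then slower rise to peak
    UNCLASSIFIED = "unclassified"


@dataclass
class FrameStack:
    """time x rows x cols fluorescence intensities."""

    intensities: np.ndarray
    sampling_rate: float
    saturation_value: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise TraceError("frame stack must be a 3D (time, rows, cols) array")
        if self.sampling_rate <= 0:
            raise TraceError("sampling_rate must be positive")


@dataclass
class ExtractionMask:
    """fiber_id -> (row0, col0) of its 5x5 pixel block."""

    blocks: dict[int, tuple[int, int]]
    spatial_filter: SpatialFilter = SpatialFilter.MEAN

    def __post_init__(self) -> None:
        self.spatial_filter = SpatialFilter(self.spatial_filter)
        seen: set[tuple[int, int]] = set()
        for fid, (r0, c0) in self.blocks.items():
            cells = {(r, c) for r in range(r0, r0 + BLOCK) for c in range(c0, c0 + BLOCK)}
            if seen & cells:
                raise TraceError(f"fiber {fid}: 5x5 block overlaps another fiber's block")
            seen |= cells


@dataclass
class FiberTrace:
    fiber_id: int
    samples: np.ndarray
    sampling_rate: float
    baseline_F: float | None = None
    saturation_value: float | None = None
    saturated_samples: np.ndarray | None = None  # per-sample pixel-clipping mask

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise TraceError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise TraceError("trace contains non-finite samples")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_ms


@dataclass
class APInterval:
    onset: int  # sample index of upstroke onset
    offset: int  # last sample of the analysis window (inclusive)
    flags: list[str] = field(default_factory=list)


@dataclass
class OpticalAPMetrics:
    fiber_id: int
    dFF_percent: float | None
    dVdt_max: float | None  # %APA/ms
    apd: dict[int, float]  # repolarization level -> ms
    snr: float | None
    olat_50: float | None  # ms
    olat_sg: float | None  # ms
    shape_class: ShapeClass = ShapeClass.UNCLASSIFIED
    excluded: bool = False
    exclusion_reason: str | None = None
    flags: list[str] = field(default_factory=list)


def _gaussian_core_weights(sigma: float = 0.8) -> np.ndarray:
    ax = np.arange(CORE) - CORE // 2
    g = np.exp(-(ax**2) / (2 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def extract_traces(stack: FrameStack, mask: ExtractionMask) -> list[FiberTrace]:
    """Average each fiber's central 3x3 pixels into a time trace."""
    nt, nr, nc = stack.intensities.shape
    gauss = _gaussian_core_weights()
    traces = []
    for fid, (r0, c0) in mask.blocks.items():
        if r0 < 0 or c0 < 0 or r0 + BLOCK > nr or c0 + BLOCK > nc:
            raise TraceError(f"fiber {fid}: block at ({r0},{c0}) outside {nr}x{nc} frame")
        core = stack.intensities[:, r0 + 1 : r0 + 1 + CORE, c0 + 1 : c0 + 1 + CORE].astype(float)
        if mask.spatial_filter is SpatialFilter.MEAN:
            sig = core.mean(axis=(1, 2))
        else:
            sig = np.tensordot(core, gauss, axes=([1, 2], [0, 1]))
        # saturation is a pixel-level event: averaging must not hide it
        sat_mask = None
        if stack.saturation_value is not None:
            sat_mask = np.any(core >= stack.saturation_value, axis=(1, 2))
        traces.append(
            FiberTrace(
                fiber_id=fid,
                samples=sig,
                sampling_rate=stack.sampling_rate,
                saturation_value=stack.saturation_value,
                saturated_samples=sat_mask,
            )
        )
    return traces


def correct_drift(
    trace: FiberTrace,
    polynomial_order: int = 3,
    ap_mask: list[tuple[int, int]] | None = None,
) -> FiberTrace:
    """Remove slow baseline drift by polynomial fitting.

    The polynomial is fitted on samples outside the AP intervals only and
    subtracted; the mean baseline level is restored afterwards so dF/F stays
    computable from the corrected trace.
    """
    if polynomial_order < 0:
        raise TraceError("polynomial order must be >= 0")
    y = trace.samples
    n = len(y)
    keep = np.ones(n, dtype=bool)
    for a, b in ap_mask or []:
        keep[max(0, a) : min(n, b + 1)] = False
    if keep.sum() < polynomial_order + 1:
        raise TraceError("insufficient baseline samples outside AP intervals for the requested order")
    t = trace.times_ms
    coeff = np.polynomial.polynomial.polyfit(t[keep], y[keep], polynomial_order)
    # evaluate inside the baseline's time span only; a polynomial fitted to a
    # one-sided baseline would otherwise explode across the masked AP region
    t_eval = np.clip(t, t[keep].min(), t[keep].max())
    fit = np.polynomial.polynomial.polyval(t_eval, coeff)
    corrected = y - fit
    base_mean = float(np.mean(y[keep]))
    corrected += base_mean - float(np.mean(corrected[keep]))
    return FiberTrace(
        fiber_id=trace.fiber_id,
        samples=corrected,
        sampling_rate=trace.sampling_rate,
        baseline_F=base_mean,
        saturation_value=trace.saturation_value,
        saturated_samples=trace.saturated_samples,
    )


def sg_window_samples(sampling_rate: float, window_ms: float, order: int, n_samples: int) -> int:
    """Odd SG window spanning ~window_ms, at least order+2 wide (min 5)."""
    w = int(round(window_ms * sampling_rate / 1000.0))
    w = max(w, order + 2, 5)
    if w % 2 == 0:
        w += 1
    if w > n_samples:
        raise TraceError("Savitzky-Golay window longer than the trace")
    return w


def _sg_derivative(samples: np.ndarray, window: int, order: int, dt_ms: float) -> np.ndarray:
    return savgol_filter(samples, window_length=window, polyorder=order, deriv=1, delta=dt_ms)


def detect_aps(
    trace: FiberTrace,
    sg_window: int | None = None,
    sg_order: int = 2,
    threshold_factor: float = 5.0,
    refractory_ms: float = 30.0,
    merge_gap_ms: float = 10.0,
    min_region_samples: int = 3,
) -> list[APInterval]:
    """Locate AP upstrokes where the SG derivative exceeds a noise-scaled threshold.

    Returns disjoint onset/offset analysis windows (each containing exactly one
    upstroke; the window runs to just before the next onset).  Upstrokes closer
    than the refractory setting are kept but flagged ``close_spacing``.
    """
    if sg_window is None:
        sg_window = sg_window_samples(trace.sampling_rate, 1.0, sg_order, len(trace.samples))
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise TraceError("sg_window must be odd and greater than sg_order")
    if sg_window > len(trace.samples):
        raise TraceError("Savitzky-Golay window longer than the trace")
    deriv = _sg_derivative(trace.samples, sg_window, sg_order, trace.dt_ms)
    mad = float(np.median(np.abs(deriv - np.median(deriv))))
    noise_sd = 1.4826 * mad
    if noise_sd == 0:
        # noiseless trace: any appreciable derivative counts as signal
        peak = float(np.max(np.abs(deriv)))
        if peak == 0:
            return []
        noise_sd = peak * 1e-9
    above = deriv > threshold_factor * noise_sd

    # contiguous supra-threshold regions -> one upstroke candidate each
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    # the filter's edge half-windows carry polynomial-extrapolation artifacts
    guard = sg_window // 2
    n_total = len(trace.samples)
    regions = [
        (int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s + 1 >= min_region_samples and s >= guard and e < n_total - guard
    ]
    if not regions:
        return []

    refractory = int(round(refractory_ms / trace.dt_ms))
    merge_gap = int(round(merge_gap_ms / trace.dt_ms))
    n = len(trace.samples)

    # group supra-threshold regions into APs.  Regions separated by less than
    # the merge gap are fragments of one upstroke (noise dips, feet, multi-
    # phasic rises); within the refractory window a region with a much weaker
    # derivative peak (< 50% of its neighbor's) is likewise a continuation,
    # while one of comparable strength is a genuinely close second AP ->
    # kept separate and flagged
    grouped: list[list[tuple[int, int]]] = [[regions[0]]]
    close_pairs: set[int] = set()
    for s, e in regions[1:]:
        prev_s = grouped[-1][0][0]
        prev_e = grouped[-1][-1][1]
        if s - prev_e < merge_gap:
            grouped[-1].append((s, e))
            continue
        if s - prev_s < refractory:
            pk_prev = max(float(deriv[a : b + 1].max()) for a, b in grouped[-1])
            pk_new = float(deriv[s : e + 1].max())
            if min(pk_prev, pk_new) < 0.5 * max(pk_prev, pk_new):
                grouped[-1].append((s, e))
                continue
            close_pairs.add(len(grouped) - 1)
            close_pairs.add(len(grouped))
        grouped.append([(s, e)])

    intervals: list[APInterval] = []
    for k, grp in enumerate(grouped):
        s = grp[0][0]
        offset = (grouped[k + 1][0][0] - 1) if k + 1 < len(grouped) else n - 1
        flags = ["close_spacing"] if k in close_pairs else []
        intervals.append(APInterval(onset=s, offset=offset, flags=flags))
    return intervals


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float | None:
    """First sub-sample crossing of ``level`` (linear interpolation)."""
    if rising:
        hit = np.flatnonzero((y[:-1] < level) & (y[1:] >= level))
    else:
        hit = np.flatnonzero((y[:-1] > level) & (y[1:] <= level))
    if hit.size == 0:
        return None
    i = int(hit[0])
    y0, y1 = y[i], y[i + 1]
    frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def compute_ap_metrics(
    trace: FiberTrace,
    interval: APInterval,
    sg_window: int | None = None,
    sg_order: int = 2,
    apd_levels: tuple[int, ...] = (50, 70, 90),
    rest_window_ms: float = 50.0,
    classify_shape: bool = True,
    pre_pad_ms: float = 10.0,
) -> OpticalAPMetrics:
    """Quantify one optical action potential.

    dF/F uses the resting fluorescence level (mean of the rest window, or the
    trace's stored baseline); the AP is normalized to APA = 100% before
    Savitzky-Golay differentiation so dV/dt_max is in %APA/ms.  APDs run from
    the 50% upstroke crossing to the stated repolarization-level recovery.
    """
    y = trace.samples
    t = trace.times_ms
    a, b = interval.onset, min(interval.offset, len(y) - 1)
    if b <= a:
        raise MetricsError("empty AP interval")
    if sg_window is None:
        sg_window = sg_window_samples(trace.sampling_rate, 1.0, sg_order, b - a + 1)
    # pre-pad so the whole upstroke foot (slow indicators cross the detection
    # threshold well into their rise) and the filter edge lie inside the segment
    a0 = max(0, a - max(sg_window, int(round(pre_pad_ms * trace.sampling_rate / 1000.0))))
    seg = y[a0 : b + 1]
    tseg = t[a0 : b + 1]
    flags = list(interval.flags)
    a = a0

    saturated = trace.saturation_value is not None and np.any(seg >= trace.saturation_value)
    if trace.saturated_samples is not None:
        saturated = saturated or bool(np.any(trace.saturated_samples[a : b + 1]))
    if saturated:
        return OpticalAPMetrics(
            fiber_id=trace.fiber_id,
            dFF_percent=None, dVdt_max=None, apd={}, snr=None, olat_50=None, olat_sg=None,
            excluded=True, exclusion_reason="saturation", flags=flags,
        )

    rest_n = max(2, int(round(rest_window_ms * trace.sampling_rate / 1000.0)))
    rest = y[max(0, a - rest_n) : a]
    if len(rest) < 2:
        raise MetricsError("no resting window available before the AP onset")
    baseline = trace.baseline_F if trace.baseline_F is not None else float(np.mean(rest))
    rest_sd = float(np.std(rest))

    if sg_window > len(seg):
        raise MetricsError("SG window longer than the AP interval")
    # amplitude and level crossings are read off a smoothed copy so a single
    # noise excursion cannot set the AP amplitude; the rest-window SD for the
    # SNR stays unfiltered
    seg_s = savgol_filter(seg, sg_window, sg_order)
    peak_idx = int(np.argmax(seg_s))
    peak = float(seg_s[peak_idx])
    apa_units = peak - baseline
    if apa_units <= 0:
        raise MetricsError("non-positive AP amplitude")
    if baseline <= 0:
        raise MetricsError("non-positive baseline fluorescence; cannot form dF/F")
    dff = 100.0 * apa_units / baseline
    if rest_sd == 0:
        raise MetricsError("zero standard deviation in the resting window; SNR undefined")
    snr = apa_units / rest_sd

    norm = (seg_s - baseline) / apa_units * 100.0
    deriv = _sg_derivative((seg - baseline) / apa_units * 100.0, sg_window, sg_order, trace.dt_ms)

    up_slice = slice(0, peak_idx + 1)
    dvdt_idx = int(np.argmax(deriv[up_slice]))
    dvdt_max = float(deriv[dvdt_idx])
    olat_sg = float(tseg[dvdt_idx])

    olat_50 = _interp_crossing(tseg[: peak_idx + 1], norm[: peak_idx + 1], 50.0, rising=True)
    if olat_50 is None:
        raise MetricsError("no 50% upstroke crossing found")
    n_crossings = int(np.sum((norm[:peak_idx] < 50.0) & (norm[1 : peak_idx + 1] >= 50.0)))
    if n_crossings > 1:
        flags.append("ambiguous_50_crossing")

    apd: dict[int, float] = {}
    for level in apd_levels:
        target = 100.0 - level
        t_rec = _interp_crossing(tseg[peak_idx:], norm[peak_idx:], target, rising=False)
        apd[int(level)] = (t_rec - olat_50) if t_rec is not None else float("nan")

    shape = ShapeClass.UNCLASSIFIED
    if classify_shape:
        shape = classify_upstroke_shape(norm[: peak_idx + 1], deriv[: peak_idx + 1], trace.dt_ms)

    return OpticalAPMetrics(
        fiber_id=trace.fiber_id,
        dFF_percent=dff,
        dVdt_max=dvdt_max,
        apd=apd,
        snr=snr,
        olat_50=olat_50,
        olat_sg=olat_sg,
        shape_class=shape,
        flags=flags,
    )


def classify_upstroke_shape(
    norm_upstroke: np.ndarray,
    sg_derivative: np.ndarray,
    dt_ms: float,
    foot_band: tuple[float, float] = (5.0, 20.0),
    foot_duration_factor: float = 2.0,
    trough_fraction: float = 0.6,
    peak_height_fraction: float = 0.15,
    min_peak_separation_ms: float = 1.0,
) -> ShapeClass:
    """Classify an amplitude-normalized upstroke (0..100 %APA, up to the peak).

    shape1: a sub-threshold "foot" (5-20% APA, lasting >= 2x the main 20-80%
    rise time) precedes a single derivative peak.  shape2: single uniform
    rise.  shape3: two derivative peaks (each >= 15% of the maximum,
    separated by >= 1 ms) with a trough between them <= 60% of the first
    peak -- the fast component first.  Upstrokes sampled with fewer than 3
    points between 10 and 90% APA are left unclassified (too coarse).
    """
    y = np.asarray(norm_upstroke, dtype=float)
    d = np.asarray(sg_derivative, dtype=float)
    t = np.arange(len(y)) * dt_ms
    if np.sum((y > 10.0) & (y < 90.0)) < 3:
        return ShapeClass.UNCLASSIFIED

    dmax = float(d.max())
    if dmax <= 0:
        return ShapeClass.UNCLASSIFIED
    peaks, _ = find_peaks(d, height=peak_height_fraction * dmax,
                          prominence=0.5 * peak_height_fraction * dmax)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(d))])

    if peaks.size >= 2:
        p1, p2 = int(peaks[0]), int(peaks[-1])
        trough = float(d[p1 : p2 + 1].min())
        if (t[p2] - t[p1]) >= min_peak_separation_ms and trough <= trough_fraction * d[p1]:
            return ShapeClass.SHAPE3

    # foot: dwell time inside the foot band vs the main 20-80% rise time
    t5 = _interp_crossing(t, y, foot_band[0], rising=True)
    t20 = _interp_crossing(t, y, foot_band[1], rising=True)
    t80 = _interp_crossing(t, y, 80.0, rising=True)
    if None not in (t5, t20, t80):
        rise = t80 - t20
        foot = t20 - t5
        if rise > 0 and foot >= foot_duration_factor * rise:
            return ShapeClass.SHAPE1

    if peaks.size == 1:
        return ShapeClass.SHAPE2
    return ShapeClass.UNCLASSIFIED


def analyze_trace(
    trace: FiberTrace,
    drift_order: int = 3,
    sg_window: int | None = None,
    sg_order: int = 2,
    threshold_factor: float = 5.0,
    refractory_ms: float = 30.0,
    apd_levels: tuple[int, ...] = (50, 70, 90),
    rest_window_ms: float = 50.0,
) -> list[OpticalAPMetrics]:
    """Full single-fiber pipeline: detect, drift-correct, quantify each AP."""
    prelim = detect_aps(trace, sg_window=sg_window, sg_order=sg_order,
                        threshold_factor=threshold_factor, refractory_ms=refractory_ms)
    if not prelim:
        return []
    pad = max(1, int(round(2.0 / trace.dt_ms)))
    ap_mask = [(max(0, iv.onset - pad), iv.offset) for iv in prelim]
    try:
        corrected = correct_drift(trace, polynomial_order=drift_order, ap_mask=ap_mask)
    except TraceError:
        corrected = trace
    out = []
    for iv in prelim:
        try:
            out.append(
                compute_ap_metrics(corrected, iv, sg_window=sg_window, sg_order=sg_order,
                                   apd_levels=apd_levels, rest_window_ms=rest_window_ms)
            )
        except (MetricsError, TraceError) as exc:
            out.append(
                OpticalAPMetrics(fiber_id=trace.fiber_id, dFF_percent=None, dVdt_max=None,
                                 apd={}, snr=None, olat_50=None, olat_sg=None, excluded=True,
                                 exclusion_reason=str(exc), flags=list(iv.flags))
            )
    return out
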