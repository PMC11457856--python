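"""Breath segmentation and tidal lung-motion metrics.

The motion metrics quantify the *speed* of lung motion during tidal
ventilation: time from inspiratory onset to a channel's within-breath peak
(T_peak) and the maximum first derivative of the pressure, volume, and flow
waves during each phase (Slope_max; on the flow channel this is the
acceleration of lung volume). Phases are defined from flow-signal crossings
with hysteresis, not from the ventilator clock, so the analyzer is
device-agnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import BreathSegment, WaveformRecording

__all__ = ["segment_breaths", "time_to_peak", "max_slope", "motion_metrics",
           "CHANNELS"]

CHANNELS = ("pressure", "volume", "flow")


def segment_breaths(recording: WaveformRecording,
                    min_insp_duration: float = 0.05,
                    flow_tolerance: float = 0.1,
                    detect_smooth_window: int = 9) -> list[BreathSegment]:
    """Segment a recording into complete breaths from the flow channel.

    Inspiration onset is a positive-going crossing of ``+flow_tolerance``
    (L/min); inspiration end is the subsequent negative-going crossing of
    ``-flow_tolerance`` (hysteresis band keeps small zero-flow chatter from
    splitting breaths); a breath's expiration ends at the next onset. Each
    boundary is anchored at the last sample *before* its crossing, so
    pressure/volume read at a boundary reflect the pre-transition state
    (transitions can complete within one sample on a stiff circuit).
    Breaths with an inspiration shorter than ``min_insp_duration`` are
    discarded, as are partial first/last breaths. Identically sub-threshold
    flow yields an empty list.

    Crossings are detected on a lightly smoothed copy of the flow
    (``detect_smooth_window``-sample moving average, 1 to disable) so that
    sensor noise around zero flow does not split breaths; each detected
    boundary is then refined to the raw-flow crossing so centred smoothing
    does not bias boundary positions. All reported indices refer to the raw
    arrays.
    """
    raw = recording.flow
    flow = raw
    if detect_smooth_window > 1:
        kernel = np.ones(detect_smooth_window) / detect_smooth_window
        flow = np.convolve(raw, kernel, mode="same")

    def refine(i: int, tol: float, sign: float) -> int:
        """Snap a smoothed-signal event at ``i`` to the raw crossing of
        ``sign * flow > tol``; returns the last pre-crossing index."""
        j = i
        n = raw.size
        if sign * raw[j] > tol:
            while j > 0 and sign * raw[j - 1] > tol:
                j -= 1
        else:
            while j < n - 1 and sign * raw[j] <= tol:
                j += 1
        return max(j - 1, 0)

    ups: list[int] = []
    downs: list[int] = []
    # start 'insp' if the trace begins above threshold (raw sample: the
    # centred smoothing is unreliable at the boundary): that first breath is
    # partial and must not contribute an onset
    state = "insp" if raw[0] > flow_tolerance else "exp"
    for i in range(1, flow.size):
        if state == "exp" and flow[i] > flow_tolerance:
            ups.append(refine(i, flow_tolerance, 1.0))
            state = "insp"
        elif state == "insp" and flow[i] < -flow_tolerance:
            downs.append(refine(i, flow_tolerance, -1.0))
            state = "exp"

    segments: list[BreathSegment] = []
    t = recording.time
    for k, up in enumerate(ups[:-1]):
        down = next((d for d in downs if d > up), None)
        if down is None or down >= ups[k + 1]:
            continue
        if t[down] - t[up] < min_insp_duration:
            continue
        segments.append(BreathSegment(
            insp_onset_idx=up, insp_end_idx=down, exp_end_idx=ups[k + 1],
            insp_onset=float(t[up]), insp_end=float(t[down]),
            exp_end=float(t[ups[k + 1]])))
    return segments


def _channel(recording: WaveformRecording, channel: str) -> np.ndarray:
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    return getattr(recording, channel)


def time_to_peak(recording: WaveformRecording, segment: BreathSegment,
                 channel: str) -> float:
    """Time (s) from inspiratory onset to the channel's within-breath maximum.

    Ties break to the earliest sample.
    """
    x = _channel(recording, channel)[segment.insp_onset_idx:segment.exp_end_idx]
    if x.size == 0:
        raise ValueError("empty breath segment")
    return float(np.argmax(x)) / recording.sample_rate


def max_slope(recording: WaveformRecording, segment: BreathSegment,
              channel: str, phase: str = "insp",
              smoothing_window: int = 7, polyorder: int = 2):
    """Maximum first derivative of a channel during one breath phase.

    The derivative is estimated with a centred Savitzky-Golay polynomial
    filter (default window 7 samples, order 2), which bounds noise
    amplification relative to raw differencing. For the inspiratory phase
    the signed maximum is returned (>= 0 for any rising wave); for the
    expiratory phase the maximum *magnitude* of the derivative (the peak
    speed of the expiratory change). Returns ``(slope_max,
    t_at_slope_max)`` with the time measured from inspiratory onset; ties
    break to the earliest sample.
    """
    if phase == "insp":
        lo, hi = segment.insp_onset_idx, segment.insp_end_idx + 1
    elif phase == "exp":
        lo, hi = segment.insp_end_idx, segment.exp_end_idx + 1
    else:
        raise ValueError("phase must be 'insp' or 'exp'")
    x = _channel(recording, channel)[lo:hi]
    if x.size < 5:
        raise ValueError("phase must contain at least 5 samples")
    if smoothing_window > x.size:
        raise ValueError(
            f"smoothing_window {smoothing_window} larger than phase ({x.size} samples)")
    dt = 1.0 / recording.sample_rate
    deriv = savgol_filter(x, smoothing_window, polyorder, deriv=1, delta=dt,
                          mode="interp")
    score = deriv if phase == "insp" else np.abs(deriv)
    m = float(score.max())
    # earliest-tie rule, robust to float jitter in the filtered derivative
    i = int(np.argmax(score >= m - (abs(m) * 1e-9 + 1e-12)))
    t_at = (lo + i - segment.insp_onset_idx) * dt
    return float(m), float(t_at)


def motion_metrics(recording: WaveformRecording,
                   min_insp_duration: float = 0.05,
                   flow_tolerance: float = 0.1,
                   smoothing_window: int = 7) -> pd.DataFrame:
    """Per-breath tidy table of T_peak and Slope_max for all three channels.

    One row per (breath, channel, phase); inspiratory rows carry
    ``T_peak_s``, both phases carry ``slope_max`` and ``t_at_slope_max_s``.

    Raises
    ------
    ValueError
        If no complete breath is found.
    """
    segments = segment_breaths(recording, min_insp_duration, flow_tolerance)
    if not segments:
        raise ValueError("no complete breath found in recording")
    rows = []
    for b, seg in enumerate(segments):
        for channel in CHANNELS:
            tp = time_to_peak(recording, seg, channel)
            for phase in ("insp", "exp"):
                try:
                    sm, t_at = max_slope(recording, seg, channel, phase,
                                         smoothing_window)
                except ValueError:
                    sm, t_at = np.nan, np.nan
                rows.append({
                    "subject_id": recording.subject_id,
                    "group": recording.group_label,
                    "breath_index": b,
                    "channel": channel,
                    "phase": phase,
                    "T_peak_s": tp if phase == "insp" else np.nan,
                    "slope_max": sm,
                    "t_at_slope_max_s": t_at,
                })
    return pd.DataFrame(rows)
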