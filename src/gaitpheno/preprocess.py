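"""Raw IMU recordings -> one time-normalized representative stride per subject.

The chain is: zero-phase 4 Hz low-pass, stride segmentation at the provided
stride-start events, per-stride time normalization to a common length L
(linear interpolation over normalized time), and a pointwise mean across a
subject's normalized strides.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, filtfilt

from .config import SignalConfig
from .types import RepresentativeGait, StrideWaveform

log = logging.getLogger(__name__)

_FILTER_ORDER = 4


def lowpass_filter(signal: np.ndarray, config: SignalConfig) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a (n,) or (n, c) series.

    Forward-backward filtering keeps waveform landmarks (heel strike,
    push-off) at their original sample positions and preserves DC.
    """
    signal = np.asarray(signal, dtype=float)
    x = signal[:, None] if signal.ndim == 1 else signal
    b, a = butter(
        _FILTER_ORDER, config.lowpass_cutoff_hz, btype="low", fs=config.sampling_rate_hz
    )
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise ValueError(
            f"series of length {x.shape[0]} too short for filter warm-up ({padlen})"
        )
    y = filtfilt(b, a, x, axis=0)
    return y[:, 0] if signal.ndim == 1 else y


def segment_strides(
    recording: np.ndarray, events: np.ndarray, subject_id: str = ""
) -> list[StrideWaveform]:
    """Cut a (n, 3) recording into strides at stride-start sample indices.

    The convention is half-open [start, next_start); the tail after the last
    event is not a complete stride and is dropped (logged).  Segments shorter
    than 2 samples are dropped with a logged count.
    """
    recording = np.asarray(recording, dtype=float)
    if recording.ndim != 2 or recording.shape[1] != 3:
        raise ValueError("recording must have shape (n, 3)")
    events = np.asarray(events, dtype=int)
    if events.size == 0:
        log.warning("subject %s: empty stride-event table", subject_id)
        return []
    if np.any(np.diff(events) <= 0):
        raise ValueError("stride events must be strictly increasing")
    if events[0] < 0 or events[-1] > recording.shape[0]:
        raise ValueError("stride events out of recording range")

    strides, dropped = [], 0
    for s, e in zip(events[:-1], events[1:]):
        if e - s < 2:
            dropped += 1
            continue
        seg = recording[s:e]
        strides.append(
            StrideWaveform(subject_id, seg[:, 0], seg[:, 1], seg[:, 2])
        )
    if dropped:
        log.info("subject %s: dropped %d short strides", subject_id, dropped)
    if events[-1] < recording.shape[0]:
        log.debug(
            "subject %s: %d-sample tail after last event ignored",
            subject_id,
            recording.shape[0] - events[-1],
        )
    return strides


def time_normalize_stride(stride: StrideWaveform, L: int) -> np.ndarray:
    """Resample a stride to exactly ``L`` points per channel.

    Linear interpolation over normalized time [0, 1]; endpoints are
    preserved.  Returns an array of shape (3, L).
    """
    n = stride.n_samples
    if n < 2:
        raise ValueError("cannot normalize a stride with < 2 samples")
    t_old = np.linspace(0.0, 1.0, n)
    t_new = np.linspace(0.0, 1.0, L)
    chans = stride.channels()
    return np.vstack([np.interp(t_new, t_old, chans[:, c]) for c in range(3)])


def _duration_mask(lengths: np.ndarray) -> np.ndarray:
    """Keep strides whose duration lies within median +/- 3*MAD."""
    med = np.median(lengths)
    mad = np.median(np.abs(lengths - med))
    if mad == 0:
        return np.ones(len(lengths), dtype=bool)
    return np.abs(lengths - med) <= 3.0 * mad


def representative_curves(
    strides: list[StrideWaveform],
    config: SignalConfig,
    exclude_outliers: bool = True,
) -> RepresentativeGait:
    """Pointwise mean of a subject's time-normalized strides, per channel.

    Strides with duration outside median +/- 3*MAD are excluded from the
    average (switchable off); if the policy would drop everything it is
    ignored for that subject.
    """
    if not strides:
        raise ValueError("no valid strides to average")
    sid = strides[0].subject_id
    kept = strides
    if exclude_outliers and len(strides) >= 3:
        lengths = np.array([s.n_samples for s in strides], dtype=float)
        mask = _duration_mask(lengths)
        if mask.any():
            kept = [s for s, m in zip(strides, mask) if m]
        n_drop = len(strides) - len(kept)
        if n_drop:
            log.info("subject %s: %d outlier strides excluded from average", sid, n_drop)
    L = config.normalized_length
    stack = np.stack([time_normalize_stride(s, L) for s in kept])  # (k, 3, L)
    return RepresentativeGait(sid, stack.mean(axis=0), len(kept))
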