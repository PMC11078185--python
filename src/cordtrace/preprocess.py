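"""Referencing, line-noise notch filtering, and event-locked epoching.

Active channels are referenced against dormant counterparts (channels
that carry no evoked response) to cancel artifacts shared across the
array — ECG, respiration, stimulation and movement.  The notch filter is
a second-order IIR notch applied forward-backward (zero phase) so that
evoked-potential latencies are not shifted.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .types import Epochs, EventTable, Recording, ValidationError

logger = logging.getLogger(__name__)


def reference_channels(
    recording: Recording,
    dormant: tuple[int, ...] | list[int],
    scheme: str = "mean",
) -> Recording:
    """Subtract a dormant-channel reference from every active channel.

    Parameters
    ----------
    dormant
        Indices of the dormant (response-free) channels.  With
        ``scheme="mean"`` the reference is their average; with
        ``scheme="single"`` the first listed dormant channel is used.
        Dormant channels pass through unchanged.
    """
    dormant = tuple(int(i) for i in dormant)
    if len(dormant) == 0:
        raise ValidationError("dormant channel set must not be empty")
    if any(i < 0 or i >= recording.n_channels for i in dormant):
        raise ValidationError(f"dormant index out of range for {recording.n_channels} channels")
    if scheme not in ("mean", "single"):
        raise ValidationError(f"unknown reference scheme: {scheme!r}")
    if scheme == "single":
        ref = recording.data[dormant[0]]
    else:
        ref = recording.data[list(dormant)].mean(axis=0)
    out = recording.data - ref[None, :]
    out[list(dormant)] = recording.data[list(dormant)]
    return recording.copy_with(out)


def notch_filter(recording: Recording, freq_hz: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase second-order IIR notch at ``freq_hz`` (default 50 Hz)."""
    nyq = recording.sample_rate / 2.0
    if not 0 < freq_hz < nyq:
        raise ValidationError(
            f"notch frequency {freq_hz} Hz must lie below the Nyquist rate {nyq} Hz"
        )
    b, a = sps.iirnotch(freq_hz, q, fs=recording.sample_rate)
    out = sps.filtfilt(b, a, recording.data, axis=1)
    return recording.copy_with(out)


def epoch(
    recording: Recording,
    events: EventTable,
    window_s: tuple[float, float] = (0.0, 0.020),
) -> Epochs:
    """Cut one window per event, ``window_s = (pre, post)`` seconds.

    Windows are half-open ``[t - pre, t + post)``; the sample at the event
    time sits at index ``floor(pre * rate)``.  Events whose window falls
    outside the recording are dropped with a logged warning.
    """
    pre, post = window_s
    if pre < 0 or post < 0:
        raise ValidationError("window bounds must be non-negative")
    fs = recording.sample_rate
    n_pre = int(np.floor(pre * fs))
    n_post = int(np.floor(post * fs))
    n_win = n_pre + n_post
    if n_win <= 0:
        raise ValidationError("epoch window has zero length")
    kept, slabs = [], []
    for i, t_e in enumerate(events.time_s):
        s0 = int(np.floor(t_e * fs)) - n_pre
        s1 = s0 + n_win
        if s0 < 0 or s1 > recording.n_samples:
            logger.warning(
                "event %d at t=%.4fs dropped: window [%d, %d) outside recording", i, t_e, s0, s1
            )
            continue
        kept.append(i)
        slabs.append(recording.data[:, s0:s1])
    data = np.stack(slabs, axis=0) if slabs else np.empty((0, recording.n_channels, n_win))
    return Epochs(
        data=data,
        window_s=(pre, post),
        sample_rate=fs,
        event_indices=np.asarray(kept, dtype=int),
        events=events,
    )
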