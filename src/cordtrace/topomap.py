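"""Circumferential topographic maps of evoked-potential amplitude.

Per-event, per-channel peak amplitudes are interpolated over the cord
circumference (piecewise-linear on the circle) to give topographic
frames, from which activation hotspots are localised; a frame sequence
over post-stimulus time tracks how the active region moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ElectrodeLayout, Epochs, ValidationError, wrap_angle_deg
from .wavelet import DetectedSpike


@dataclass
class TopoFrame:
    """Amplitude over a dense angular grid at one (relative) time."""

    time_s: float
    angles_deg: np.ndarray
    amplitude_uV: np.ndarray
    interpolation: str = "circular-linear"


@dataclass
class Hotspot:
    """Location and magnitude of the dominant activation."""

    angle_deg: float | None
    magnitude_uV: float
    secondary_angle_deg: float | None = None
    secondary_magnitude_uV: float | None = None
    found: bool = True


def peak_amplitudes(epochs: Epochs, spikes: list[DetectedSpike]) -> np.ndarray:
    """Events x channels matrix of peak detected ECAP amplitude.

    Each spike is attributed to the event whose epoch window contains its
    peak time; entry (e, c) is the largest peak amplitude detected for
    that event on that channel, or 0 if none was.
    """
    n_e, n_c = epochs.n_events, epochs.n_channels
    out = np.zeros((n_e, n_c))
    pre, post = epochs.window_s
    starts = epochs.events.time_s[epochs.event_indices] - pre
    ends = epochs.events.time_s[epochs.event_indices] + post
    for sp in spikes:
        if not 0 <= sp.channel < n_c:
            raise ValidationError(f"spike channel {sp.channel} outside the epoch array")
        hits = np.nonzero((sp.peak_time_s >= starts) & (sp.peak_time_s < ends))[0]
        for e in hits:
            out[e, sp.channel] = max(out[e, sp.channel], sp.peak_amplitude_uV)
    return out


def build_topoframe(
    values: np.ndarray,
    layout: ElectrodeLayout,
    grid_step_deg: float = 1.0,
    time_s: float = 0.0,
) -> TopoFrame:
    """Interpolate per-channel values onto a dense angular grid.

    Piecewise-linear interpolation between adjacent electrodes, wrapping
    across +/-180 only when the layout covers the full circumference; the
    frame passes through the electrode values exactly (up to grid
    resolution the electrode angles themselves are included in the grid).
    """
    if grid_step_deg <= 0:
        raise ValidationError(f"grid step must be positive, got {grid_step_deg}")
    values = np.asarray(values, dtype=float)
    if values.size != layout.n_electrodes:
        raise ValidationError("value vector length must equal the electrode count")
    order = np.argsort(layout.angles_deg)
    ang = layout.angles_deg[order]
    val = values[order]
    if layout.coverage_fraction >= 1.0:
        grid = np.arange(-180.0, 180.0, grid_step_deg)
        interp = np.interp(grid, ang, val, period=360.0)
    else:
        grid = np.arange(ang[0], ang[-1] + grid_step_deg / 2.0, grid_step_deg)
        interp = np.interp(grid, ang, val)
    # exact pass-through at the electrode angles
    grid = np.concatenate([grid, ang])
    interp = np.concatenate([interp, val])
    order2 = np.argsort(grid)
    grid, interp = grid[order2], interp[order2]
    keep = np.concatenate([[True], np.diff(grid) > 1e-9])
    return TopoFrame(time_s=time_s, angles_deg=grid[keep], amplitude_uV=interp[keep])


def find_hotspot(
    frame: TopoFrame,
    n_hotspots: int = 1,
    min_separation_deg: float = 30.0,
) -> Hotspot:
    """Locate the global activation maximum, optionally a second one.

    The secondary hotspot is the largest circular local maximum at least
    ``min_separation_deg`` away from the primary.  A flat (all-equal)
    frame yields a flagged no-hotspot result.
    """
    amp = frame.amplitude_uV
    if amp.size == 0:
        raise ValidationError("empty topographic frame")
    if np.ptp(amp) == 0:
        return Hotspot(angle_deg=None, magnitude_uV=float(amp.max()), found=False)
    i = int(np.argmax(amp))
    primary = Hotspot(angle_deg=float(frame.angles_deg[i]), magnitude_uV=float(amp[i]))
    if n_hotspots < 2:
        return primary
    # circular local maxima
    left = np.roll(amp, 1)
    right = np.roll(amp, -1)
    is_max = (amp >= left) & (amp >= right)
    sep = np.abs(wrap_angle_deg(frame.angles_deg - primary.angle_deg))
    candidates = np.nonzero(is_max & (sep >= min_separation_deg))[0]
    if candidates.size:
        j = candidates[np.argmax(amp[candidates])]
        primary.secondary_angle_deg = float(frame.angles_deg[j])
        primary.secondary_magnitude_uV = float(amp[j])
    return primary


def temporal_evolution(
    epochs: Epochs,
    layout: ElectrodeLayout,
    step_ms: float,
    event_indices: np.ndarray | None = None,
    grid_step_deg: float = 1.0,
) -> list[TopoFrame]:
    """Topographic frames over post-stimulus time.

    The selected epochs are averaged per channel; each frame interpolates
    the peak instantaneous amplitude within one ``step_ms`` bin.  Frame
    count is ``floor(window / step)``.
    """
    if step_ms <= 0:
        raise ValidationError("step must be positive")
    step = int(round(step_ms / 1000.0 * epochs.sample_rate))
    if step > epochs.n_samples:
        raise ValidationError("step larger than the epoch window")
    sel = np.arange(epochs.n_events) if event_indices is None else np.asarray(event_indices)
    mean_epoch = epochs.data[sel].mean(axis=0)  # channels x samples
    n_frames = epochs.n_samples // step
    frames = []
    for k in range(n_frames):
        seg = mean_epoch[:, k * step : (k + 1) * step]
        values = seg.max(axis=1)
        t = (k * step) / epochs.sample_rate - epochs.window_s[0]
        frames.append(build_topoframe(values, layout, grid_step_deg, time_s=t))
    return frames
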