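"""Core domain types shared by every pipeline stage.

All quantities carry fixed units: potentials in microvolts, times in
seconds, frequencies in hertz, angles in degrees.  The angular convention
around the cord circumference is: 0 deg at the dorsal midline, +90 deg at
the animal's left lateral aspect (viewed from rostral), and +/-180 deg at
the ventral midline.  Angles live in the half-open interval [-180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised stimulation-source labels.  MEP = motor evoked potential
#: (descending, from motor-cortex stimulation), SSEP = somatosensory evoked
#: potential (ascending, from peripheral-nerve stimulation).  TIBIAL and
#: PERONEAL are SSEP subsets by stimulated nerve.
EVENT_LABELS = ("MEP_L", "MEP_R", "SSEP_L", "SSEP_R", "TIBIAL", "PERONEAL")

#: Manufactured circumferential device lengths, in millimetres.
DEVICE_LENGTHS_MM = (8.90, 9.90, 10.90)


class CordtraceError(Exception):
    """Base class for all package errors."""


class ValidationError(CordtraceError):
    """A domain invariant was violated."""


class FormatError(CordtraceError):
    """A file did not conform to the expected container layout."""


class LayoutMismatchError(ValidationError):
    """Recording channel count disagrees with the electrode layout."""


def wrap_angle_deg(angle):
    """Wrap angle(s) in degrees into [-180, 180)."""
    return np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0


@dataclass
class ElectrodeLayout:
    """Angular positions of electrodes around the cord circumference.

    Parameters
    ----------
    angles_deg
        Per-electrode angle in degrees, dorsal midline = 0, increasing
        toward the animal's left; strictly ordered along the device.
    midline_index
        Index of the dorsal-midline electrode (angle exactly 0).
    device_length_mm
        Physical device length; one of 8.90, 9.90 or 10.90 mm.
    coverage_fraction
        Fraction of the full circumference the array spans, in (0, 1].
    """

    angles_deg: np.ndarray
    midline_index: int
    device_length_mm: float = 9.90
    coverage_fraction: float = 1.0

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.ndim != 1 or self.angles_deg.size < 2:
            raise ValidationError("layout needs at least 2 electrode angles")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValidationError(
                f"coverage_fraction must be in (0, 1], got {self.coverage_fraction}"
            )
        if not 0 <= self.midline_index < self.angles_deg.size:
            raise ValidationError("midline_index out of range")
        if abs(self.angles_deg[self.midline_index]) > 1e-9:
            raise ValidationError("midline electrode angle must be 0 deg")
        # strict ordering along the device (angles may wrap once at +/-180
        # for a full-coverage array, so check pairwise distinctness of the
        # unwrapped sequence instead of monotonicity of raw values)
        unwrapped = np.unwrap(np.deg2rad(self.angles_deg))
        diffs = np.diff(unwrapped)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("electrode angles must be strictly ordered along the device")

    @property
    def n_electrodes(self) -> int:
        return int(self.angles_deg.size)

    @property
    def spacing_deg(self) -> float:
        """Median adjacent angular spacing, degrees."""
        unwrapped = np.unwrap(np.deg2rad(self.angles_deg))
        return float(np.rad2deg(np.median(np.abs(np.diff(unwrapped)))))


@dataclass
class Recording:
    """Multichannel epidural recording.

    ``data`` is channels x samples in microvolts at ``sample_rate`` Hz.
    """

    data: np.ndarray
    sample_rate: float = 30_000.0
    channel_ids: list[str] | None = None
    layout: ElectrodeLayout | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.layout is not None and self.layout.n_electrodes != self.n_channels:
            raise LayoutMismatchError(
                f"recording has {self.n_channels} channels but layout has "
                f"{self.layout.n_electrodes} electrodes"
            )
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValidationError("channel_ids length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def copy_with(self, data: np.ndarray) -> "Recording":
        """New Recording sharing metadata but holding different samples."""
        return Recording(
            data=data,
            sample_rate=self.sample_rate,
            channel_ids=list(self.channel_ids),
            layout=self.layout,
            annotations=dict(self.annotations),
        )


@dataclass
class EventTable:
    """Stimulation events: onset time, source label, stimulus amplitude."""

    time_s: np.ndarray
    label: list[str]
    stim_amplitude_uA: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.stim_amplitude_uA = np.asarray(self.stim_amplitude_uA, dtype=float)
        self.label = list(self.label)
        if not (self.time_s.size == len(self.label) == self.stim_amplitude_uA.size):
            raise ValidationError("event table columns must have equal length")
        bad = sorted(set(self.label) - set(EVENT_LABELS))
        if bad:
            raise ValidationError(f"unknown event label(s): {bad}; allowed: {EVENT_LABELS}")
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass
class Epochs:
    """Event-locked windows: events x channels x samples, microvolts.

    ``window_s`` is (pre, post) in seconds around each event time; the
    sample at the event time sits at index ``floor(pre * rate)``.
    ``event_indices`` maps epoch rows back to rows of the source
    EventTable (events whose window fell outside the recording are
    dropped).
    """

    data: np.ndarray
    window_s: tuple[float, float]
    sample_rate: float
    event_indices: np.ndarray
    events: EventTable

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def labels(self) -> list[str]:
        return [self.events.label[i] for i in self.event_indices]
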