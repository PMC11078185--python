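"""Synthetic circumferential-recording generator with ground truth.

The generator produces multichannel epidural recordings carrying the
statistical structure the analysis chain assumes:

* time-locked, predominantly positive evoked compound action potentials
  (ECAPs) whose per-channel amplitudes follow smooth angular hotspot
  profiles around the cord circumference — a single dorsal, side-shifted
  hotspot for somatosensory sources and a ventrolateral + lateral double
  hotspot for motor sources, left/right mirrored;
* an ECG-like Ricker-shaped transient shared across channels, slow
  respiration drift, 50-Hz line interference, white instrument noise, and
  brief stimulation artifacts at every event;
* an alternating-source event schedule (~1 s inter-stimulus interval over
  a ~70 s session).

Every hidden parameter (hotspot angles, clean per-channel peak
amplitudes, true peak times, noise seeds) is returned as
:class:`GroundTruth` so recovery tests can score the pipeline against
what was actually injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .types import ElectrodeLayout, EventTable, Recording, ValidationError, wrap_angle_deg

__all__ = [
    "SourceProfile",
    "ECAPTemplate",
    "GroundTruth",
    "make_layout",
    "source_gains",
    "default_profiles",
    "simulate_session",
    "ricker",
]


def ricker(t: np.ndarray, width_s: float) -> np.ndarray:
    """Ricker (Mexican-hat) pulse with characteristic width ``width_s``.

    psi(t) = (1 - (t/a)^2) * exp(-t^2 / (2 a^2)) with a = width_s / 2, so
    the positive lobe spans roughly one ``width_s``.
    """
    a = width_s / 2.0
    u = t / a
    return (1.0 - u**2) * np.exp(-(u**2) / 2.0)


@dataclass
class SourceProfile:
    """Angular hotspot profile of one evoked-potential source.

    The per-channel gain is a sum of von Mises-shaped bumps
    ``g(theta) = sum_b a_b * exp(kappa * (cos(theta - theta_b) - 1))``
    normalised so its maximum over the circle equals 1.  Somatosensory
    sources use one dorsal, side-shifted bump; motor sources use a
    ventrolateral + lateral pair.  Left/right profiles of the same
    modality are mirror images through the dorsal midline (0 deg).
    """

    label: str
    hotspot_angles_deg: tuple[float, ...]
    concentration: float = 10.0
    relative_amplitudes: tuple[float, ...] | None = None
    # optional delayed secondary component, modelling a later-arriving
    # volley whose hotspot sits elsewhere (topography shifting with time)
    secondary_angles_deg: tuple[float, ...] | None = None
    secondary_delay_ms: float = 0.0
    secondary_scale: float = 0.0

    def __post_init__(self):
        if self.relative_amplitudes is None:
            self.relative_amplitudes = tuple(1.0 for _ in self.hotspot_angles_deg)
        if len(self.relative_amplitudes) != len(self.hotspot_angles_deg):
            raise ValidationError("relative_amplitudes must match hotspot_angles_deg")

    def mirrored(self, label: str) -> "SourceProfile":
        """The left/right mirror image through the 0-deg (dorsal) axis."""
        return SourceProfile(
            label=label,
            hotspot_angles_deg=tuple(wrap_angle_deg(-a) for a in self.hotspot_angles_deg),
            concentration=self.concentration,
            relative_amplitudes=self.relative_amplitudes,
            secondary_angles_deg=None
            if self.secondary_angles_deg is None
            else tuple(wrap_angle_deg(-a) for a in self.secondary_angles_deg),
            secondary_delay_ms=self.secondary_delay_ms,
            secondary_scale=self.secondary_scale,
        )

    def gain_function(self, angles_deg: np.ndarray) -> np.ndarray:
        return _bump_mixture(
            np.asarray(angles_deg, dtype=float),
            self.hotspot_angles_deg,
            self.concentration,
            self.relative_amplitudes,
        )


def _bump_mixture(angles_deg, centers_deg, kappa, rel_amps):
    theta = np.deg2rad(angles_deg)
    g = np.zeros_like(theta, dtype=float)
    for c, a in zip(centers_deg, rel_amps):
        g += a * np.exp(kappa * (np.cos(theta - np.deg2rad(c)) - 1.0))
    # normalise so the max over the *circle* (dense grid) is 1, making the
    # profile independent of where electrodes happen to sit
    grid = np.deg2rad(np.arange(-180.0, 180.0, 0.05))
    gmax = np.zeros_like(grid)
    for c, a in zip(centers_deg, rel_amps):
        gmax += a * np.exp(kappa * (np.cos(grid - np.deg2rad(c)) - 1.0))
    return g / gmax.max()


@dataclass
class ECAPTemplate:
    """Parametric biphasic evoked waveform with a dominant positive phase.

    A difference of two centred Gaussians (narrow positive core minus a
    wider, lower surround with equal integral) gives a zero-integral,
    positive-peaked pulse.  The peak is normalised to 1 and scaled by
    ``amplitude_uV`` at sampling time.
    """

    duration_ms: float = 4.0
    latency_s: float = 0.0015
    amplitude_uV: float = 50.0
    core_fraction: float = 0.10  # sigma of the positive core / duration

    def sample(self, sample_rate: float) -> tuple[np.ndarray, int]:
        """Return (waveform, index of the positive peak)."""
        n = int(round(self.duration_ms / 1000.0 * sample_rate))
        n = max(n, 3)
        t = (np.arange(n) - (n - 1) / 2.0) / sample_rate
        s1 = self.core_fraction * self.duration_ms / 1000.0
        s2 = 2.5 * s1
        core = np.exp(-(t**2) / (2 * s1**2))
        surround = np.exp(-(t**2) / (2 * s2**2))
        # balance the truncated lobes exactly so the pulse integrates to 0
        w = core - (core.sum() / surround.sum()) * surround
        w = w / w.max()
        return self.amplitude_uV * w, int(np.argmax(w))


@dataclass
class GroundTruth:
    """Hidden generator parameters, one row per emitted event."""

    labels: list[str]
    event_times_s: np.ndarray
    peak_times_s: np.ndarray
    hotspot_angles_deg: list[tuple[float, ...]]
    clean_peak_uV: np.ndarray  # events x channels
    conduction_latency_s: float
    ecg_beat_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "event_time_s": self.event_times_s,
                "peak_time_s": self.peak_times_s,
                "hotspot_angles_deg": [
                    ";".join(f"{a:.3f}" for a in angs) for angs in self.hotspot_angles_deg
                ],
            }
        )
        for c in range(self.clean_peak_uV.shape[1]):
            df[f"clean_peak_uV_ch{c:02d}"] = self.clean_peak_uV[:, c]
        return df


def make_layout(n_electrodes: int, coverage_fraction: float = 1.0) -> ElectrodeLayout:
    """Evenly spaced circumferential layout with one electrode at 0 deg.

    For full coverage the spacing is ``360 / n`` degrees and the array
    wraps the whole circumference; for partial coverage the electrodes
    span ``coverage_fraction * 360`` degrees centred on the dorsal
    midline.
    """
    if n_electrodes < 2:
        raise ValidationError(f"need at least 2 electrodes, got {n_electrodes}")
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValidationError(f"coverage_fraction must be in (0, 1], got {coverage_fraction}")
    spacing = coverage_fraction * 360.0 / n_electrodes
    midline = n_electrodes // 2
    angles = (np.arange(n_electrodes) - midline) * spacing
    angles = wrap_angle_deg(angles)
    return ElectrodeLayout(
        angles_deg=angles,
        midline_index=midline,
        coverage_fraction=coverage_fraction,
    )


def source_gains(profile: SourceProfile, layout: ElectrodeLayout) -> np.ndarray:
    """Per-channel gain in [0, 1] of ``profile`` sampled at the electrodes."""
    return profile.gain_function(layout.angles_deg)


def default_profiles() -> dict[str, SourceProfile]:
    """Source profiles used by the default synthetic sessions.

    Somatosensory (SSEP) sources sit dorsally, shifted ~20 deg toward the
    stimulated side (the dorsal-column entry zone); tibial and peroneal
    sub-sources are two nearby dorsal hotspots on the same side.  Motor
    (MEP) sources pair a ventrolateral bump with a weaker lateral one.
    All right-side profiles are mirrors of the left.
    """
    ssep_l = SourceProfile("SSEP_L", (20.0,), concentration=10.0)
    mep_l = SourceProfile(
        "MEP_L", (135.0, 90.0), concentration=12.0, relative_amplitudes=(1.0, 0.8)
    )
    return {
        "SSEP_L": ssep_l,
        "SSEP_R": ssep_l.mirrored("SSEP_R"),
        "MEP_L": mep_l,
        "MEP_R": mep_l.mirrored("MEP_R"),
        "TIBIAL": SourceProfile("TIBIAL", (15.0,), concentration=10.0),
        "PERONEAL": SourceProfile("PERONEAL", (45.0,), concentration=10.0),
    }


def _event_schedule(cfg: GeneratorConfig) -> tuple[np.ndarray, list[str]]:
    times = np.arange(cfg.first_event_s, cfg.duration_s - 0.05, cfg.isi_s)
    labels = [cfg.schedule[i % len(cfg.schedule)] for i in range(times.size)]
    if times.size == 0:
        raise ValidationError("event schedule is empty; duration too short")
    if times[-1] >= cfg.duration_s:
        raise ValidationError("schedule extends beyond the recording duration")
    return times, labels


def simulate_session(
    cfg: GeneratorConfig,
    seed: int = 0,
    profiles: dict[str, SourceProfile] | None = None,
    layout: ElectrodeLayout | None = None,
) -> tuple[Recording, EventTable, GroundTruth]:
    """Simulate one stimulation session.

    The recording is the sum of clean evoked responses (template x
    per-channel hotspot gains, delayed by the conduction latency) and the
    configured noise terms.  Noise realisations are drawn from seed
    substreams that do not depend on the event schedule, so recordings
    with different schedules share the same noise background for a given
    seed (which makes the generator additive in its events).
    """
    if profiles is None:
        profiles = default_profiles()
    if layout is None:
        layout = make_layout(cfg.n_electrodes, cfg.coverage_fraction)
    fs = cfg.sample_rate_hz
    n_samples = int(round(cfg.duration_s * fs))
    n_ch = layout.n_electrodes

    ss = np.random.SeedSequence(seed)
    rng_amp, rng_ecg, rng_resp, rng_line, rng_white = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    event_times, labels = _event_schedule(cfg)
    # fill the (large) data array in place: white noise first, everything
    # else added on top, avoiding full-size temporaries
    data = np.empty((n_ch, n_samples), dtype=float)
    if cfg.white_sigma_uV > 0:
        rng_white.standard_normal(out=data)
        data *= cfg.white_sigma_uV
    else:
        data.fill(0.0)

    # --- clean evoked responses -------------------------------------------
    latency = cfg.conduction_latency_ms / 1000.0
    template = ECAPTemplate(
        duration_ms=cfg.ecap_duration_ms, latency_s=latency, amplitude_uV=1.0
    )
    wave, peak_idx = template.sample(fs)
    clean_peaks = np.zeros((len(event_times), n_ch))
    peak_times = np.zeros(len(event_times))
    hotspots: list[tuple[float, ...]] = []
    jitter = rng_amp.uniform(1.0 - cfg.amplitude_jitter, 1.0 + cfg.amplitude_jitter,
                             size=len(event_times))
    gain_cache: dict[str, np.ndarray] = {}
    for e, (t_e, lab) in enumerate(zip(event_times, labels)):
        prof = profiles[lab]
        if lab not in gain_cache:
            gain_cache[lab] = source_gains(prof, layout)
        gains = gain_cache[lab]
        amp = cfg.ecap_amplitude_uV * jitter[e]
        peak_sample = int(round((t_e + latency) * fs))
        start = peak_sample - peak_idx
        _add_pulse(data, amp * gains, wave, start)
        if prof.secondary_angles_deg is not None and prof.secondary_scale > 0:
            sec = SourceProfile(
                lab, prof.secondary_angles_deg, prof.concentration
            )
            g2 = source_gains(sec, layout)
            start2 = start + int(round(prof.secondary_delay_ms / 1000.0 * fs))
            _add_pulse(data, amp * prof.secondary_scale * g2, wave, start2)
        clean_peaks[e] = amp * gains
        peak_times[e] = peak_sample / fs
        hotspots.append(tuple(prof.hotspot_angles_deg))

    # --- noise terms (assembled once in a single-channel buffer, then
    # broadcast onto every channel: all are common-source artifacts) -------
    t = np.arange(n_samples) / fs
    common = np.zeros(n_samples)
    ecg_beats = np.empty(0)
    if cfg.ecg_amplitude_uV > 0:
        beat_period = 1.0 / cfg.ecg_rate_hz
        phase = rng_ecg.uniform(0, beat_period)
        ecg_beats = np.arange(phase, cfg.duration_s, beat_period)
        width = cfg.ecg_width_ms / 1000.0
        half = int(round(3 * width * fs))
        pulse = ricker((np.arange(2 * half + 1) - half) / fs, width)
        for tb in ecg_beats:
            _add_pulse_1d(common, cfg.ecg_amplitude_uV * pulse, int(round(tb * fs)) - half)
    if cfg.resp_amplitude_uV > 0:
        phase = rng_resp.uniform(0, 2 * np.pi)
        common += cfg.resp_amplitude_uV * np.sin(2 * np.pi * cfg.resp_rate_hz * t + phase)
    if cfg.line_amplitude_uV > 0:
        phase = rng_line.uniform(0, 2 * np.pi)
        common += cfg.line_amplitude_uV * np.sin(2 * np.pi * cfg.line_freq_hz * t + phase)
    if np.any(common):
        data += common
    if cfg.stim_artifact_amplitude_uV > 0:
        n_art = max(int(round(cfg.stim_artifact_duration_ms / 1000.0 * fs)), 2)
        art = cfg.stim_artifact_amplitude_uV * np.sin(
            2 * np.pi * np.arange(n_art) / n_art
        )
        for t_e in event_times:
            _add_pulse_1d_broadcast(data, art, int(round(t_e * fs)))

    recording = Recording(
        data=data,
        sample_rate=fs,
        layout=layout,
        annotations={"generator_seed": int(seed)},
    )
    events = EventTable(
        time_s=event_times,
        label=labels,
        stim_amplitude_uA=np.full(len(event_times), cfg.stim_amplitude_uA),
    )
    truth = GroundTruth(
        labels=labels,
        event_times_s=event_times,
        peak_times_s=peak_times,
        hotspot_angles_deg=hotspots,
        clean_peak_uV=clean_peaks,
        conduction_latency_s=latency,
        ecg_beat_times_s=ecg_beats,
        seed=seed,
    )
    return recording, events, truth


def _add_pulse(data: np.ndarray, gains: np.ndarray, wave: np.ndarray, start: int) -> None:
    """Add gains[:, None] * wave into data at sample offset start, clipped."""
    n = data.shape[1]
    lo, hi = max(start, 0), min(start + wave.size, n)
    if lo >= hi:
        return
    data[:, lo:hi] += gains[:, None] * wave[lo - start : hi - start]


def _add_pulse_1d(series: np.ndarray, wave: np.ndarray, start: int) -> None:
    n = series.size
    lo, hi = max(start, 0), min(start + wave.size, n)
    if lo >= hi:
        return
    series[lo:hi] += wave[lo - start : hi - start]


def _add_pulse_1d_broadcast(data: np.ndarray, wave: np.ndarray, start: int) -> None:
    n = data.shape[1]
    lo, hi = max(start, 0), min(start + wave.size, n)
    if lo >= hi:
        return
    data[:, lo:hi] += wave[lo - start : hi - start]
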