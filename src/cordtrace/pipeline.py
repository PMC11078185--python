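"""End-to-end convenience chains over the stage modules.

These helpers wire referencing -> notch -> denoising -> detection ->
peak-amplitude mapping -> classification in the default order, so tests,
the CLI and downstream scripts all exercise the same path.
"""

from __future__ import annotations

import numpy as np

from . import classify as clf
from . import synth
from .config import SessionConfig
from .preprocess import epoch, notch_filter, reference_channels
from .topomap import peak_amplitudes
from .types import ElectrodeLayout, Epochs, EventTable, Recording
from .wavelet import DetectedSpike, detect_session


def default_dormant_channels(
    layout: ElectrodeLayout,
    profiles: dict[str, synth.SourceProfile] | None = None,
    labels: tuple[str, ...] | None = None,
    gain_threshold: float = 0.15,
) -> tuple[int, ...]:
    """Channels expected to stay response-free across the session's sources.

    A channel is dormant when its hotspot gain is below ``gain_threshold``
    for every source in the schedule; on the default full-coverage layout
    these are the electrodes near the ventral midline, between the two
    motor territories.  Falls back to the single least-driven channel if
    no channel clears the threshold.
    """
    if profiles is None:
        profiles = synth.default_profiles()
    if labels is None:
        labels = tuple(profiles.keys())
    gains = np.max(
        [synth.source_gains(profiles[l], layout) for l in labels], axis=0
    )
    idx = np.nonzero(gains < gain_threshold)[0]
    if idx.size == 0:
        idx = np.asarray([int(np.argmin(gains))])
    return tuple(int(i) for i in idx)


def preprocess_session(
    recording: Recording,
    cfg: SessionConfig,
) -> Recording:
    """Reference to the configured dormant set, then notch-filter."""
    pp = cfg.preprocess
    dormant = pp.dormant_channels
    if not dormant and recording.layout is not None:
        dormant = default_dormant_channels(recording.layout)
    out = reference_channels(recording, dormant, scheme=pp.reference_scheme)
    if pp.notch:
        out = notch_filter(out, pp.notch_freq_hz, pp.notch_q)
    return out


def session_peak_map(
    recording: Recording,
    events: EventTable,
    cfg: SessionConfig | None = None,
) -> tuple[np.ndarray, Epochs, list[DetectedSpike]]:
    """Full detection chain: preprocess, denoise, detect, map peaks.

    Returns the events x channels peak-amplitude map, the epochs it is
    indexed against, and the pooled detected spikes.
    """
    if cfg is None:
        cfg = SessionConfig()
    processed = preprocess_session(recording, cfg)
    spikes, denoised, _ = detect_session(processed, cfg.denoise, cfg.detect)
    epochs = epoch(denoised, events, cfg.preprocess.epoch_window_s)
    return peak_amplitudes(epochs, spikes), epochs, spikes


def classify_session(
    peak_map: np.ndarray,
    labels: list[str],
    cfg: SessionConfig | None = None,
    seed: int | None = None,
) -> clf.ClassificationResult:
    """Binarize, split 60/40 stratified, and run KNN classification."""
    if cfg is None:
        cfg = SessionConfig()
    if seed is None:
        seed = cfg.seed
    features = clf.binarize(peak_map)
    tr, te = clf.split(labels, cfg.classify.train_fraction, seed)
    return clf.knn_classify(
        features.values[tr],
        [labels[i] for i in tr],
        features.values[te],
        [labels[i] for i in te],
        k=cfg.classify.k,
        metric=cfg.classify.metric,
    )
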