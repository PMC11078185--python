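"""Structured configuration for every pipeline stage.

A :class:`SessionConfig` bundles one sub-config per stage plus a global
random seed; every stochastic operation in the pipeline draws from
generators derived from that seed, so identical configs give identical
outputs end to end.  Configs round-trip through a single JSON document.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field


@dataclass
class GeneratorConfig:
    """Synthetic-session parameters.

    Defaults emulate the in vivo acquisition conditions: 32 circumferential
    channels at 30 kHz, ~70 s sessions with 1 s between stimulation pulses,
    alternating left/right SSEP/MEP sources, and a peak signal-to-noise
    ratio of 5 (50 uV evoked peak over 10 uV white noise).
    """

    sample_rate_hz: float = 30_000.0
    duration_s: float = 70.0
    isi_s: float = 1.0
    first_event_s: float = 0.5
    schedule: tuple[str, ...] = ("SSEP_L", "MEP_L", "SSEP_R", "MEP_R")
    n_electrodes: int = 32
    coverage_fraction: float = 1.0
    stim_amplitude_uA: float = 100.0
    # evoked waveform
    ecap_amplitude_uV: float = 50.0
    ecap_duration_ms: float = 4.0
    conduction_latency_ms: float = 1.5
    amplitude_jitter: float = 0.10
    # noise model
    ecg_rate_hz: float = 6.0
    ecg_amplitude_uV: float = 20.0
    ecg_width_ms: float = 5.0
    resp_rate_hz: float = 1.0
    resp_amplitude_uV: float = 15.0
    line_freq_hz: float = 50.0
    line_amplitude_uV: float = 5.0
    white_sigma_uV: float = 10.0
    stim_artifact_amplitude_uV: float = 30.0
    stim_artifact_duration_ms: float = 0.5


@dataclass
class PreprocessConfig:
    dormant_channels: tuple[int, ...] = ()
    reference_scheme: str = "mean"  # "mean" | "single"
    notch: bool = True
    notch_freq_hz: float = 50.0
    notch_q: float = 30.0
    epoch_window_s: tuple[float, float] = (0.0, 0.020)


@dataclass
class DenoiseConfig:
    wavelet: str = "db5"
    levels: int = 3
    variant: str = "swt"  # stationary (undecimated) | "dwt" (decimated)
    boundary: str = "symmetric"


@dataclass
class DetectConfig:
    refractory_ms: float = 4.0
    window_ms: float = 4.0
    polarity: str = "positive"  # "positive" | "signed"


@dataclass
class ClassifyConfig:
    k: int = 1
    metric: str = "cityblock"
    train_fraction: float = 0.60


@dataclass
class BypassConfig:
    threshold_uV: float = 20.0
    gain: float = 10.0
    refractory_ms: float = 100.0
    source_channel: int = 0
    loop_delay_ms: float = 0.2
    proximal_latency_ms: float = 0.8
    conduction_latency_ms: float = 1.5
    injury_time_s: float = 35.0


@dataclass
class SessionConfig:
    """Top-level configuration: one block per stage plus a global seed."""

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    bypass: BypassConfig = field(default_factory=BypassConfig)

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        doc = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source: str | os.PathLike) -> "SessionConfig":
        """Load from a JSON file path or a JSON string."""
        if os.path.exists(str(source)):
            with open(source) as f:
                raw = json.load(f)
        else:
            raw = json.loads(str(source))
        kwargs = {}
        for f_ in dataclasses.fields(cls):
            if f_.name not in raw:
                continue
            val = raw[f_.name]
            if dataclasses.is_dataclass(f_.type) or f_.name in (
                "generator",
                "preprocess",
                "denoise",
                "detect",
                "classify",
                "bypass",
            ):
                sub_cls = {
                    "generator": GeneratorConfig,
                    "preprocess": PreprocessConfig,
                    "denoise": DenoiseConfig,
                    "detect": DetectConfig,
                    "classify": ClassifyConfig,
                    "bypass": BypassConfig,
                }[f_.name]
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in val.items()}
                kwargs[f_.name] = sub_cls(**sub)
            else:
                kwargs[f_.name] = val
        return cls(**kwargs)
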