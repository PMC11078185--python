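"""Topographic mapping: peak maps, interpolation, hotspot localisation."""

import numpy as np
import pytest

from cordtrace import EventTable, Recording, ValidationError
from cordtrace.preprocess import epoch
from cordtrace import synth
from cordtrace.topomap import (
    build_topoframe,
    find_hotspot,
    peak_amplitudes,
    temporal_evolution,
)
from cordtrace.wavelet import DetectedSpike
from conftest import make_noiseless
from cordtrace.config import GeneratorConfig


def _epochs(n_events=2, n_ch=4, fs=1000.0):
    rec = Recording(data=np.zeros((n_ch, 2000)), sample_rate=fs)
    events = EventTable(
        time_s=np.arange(n_events) * 0.5 + 0.25,
        label=["MEP_L"] * n_events,
        stim_amplitude_uA=[1] * n_events,
    )
    return epoch(rec, events, (0.0, 0.02))


def _spike(channel, t, amp):
    return DetectedSpike(channel=channel, peak_time_s=t, peak_amplitude_uV=amp,
                         waveform=np.zeros(4))


class TestPeakAmplitudes:
    def test_no_spikes_all_zero(self):
        ep = _epochs()
        assert not peak_amplitudes(ep, []).any()

    def test_spike_lands_in_its_event_window(self):
        ep = _epochs()
        out = peak_amplitudes(ep, [_spike(2, 0.255, 7.0)])
        assert out[0, 2] == 7.0
        assert out.sum() == 7.0

    def test_two_spikes_larger_recorded(self):
        ep = _epochs()
        out = peak_amplitudes(ep, [_spike(1, 0.251, 3.0), _spike(1, 0.256, 9.0)])
        assert out[0, 1] == 9.0

    def test_noiseless_session_map_matches_ground_truth(self, tiny_noiseless):
        from cordtrace.config import SessionConfig
        from cordtrace.pipeline import session_peak_map

        cfg = SessionConfig()
        cfg.generator = tiny_noiseless
        rec, events, truth = synth.simulate_session(tiny_noiseless, seed=0)
        peak_map, epochs, _ = session_peak_map(rec, events, cfg)
        for e in range(peak_map.shape[0]):
            ch = int(np.argmax(truth.clean_peak_uV[e]))
            assert peak_map[e, ch] == pytest.approx(
                truth.clean_peak_uV[e, ch], rel=0.15
            )

    def test_bad_channel_rejected(self):
        ep = _epochs(n_ch=2)
        with pytest.raises(ValidationError):
            peak_amplitudes(ep, [_spike(5, 0.251, 1.0)])


class TestBuildTopoframe:
    def test_uniform_values_flat_frame(self, layout32):
        frame = build_topoframe(np.full(32, 4.2), layout32)
        np.testing.assert_allclose(frame.amplitude_uV, 4.2)

    def test_single_active_electrode(self, layout32):
        v = np.zeros(32)
        v[5] = 1.0
        frame = build_topoframe(v, layout32)
        assert frame.angles_deg[np.argmax(frame.amplitude_uV)] == pytest.approx(
            layout32.angles_deg[5]
        )

    def test_midpoint_linear_interpolation(self):
        lay = synth.make_layout(4, 1.0)
        v = np.zeros(4)
        i90 = int(np.argmin(np.abs(lay.angles_deg - 90.0)))
        i0 = lay.midline_index
        v[i0], v[i90] = 2.0, 4.0
        frame = build_topoframe(v, lay, grid_step_deg=1.0)
        k = int(np.argmin(np.abs(frame.angles_deg - 45.0)))
        assert frame.amplitude_uV[k] == pytest.approx(3.0)

    def test_passes_through_electrode_values(self, layout32, rng):
        v = rng.uniform(0, 5, 32)
        frame = build_topoframe(v, layout32, grid_step_deg=0.7)
        for a, val in zip(layout32.angles_deg, v):
            k = int(np.argmin(np.abs(frame.angles_deg - a)))
            assert frame.amplitude_uV[k] == pytest.approx(val, abs=1e-9)

    def test_interpolation_bounded_by_inputs(self, layout32, rng):
        v = rng.uniform(1, 3, 32)
        frame = build_topoframe(v, layout32)
        assert frame.amplitude_uV.min() >= v.min() - 1e-12
        assert frame.amplitude_uV.max() <= v.max() + 1e-12

    def test_bad_grid_step(self, layout32):
        with pytest.raises(ValidationError):
            build_topoframe(np.zeros(32), layout32, grid_step_deg=0.0)


class TestFindHotspot:
    def test_von_mises_bump_located(self, layout32):
        prof = synth.SourceProfile("SSEP_L", (-120.0,), concentration=10.0)
        frame = build_topoframe(synth.source_gains(prof, layout32), layout32)
        hs = find_hotspot(frame)
        assert hs.found
        # linear interpolation peaks at the electrode nearest the bump
        assert abs(synth.wrap_angle_deg(hs.angle_deg + 120.0)) <= layout32.spacing_deg / 2

    def test_dual_hotspot_mep(self, layout32):
        prof = synth.default_profiles()["MEP_L"]
        frame = build_topoframe(synth.source_gains(prof, layout32), layout32)
        hs = find_hotspot(frame, n_hotspots=2)
        angles = sorted([hs.angle_deg, hs.secondary_angle_deg])
        assert angles[0] == pytest.approx(90.0, abs=layout32.spacing_deg)
        assert angles[1] == pytest.approx(135.0, abs=layout32.spacing_deg)

    def test_flat_frame_flagged(self, layout32):
        frame = build_topoframe(np.zeros(32), layout32)
        hs = find_hotspot(frame)
        assert not hs.found and hs.angle_deg is None


class TestTemporalEvolution:
    def test_static_source_constant_hotspot(self, layout32):
        cfg = make_noiseless(GeneratorConfig(sample_rate_hz=2000.0, duration_s=4.0))
        rec, events, _ = synth.simulate_session(cfg, seed=0)
        ep = epoch(rec, events, (0.0, 0.004))
        sel = [i for i, l in enumerate(ep.labels) if l == "SSEP_L"]
        frames = temporal_evolution(ep, rec.layout, step_ms=1.0, event_indices=sel)
        assert len(frames) == 4
        peak = max(f.amplitude_uV.max() for f in frames)
        active = [f for f in frames if f.amplitude_uV.max() > 0.2 * peak]
        angles = [find_hotspot(f).angle_deg for f in active]
        assert len(active) >= 1
        assert np.ptp(angles) <= layout32.spacing_deg

    def test_switching_source_moves_hotspot(self):
        """A delayed secondary volley shifts the topographic hotspot."""
        cfg = make_noiseless(GeneratorConfig(
            sample_rate_hz=2000.0, duration_s=4.0, schedule=("SSEP_L",),
            ecap_duration_ms=2.0, conduction_latency_ms=1.0,
        ))
        profiles = synth.default_profiles()
        profiles["SSEP_L"] = synth.SourceProfile(
            "SSEP_L", (20.0,), concentration=15.0,
            secondary_angles_deg=(-120.0,), secondary_delay_ms=4.0, secondary_scale=1.0,
        )
        rec, events, _ = synth.simulate_session(cfg, seed=0, profiles=profiles)
        ep = epoch(rec, events, (0.0, 0.008))
        frames = temporal_evolution(ep, rec.layout, step_ms=2.0)
        # primary peak sits at 1 ms (frame 0), secondary at 5 ms (frame 2)
        early = find_hotspot(frames[0]).angle_deg
        late = find_hotspot(frames[2]).angle_deg
        assert abs(synth.wrap_angle_deg(early - 20.0)) <= rec.layout.spacing_deg
        assert abs(synth.wrap_angle_deg(late + 120.0)) <= rec.layout.spacing_deg

    def test_step_equals_window_single_frame(self, layout32):
        ep = _epochs(n_ch=32)
        frames = temporal_evolution(ep, layout32, step_ms=20.0)
        assert len(frames) == 1

    def test_step_larger_than_window_rejected(self, layout32):
        ep = _epochs(n_ch=32)
        with pytest.raises(ValidationError):
            temporal_evolution(ep, layout32, step_ms=100.0)


def test_rotation_equivariance_of_recovered_hotspot(layout32):
    """Rotating the source rotates the recovered hotspot angle with it."""
    base = 20.0
    for delta in np.arange(0.0, 360.0, 30.0):
        target = synth.wrap_angle_deg(base + delta)
        prof = synth.SourceProfile("SSEP_L", (float(target),), concentration=10.0)
        frame = build_topoframe(synth.source_gains(prof, layout32), layout32)
        hs = find_hotspot(frame)
        assert abs(synth.wrap_angle_deg(hs.angle_deg - target)) <= layout32.spacing_deg
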