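"""Induction protocols, phase maps and episode classification."""

import numpy as np
import pytest

from atrisim.induction import (
    EndpointRecord, InductionConfig, InductionProtocol, burst_schedule,
    classify_episode, screen_single_stimulus, spiral_initial_condition,
    spiral_phase_map,
)
from atrisim.ionic import DomainError, REFERENCE_ELECTROLYTES
from atrisim.monodomain import Geometry2D, TissueResult
from atrisim.substrate import SubstrateConfig, build_substrate, generate_iir_field


class TestBurstSchedule:
    def test_default_timing(self):
        """Five S1 at CL 700 (0..2800 ms), 400-ms pause from the last S1,
        then five burst stimuli at CL 160 (3200..3840 ms)."""
        s1, burst = burst_schedule()
        assert s1 == [0.0, 700.0, 1400.0, 2100.0, 2800.0]
        assert burst == [3200.0, 3360.0, 3520.0, 3680.0, 3840.0]

    def test_schedule_strictly_increasing(self):
        s1, burst = burst_schedule()
        sched = s1 + burst
        assert all(b > a for a, b in zip(sched, sched[1:]))

    def test_tracking_window_is_5_seconds(self):
        assert InductionConfig().track_ms == 5000.0


class TestSpiralPhaseMap:
    @pytest.fixture(scope="class")
    def geom(self):
        return Geometry2D(nx=101, ny=101, spacing_um=500.0)

    def test_phase_range(self, geom):
        ph = spiral_phase_map(geom)
        assert ph.min() >= 0.0 and ph.max() < 2.0 * np.pi

    def test_four_cores_alternating_chirality(self, geom):
        """Winding number of the phase around each of the 4 cores is +-1
        with opposite signs for adjacent cores."""
        ph = spiral_phase_map(geom).reshape(101, 101)

        def winding(cx, cy, r=6):
            ang = np.linspace(0, 2 * np.pi, 200, endpoint=False)
            ix = (cx + r * np.cos(ang)).astype(int)
            iy = (cy + r * np.sin(ang)).astype(int)
            d = np.diff(ph[iy, ix])
            d = np.mod(d + np.pi, 2 * np.pi) - np.pi
            return int(np.round(d.sum() / (2 * np.pi)))

        w = {(qx, qy): winding(25 + 50 * qx, 25 + 50 * qy)
             for qx in (0, 1) for qy in (0, 1)}
        assert all(abs(v) == 1 for v in w.values())
        assert w[(0, 0)] == -w[(1, 0)] == -w[(0, 1)] == w[(1, 1)]

    def test_small_sheet_rejected(self):
        cfg = SubstrateConfig(size_cm=2.0)
        iir, t = generate_iir_field(cfg, 1, target_fraction=0.1)
        sub = build_substrate(iir, cfg, target_fraction=t)
        with pytest.raises(DomainError):
            spiral_initial_condition(sub, REFERENCE_ELECTROLYTES)

    def test_unknown_protocol_kind_rejected(self):
        with pytest.raises(DomainError):
            InductionProtocol("burst_everywhere")


def _synthetic_result(act_times_ms, n_nodes=100, t_final=0.0,
                      track_ms=5000.0, quiescent=True):
    """TissueResult with prescribed activation times on every node."""
    max_ev = 64
    at = np.full((n_nodes, max_ev), np.nan)
    counts = np.zeros(n_nodes, dtype=np.int64)
    for node in range(n_nodes):
        ts = np.asarray(act_times_ms, dtype=float)
        at[node, :ts.size] = ts
        counts[node] = ts.size
    fmax = np.full(n_nodes, -80.0 if quiescent else -20.0)
    geom = Geometry2D(nx=10, ny=10, spacing_um=500.0)
    return TissueResult(geom, np.empty(0), None, 0.05, at, counts, fmax,
                        meta={"t_final_stimulus": t_final,
                              "t_end": t_final + track_ms})


class TestClassifyEpisode:
    def test_quiescent_recording_not_induced(self):
        rec = classify_episode(_synthetic_result([]), "four_spirals")
        assert not rec.induced_any
        assert rec.terminated is None
        assert np.isnan(rec.dominant_frequency_hz)

    def test_periodic_train_at_200ms_is_5_hz(self):
        times = list(np.arange(100.0, 1900.0, 200.0))
        rec = classify_episode(_synthetic_result(times), "four_spirals")
        assert rec.induced_any
        assert rec.dominant_frequency_hz == pytest.approx(5.0, abs=1e-9)

    def test_terminated_episode(self):
        """Activity confined to the first second of the window with a
        repolarised final state counts as terminated."""
        times = list(np.arange(100.0, 1000.0, 180.0))
        rec = classify_episode(_synthetic_result(times, quiescent=True),
                               "four_spirals")
        assert rec.induced_any and rec.terminated

    def test_sustained_episode_not_terminated(self):
        times = list(np.arange(100.0, 5000.0, 180.0))
        rec = classify_episode(_synthetic_result(times, quiescent=False),
                               "four_spirals")
        assert rec.induced_any and rec.terminated is False

    def test_slow_rhythm_not_arrhythmia(self):
        """Three activations at a 700-ms cycle length (paced rhythm) do not
        classify as an induced arrhythmia."""
        rec = classify_episode(_synthetic_result([100.0, 800.0, 1500.0]),
                               "four_spirals")
        assert not rec.induced_any

    def test_site_flags_follow_protocol(self):
        times = list(np.arange(100.0, 2000.0, 150.0))
        rec_laa = classify_episode(_synthetic_result(times), "burst_LAA")
        rec_ar = classify_episode(_synthetic_result(times), "burst_roof")
        assert rec_laa.induced_LAA and not rec_laa.induced_AR
        assert rec_ar.induced_AR and not rec_ar.induced_LAA
        assert rec_laa.induced_any == (rec_laa.induced_LAA or rec_laa.induced_AR)

    def test_short_window_rejected(self):
        res = _synthetic_result([100.0], track_ms=1000.0)
        with pytest.raises(DomainError):
            classify_episode(res, "four_spirals")


class TestScreenSingleStimulus:
    def test_healthy_baseline_not_self_sustaining(self):
        cfg = SubstrateConfig(size_cm=2.0)
        iir, _ = generate_iir_field(cfg, 3, target_fraction=0.0)
        sub = build_substrate(iir, cfg, target_fraction=0.0)
        icfg = InductionConfig(n_prepace=30)
        assert screen_single_stimulus(sub, REFERENCE_ELECTROLYTES, icfg,
                                      persist_ms=500.0) is False
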