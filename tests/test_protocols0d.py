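"""Pacing, limit-cycle attainment and AP biomarker extraction."""

import numpy as np
import pytest

from atrisim.ionic import CellParameters, ElectrolyteSet, REFERENCE_ELECTROLYTES, rest_state
from atrisim.protocols0d import (
    PacingSpec, Trace, ap_biomarkers, integrate_adaptive, limit_cycle_ap,
    prepace, record_ap,
)

# limit-cycle APD90 of the healthy baseline AP (CL 1000 ms, 100-beat train),
# cross-checked against an independent adaptive-solver re-integration below
GOLDEN_APD90_MS = 287.07


class TestPacingSpec:
    def test_15_minutes_at_cl_1000_is_900_beats(self):
        assert PacingSpec.minutes(15, 1000.0).beats == 900

    def test_invalid_specs_rejected(self):
        from atrisim.ionic import DomainError
        with pytest.raises(DomainError):
            PacingSpec(cl_ms=1.0, n_beats=1)  # CL <= stimulus width
        with pytest.raises(DomainError):
            PacingSpec(cl_ms=500.0)           # no duration


class TestPrepace:
    def test_zero_duration_returns_initial_state(self, healthy_params):
        y0 = rest_state()
        res = prepace(healthy_params, REFERENCE_ELECTROLYTES,
                      PacingSpec(cl_ms=1000.0, n_beats=0), initial=y0)
        assert np.array_equal(res.state, y0)

    def test_residual_shrinks_with_training(self, baseline_lc):
        """The limit-cycle residual after 100 beats is below the residual
        after 10 beats (monotone approach to the attractor)."""
        _, _, pre = baseline_lc
        hist = pre.residual_history
        assert hist[-1] < hist[9]
        assert pre.residual == hist[-1]


class TestRecordAp:
    def test_zero_beats_empty_trace(self, healthy_params):
        tr = record_ap(rest_state(), healthy_params, REFERENCE_ELECTROLYTES,
                       PacingSpec(cl_ms=1000.0, n_beats=1), n_beats=0)
        assert tr.t.size == 0

    def test_trace_starts_at_input_state(self, baseline_lc):
        _, trace, pre = baseline_lc
        assert trace.V[0] == pytest.approx(pre.state[0], abs=1e-9)

    def test_beat_to_beat_apd90_stable_at_limit_cycle(self, healthy_params,
                                                      baseline_lc):
        """Successive on-rhythm beats at the limit cycle have APD90 within
        1 ms (the first recorded beat is skipped: its diastolic interval is
        lengthened by the pre-stimulus recording pad)."""
        _, _, pre = baseline_lc
        pacing = PacingSpec(cl_ms=1000.0, n_beats=100)
        tr = record_ap(pre.state, healthy_params, REFERENCE_ELECTROLYTES,
                       pacing, n_beats=3)
        two = ap_biomarkers(Trace(*_beat(tr, 1)))
        three = ap_biomarkers(Trace(*_beat(tr, 2)))
        assert abs(two.apd90 - three.apd90) < 1.0


def _beat(trace, k, cl=1000.0, pre=50.0):
    sel = (trace.t >= k * cl) & (trace.t < pre + (k + 1) * cl - 1.0)
    return trace.t[sel], trace.states[sel]


class TestApBiomarkers:
    def test_trapezoid_pulse_analytic_apd(self):
        """Constructed trapezoid AP with a known 90 %-repolarisation time."""
        t = np.arange(0.0, 400.0, 0.1)
        V = np.full_like(t, -80.0)
        up, top, down = 10.0, 20.0, 300.0
        rising = (t >= up) & (t < up + 1.0)
        V[rising] = -80.0 + 100.0 * (t[rising] - up)
        V[(t >= up + 1.0) & (t < top)] = 20.0
        falling = (t >= top) & (t < down)
        V[falling] = 20.0 - 100.0 * (t[falling] - top) / (down - top)
        bm = ap_biomarkers(Trace(t, np.column_stack([V] + [np.zeros_like(V)] * 20)))
        # 90 % of the 100-mV amplitude is recovered at V = -70 mV
        t_cross = top + 0.9 * (down - top)
        assert bm.apd90 == pytest.approx(t_cross - bm.upstroke_time, abs=0.2)
        assert bm.rmp == -80.0
        assert bm.amplitude == pytest.approx(100.0, abs=0.1)

    def test_golden_apd90_and_adaptive_crosscheck(self, baseline_lc,
                                                  healthy_params):
        """The frozen baseline APD90 reproduces, and an independent
        adaptive-solver re-integration agrees within 2.5 ms."""
        bm, _, pre = baseline_lc
        assert bm.apd90 == pytest.approx(GOLDEN_APD90_MS, abs=0.5)
        tr = integrate_adaptive(pre.state, healthy_params,
                                REFERENCE_ELECTROLYTES, 1050.0,
                                stim_events=[(50.0, 2.0, 23.0)],
                                rtol=1e-8, atol=1e-10)
        bm_ad = ap_biomarkers(tr)
        assert abs(bm.apd90 - bm_ad.apd90) < 2.5

    def test_low_sodium_shortens_apd70(self, baseline_lc, healthy_params):
        bm_base, _, _ = baseline_lc
        bm_low, _, _ = limit_cycle_ap(healthy_params,
                                      ElectrolyteSet(4.5, 105.0, 1.8),
                                      n_prepace=100)
        assert bm_low.apd70 < bm_base.apd70

    def test_no_ap_flagged_invalid(self):
        t = np.arange(0.0, 100.0, 0.1)
        V = -80.0 + 5.0 * np.sin(t / 10.0)  # subthreshold wobble
        bm = ap_biomarkers(Trace(t, np.column_stack([V] + [np.zeros_like(V)] * 20)))
        assert not bm.valid

    def test_time_offset_invariance(self, baseline_lc):
        _, trace, _ = baseline_lc
        bm0 = ap_biomarkers(trace)
        shifted = Trace(trace.t + 1234.5, trace.states)
        bm1 = ap_biomarkers(shifted)
        assert bm1.apd90 == pytest.approx(bm0.apd90, abs=1e-9)
        assert bm1.rmp == bm0.rmp

    def test_trace_csv_with_currents(self, baseline_lc, tmp_path):
        """Golden-trace export: per-current columns recomputed from the
        stored states sum (with sign) to -dV/dt away from the stimulus."""
        import pandas as pd
        _, trace, _ = baseline_lc
        path = tmp_path / "trace.csv"
        trace.to_csv(path, with_currents=True)
        df = pd.read_csv(path)
        assert "INaCa_pA_pF" in df.columns and "V_mV" in df.columns
        assert len(df) == trace.t.size

    def test_output_step_halving(self, healthy_params, baseline_lc):
        """Halving the output step changes APD90 by at most 0.5 ms."""
        _, _, pre = baseline_lc
        pacing = PacingSpec(cl_ms=1000.0, n_beats=100)
        bm_a = ap_biomarkers(record_ap(pre.state, healthy_params,
                                       REFERENCE_ELECTROLYTES, pacing,
                                       out_dt=0.1))
        bm_b = ap_biomarkers(record_ap(pre.state, healthy_params,
                                       REFERENCE_ELECTROLYTES, pacing,
                                       out_dt=0.05))
        assert abs(bm_a.apd90 - bm_b.apd90) <= 0.5
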