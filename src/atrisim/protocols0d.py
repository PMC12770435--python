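"""Single-myocyte pacing protocols and action-potential biomarkers.

Pacing uses a rectangular 2-ms stimulus at twice the diastolic threshold
(the threshold is found once by bisection at reference conditions). A cell is
"pre-paced" with a constant-cycle-length train to approximate a limit cycle;
the residual between the states at the start of the last two beats is
reported (not enforced).

The default integrator is the fixed-step Rush-Larsen scheme of
:mod:`atrisim._kernels` (dt 0.025 ms); :func:`integrate_adaptive` provides a
scipy adaptive-solver path over the same right-hand side, used as an
independent numerical cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels as K
from .ionic import (
    DEFAULT_MASK, CellParameters, CurrentSet, DomainError, ElectrolyteOverrideMask,
    ElectrolyteSet, NumericalError, N_STATES, STATE_NAMES, compute_currents,
    derivatives, rest_state,
)

__all__ = [
    "DEFAULT_DT", "DEFAULT_STIM_AMP", "DEFAULT_STIM_DUR",
    "PacingSpec", "PrepaceResult", "Trace", "APBiomarkers",
    "prepace", "record_ap", "ap_biomarkers", "limit_cycle_ap",
    "diastolic_threshold", "integrate_adaptive",
]

DEFAULT_DT = 0.025          # ms, 0-D fixed-step integration
DEFAULT_STIM_DUR = 2.0      # ms, rectangular pulse
# twice the diastolic threshold found by bisection at reference conditions
# (threshold ~= 11.4 pA/pF for a 2-ms pulse from rest)
DEFAULT_STIM_AMP = 23.0     # pA/pF

# normalisation scales for the limit-cycle residual (per state component)
_RESIDUAL_SCALE = np.array([100.0] + [1.0] * 15 + [14.0, 140.0, 1e-3, 2.0, 2.0])


@dataclass(frozen=True)
class PacingSpec:
    """Constant-cycle-length stimulus train."""

    cl_ms: float
    n_beats: int | None = None
    duration_ms: float | None = None
    stim_amp: float = DEFAULT_STIM_AMP
    stim_dur: float = DEFAULT_STIM_DUR
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if not self.cl_ms > self.stim_dur > 0:
            raise DomainError("need cycle_length > stimulus width > 0")
        if self.n_beats is None and self.duration_ms is None:
            raise DomainError("give n_beats or duration_ms")
        if self.n_beats is not None and self.n_beats < 0:
            raise DomainError("n_beats must be >= 0")
        if self.duration_ms is not None and self.duration_ms < 0:
            raise DomainError("duration_ms must be >= 0")

    @property
    def beats(self) -> int:
        if self.n_beats is not None:
            return int(self.n_beats)
        return int(round(self.duration_ms / self.cl_ms))

    @classmethod
    def minutes(cls, minutes: float, cl_ms: float, **kw) -> "PacingSpec":
        """Train lasting ``minutes`` at cycle length ``cl_ms`` (e.g. the
        standard 15-min pre-pacing train at CL 1000 ms = 900 beats)."""
        return cls(cl_ms=cl_ms, duration_ms=minutes * 60_000.0, **kw)


@dataclass
class PrepaceResult:
    state: np.ndarray
    residual: float
    n_beats: int
    residual_history: np.ndarray  # residual after each beat (len n_beats-1)


def _prepare(params, electrolytes, reference, mask):
    if reference is None:
        reference = electrolytes
    if mask is None:
        mask = DEFAULT_MASK
    elec_pc = mask.resolve(electrolytes, reference)
    return K.prepare_cell(params, elec_pc)


def prepace(params: CellParameters, electrolytes: ElectrolyteSet,
            pacing: PacingSpec, initial: np.ndarray | None = None,
            reference: ElectrolyteSet | None = None,
            mask: ElectrolyteOverrideMask | None = None) -> PrepaceResult:
    """Deliver a pacing train and return the end-of-train state.

    The limit-cycle residual is the max-norm difference between the
    (scale-normalised) states at the start of the last two beats.
    """
    y = rest_state() if initial is None else np.array(initial, dtype=float)
    n = pacing.beats
    if n == 0:
        return PrepaceResult(y, np.nan, 0, np.empty(0))
    gp, aux, veca = _prepare(params, electrolytes, reference, mask)
    tabs = K.build_tables(pacing.dt)
    beat_states = np.empty((n + 1, N_STATES))
    bad = K.pace_cell(y, n, pacing.cl_ms, pacing.dt, pacing.stim_dur,
                      pacing.stim_amp, gp, aux, veca, tabs, beat_states)
    if bad >= 0:
        raise NumericalError(f"solver failure during pre-pacing at beat {bad}")
    diffs = np.abs(np.diff(beat_states, axis=0)) / _RESIDUAL_SCALE
    hist = diffs.max(axis=1)
    return PrepaceResult(y, float(hist[-1]), n, hist)


@dataclass
class Trace:
    """Recorded 0-D trajectory (uniform time grid)."""

    t: np.ndarray                   # ms
    states: np.ndarray              # (nt, 21)
    params: CellParameters | None = None
    elec_pc: np.ndarray | None = None

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    def currents(self) -> dict:
        """Per-sample currents (recomputed from the stored states)."""
        if self.params is None or self.elec_pc is None:
            raise DomainError("trace has no parameter context")
        rows = [compute_currents(s, self.params, self.elec_pc) for s in self.states]
        return {name: np.array([getattr(r, name) for r in rows])
                for name in CurrentSet._fields}

    def to_csv(self, path, with_currents: bool = False) -> None:
        import pandas as pd
        data = {"time_ms": self.t, "V_mV": self.V}
        for i, name in enumerate(STATE_NAMES[1:], start=1):
            data[name] = self.states[:, i]
        if with_currents:
            data.update({f"{k}_pA_pF": v for k, v in self.currents().items()})
        pd.DataFrame(data).to_csv(path, index=False)


def record_ap(state: np.ndarray, params: CellParameters,
              electrolytes: ElectrolyteSet, pacing: PacingSpec,
              n_beats: int = 1, out_dt: float = 0.1, pre_ms: float = 50.0,
              reference: ElectrolyteSet | None = None,
              mask: ElectrolyteOverrideMask | None = None) -> Trace:
    """Record ``n_beats`` stimulated beats densely (default 0.1-ms output).

    The trace starts ``pre_ms`` before the first stimulus so the pre-stimulus
    RMP is observable. ``n_beats = 0`` returns an empty trace.
    """
    if n_beats == 0:
        return Trace(np.empty(0), np.empty((0, N_STATES)))
    y = np.array(state, dtype=float)
    gp, aux, veca = _prepare(params, electrolytes, reference, mask)
    tabs = K.build_tables(pacing.dt)
    t_end = pre_ms + n_beats * pacing.cl_ms
    n_steps = int(round(t_end / pacing.dt))
    out_every = max(1, int(round(out_dt / pacing.dt)))
    ev_start = pre_ms + pacing.cl_ms * np.arange(n_beats, dtype=float)
    ev_dur = np.full(n_beats, pacing.stim_dur)
    ev_amp = np.full(n_beats, pacing.stim_amp)
    out = np.empty((n_steps // out_every + 1, N_STATES))
    bad = K.record_cell(y, n_steps, pacing.dt, ev_start, ev_dur, ev_amp,
                        gp, aux, veca, tabs, out_every, out)
    if bad >= 0:
        raise NumericalError(f"solver failure at t={bad * pacing.dt:.3f} ms")
    t = np.arange(out.shape[0]) * out_every * pacing.dt
    elec_pc = (mask or DEFAULT_MASK).resolve(electrolytes, reference or electrolytes)
    return Trace(t, out, params, elec_pc)


@dataclass
class APBiomarkers:
    """Action-potential biomarkers of a single stimulated beat."""

    rmp: float = np.nan            # mV, pre-upstroke minimum
    apd70: float = np.nan          # ms
    apd90: float = np.nan          # ms
    plateau_peak: float = np.nan   # mV, max V in the post-spike window
    amplitude: float = np.nan      # mV
    dvdt_max: float = np.nan       # mV/ms
    upstroke_time: float = np.nan  # ms
    valid: bool = False


def _apd(t, V, t_up, i_peak, level) -> float:
    """Time from t_up to the first downward crossing of ``level`` after the
    peak (linear interpolation); NaN if never crossed."""
    below = np.flatnonzero(V[i_peak:] <= level)
    if below.size == 0:
        return np.nan
    i = i_peak + below[0]
    if i == 0 or V[i] == V[i - 1]:
        tc = t[i]
    else:
        tc = t[i - 1] + (t[i] - t[i - 1]) * (V[i - 1] - level) / (V[i - 1] - V[i])
    return float(tc - t_up)


def ap_biomarkers(trace: Trace, plateau_window: tuple = (15.0, 200.0),
                  min_amplitude: float = 40.0) -> APBiomarkers:
    """Extract RMP, APD70/90, plateau peak, amplitude and upstroke metrics.

    The trace must contain exactly one stimulated AP. An AP with amplitude
    below ``min_amplitude`` mV is flagged invalid (fields undefined).
    """
    t, V = trace.t, trace.V
    if t.size < 5:
        return APBiomarkers()
    dvdt = np.gradient(V, t)
    i_up = int(np.argmax(dvdt))
    t_up = float(t[i_up])
    pre = V[:i_up] if i_up > 0 else V[:1]
    rmp = float(np.min(pre))
    i_peak = i_up + int(np.argmax(V[i_up:]))
    peak = float(V[i_peak])
    amplitude = peak - rmp
    if amplitude < min_amplitude:
        return APBiomarkers(rmp=rmp, amplitude=amplitude, valid=False)
    w0, w1 = plateau_window
    sel = (t >= t[i_peak] + w0) & (t <= t[i_peak] + w1)
    plateau_peak = float(np.max(V[sel])) if np.any(sel) else np.nan
    return APBiomarkers(
        rmp=rmp,
        apd70=_apd(t, V, t_up, i_peak, peak - 0.70 * amplitude),
        apd90=_apd(t, V, t_up, i_peak, peak - 0.90 * amplitude),
        plateau_peak=plateau_peak,
        amplitude=amplitude,
        dvdt_max=float(dvdt[i_up]),
        upstroke_time=t_up,
        valid=True,
    )


def limit_cycle_ap(params: CellParameters, electrolytes: ElectrolyteSet,
                   cl_ms: float = 1000.0, n_prepace: int = 100,
                   reference: ElectrolyteSet | None = None,
                   mask: ElectrolyteOverrideMask | None = None,
                   pacing: PacingSpec | None = None):
    """Pre-pace to (near) limit cycle, record one beat, return
    ``(APBiomarkers, Trace, PrepaceResult)``."""
    if pacing is None:
        pacing = PacingSpec(cl_ms=cl_ms, n_beats=n_prepace)
    pre = prepace(params, electrolytes, pacing, reference=reference, mask=mask)
    trace = record_ap(pre.state, params, electrolytes, pacing, n_beats=1,
                      reference=reference, mask=mask)
    return ap_biomarkers(trace), trace, pre


def diastolic_threshold(params: CellParameters, electrolytes: ElectrolyteSet,
                        stim_dur: float = DEFAULT_STIM_DUR,
                        lo: float = 0.5, hi: float = 80.0,
                        tol: float = 0.25) -> float:
    """Diastolic stimulation threshold (pA/pF) by bisection from rest.

    An amplitude captures if a single ``stim_dur`` pulse from the resting
    state elicits an AP (amplitude >= 40 mV and positive overshoot of
    -10 mV within 50 ms).
    """
    def captures(amp: float) -> bool:
        pacing = PacingSpec(cl_ms=100.0, n_beats=1, stim_amp=amp,
                            stim_dur=stim_dur)
        tr = record_ap(rest_state(), params, electrolytes, pacing,
                       n_beats=1, pre_ms=2.0)
        sel = tr.t <= 52.0
        return bool(np.max(tr.V[sel]) > -10.0)

    if captures(lo):
        return lo
    if not captures(hi):
        raise DomainError("no capture even at the maximum test amplitude")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


def integrate_adaptive(state: np.ndarray, params: CellParameters,
                       electrolytes: ElectrolyteSet, t_end: float,
                       stim_events: Sequence[tuple] = (),
                       reference: ElectrolyteSet | None = None,
                       mask: ElectrolyteOverrideMask | None = None,
                       rtol: float = 1e-8, atol: float = 1e-8,
                       out_dt: float = 0.1) -> Trace:
    """Adaptive-solver (scipy LSODA) integration of the same model.

    ``stim_events`` are ``(start_ms, duration_ms, amplitude)`` tuples; the
    integration is split at event boundaries so the solver never steps over
    a stimulus edge. Used as an independent cross-check of the fixed-step
    scheme.
    """
    from scipy.integrate import solve_ivp

    if reference is None:
        reference = electrolytes
    if mask is None:
        mask = DEFAULT_MASK

    edges = {0.0, float(t_end)}
    for (s, d, _a) in stim_events:
        edges.add(float(s))
        edges.add(float(s + d))
    edges = sorted(e for e in edges if 0.0 <= e <= t_end)

    def stim_at(tm: float) -> float:
        tot = 0.0
        for (s, d, a) in stim_events:
            if s <= tm < s + d:
                tot += a
        return tot

    y = np.array(state, dtype=float)
    ts = [np.array([0.0])]
    ys = [y[None, :]]
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 - t0 <= 0:
            continue
        amp = stim_at(0.5 * (t0 + t1))

        def rhs(tm, yy, amp=amp):
            dy, _ = derivatives(yy, params, electrolytes, reference, mask, stim=amp)
            return dy

        t_eval = np.arange(t0, t1, out_dt)[1:]
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=np.append(t_eval, t1), max_step=5.0)
        if not sol.success:
            raise NumericalError(f"adaptive solver failed in [{t0}, {t1}]: {sol.message}")
        y = sol.y[:, -1].copy()
        ts.append(sol.t)
        ys.append(sol.y.T)
    t = np.concatenate(ts)
    states = np.vstack(ys)
    elec_pc = mask.resolve(electrolytes, reference)
    return Trace(t, states, params, elec_pc)
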