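"""Arrhythmia induction protocols, episode tracking and binary endpoints.

Three induction protocols are applied to a 2-D substrate:

* ``burst_LAA`` / ``burst_roof``: after initialising every node from its
  region's CL-700 pacing limit cycle, five S1 stimuli are delivered in the
  coronary-sinus analogue box at CL 700 ms; 400 ms after the last S1, a
  short burst of five stimuli at CL 160 ms is delivered at the ectopic site
  (LAA or roof analogue). The episode is tracked for 5 s beyond the final
  stimulus.
* ``four_spirals``: the sheet is initialised directly with four spiral
  voltage waves of alternating chirality; node states are sampled along the
  CL-300 pacing limit cycle according to an Archimedean-spiral phase map
  (2 x 2 arrangement). The episode is tracked for 5 s.

Episode classification (criteria are configurable defaults): an arrhythmia
is *induced* when any node shows at least 3 activations after the final
stimulus with mean cycle length < 500 ms; it is *terminated* when, despite
induction, the tissue is quiescent over the final 200 ms of the 5-s window
(no activations and all V below RMP + 10 mV). The dominant frequency is the
reciprocal of the mean inter-activation interval over active nodes
(interval-based rather than spectral; robust on 5-s records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ionic import CellParameters, DomainError, ElectrolyteSet, N_STATES
from .monodomain import StimulusEvent, TissueResult, solve_monodomain
from .protocols0d import DEFAULT_STIM_DUR, PacingSpec, prepace, record_ap
from .substrate import Substrate

__all__ = [
    "InductionConfig", "InductionProtocol", "EndpointRecord",
    "burst_schedule", "burst_induction", "spiral_phase_map",
    "spiral_initial_condition", "classify_episode", "screen_single_stimulus",
]


@dataclass(frozen=True)
class InductionConfig:
    """Protocol timing and episode-detection thresholds."""

    s1_cl_ms: float = 700.0
    n_s1: int = 5
    pause_ms: float = 400.0          # from the last S1 to the first burst stimulus
    burst_cl_ms: float = 160.0
    n_burst: int = 5
    track_ms: float = 5000.0         # tracking window beyond the final stimulus
    prepace_cl_burst: float = 700.0
    prepace_cl_spiral: float = 300.0
    n_prepace: int = 100             # desk-scale; the full protocol uses 15 min
    stim_amp: float = 60.0           # pA/pF in tissue
    stim_dur: float = DEFAULT_STIM_DUR
    dt: float = 0.05                 # ms, 2-D tissue step
    # episode criteria
    min_activations: int = 3
    max_cl_ms: float = 500.0
    quiescence_ms: float = 200.0
    rmp_margin_mv: float = 10.0
    # radial pitch of the phase map; of the order of the tissue wavelength
    # (CV x APD ~ 10 cm for healthy atrial tissue) so the imposed spiral is
    # not everywhere refractory
    spiral_pitch_cm: float = 6.0


@dataclass(frozen=True)
class InductionProtocol:
    kind: str                        # burst_LAA | burst_roof | four_spirals
    config: InductionConfig = field(default_factory=InductionConfig)

    def __post_init__(self) -> None:
        if self.kind not in ("burst_LAA", "burst_roof", "four_spirals"):
            raise DomainError(f"unknown protocol kind {self.kind!r}")


@dataclass
class EndpointRecord:
    """Binary outcomes of one induction simulation."""

    induced_LAA: bool = False
    induced_AR: bool = False
    induced_any: bool = False
    terminated: bool | None = None   # defined only when induced
    dominant_frequency_hz: float = np.nan
    episode_duration_s: float = np.nan
    excluded_single_stimulus: bool = False


def burst_schedule(config: InductionConfig | None = None):
    """S1 and ectopic-burst stimulus onset times (ms from protocol start).

    With the defaults: S1 at 0, 700, ..., 2800 ms; after a 400-ms pause
    measured from the last S1, burst stimuli at 3200, 3360, 3520, 3680,
    3840 ms.
    """
    c = config or InductionConfig()
    s1 = [k * c.s1_cl_ms for k in range(c.n_s1)]
    burst0 = s1[-1] + c.pause_ms
    burst = [burst0 + k * c.burst_cl_ms for k in range(c.n_burst)]
    return s1, burst


def _region_initial_states(substrate: Substrate, electrolytes: ElectrolyteSet,
                           cl_ms: float, n_prepace: int) -> np.ndarray:
    """Per-node initial states from each region's 0-D pacing limit cycle."""
    n = substrate.geometry.n_nodes
    Y = np.empty((n, N_STATES))
    done: dict[int, np.ndarray] = {}
    for r in np.unique(substrate.region_id):
        p = substrate.params_by_region[int(r)]
        key = id(p)
        if key not in done:
            pre = prepace(p, electrolytes,
                          PacingSpec(cl_ms=cl_ms, n_beats=n_prepace))
            done[key] = pre.state
        Y[substrate.region_id == r] = done[key]
    return Y


def burst_induction(substrate: Substrate, site: str,
                    electrolytes: ElectrolyteSet,
                    config: InductionConfig | None = None) -> TissueResult:
    """Burst-pacing induction at the LAA or roof analogue site.

    A failure of the ectopic burst to capture is a legitimate negative
    outcome, not an error.
    """
    if site not in ("LAA", "roof"):
        raise DomainError("site must be 'LAA' or 'roof'")
    c = config or InductionConfig()
    s1_times, burst_times = burst_schedule(c)

    Y0 = _region_initial_states(substrate, electrolytes,
                                c.prepace_cl_burst, c.n_prepace)
    cs = substrate.stimulus_masks["CS"]
    ect = substrate.stimulus_masks[site]
    stimuli = [StimulusEvent(cs, t, c.stim_dur, c.stim_amp) for t in s1_times]
    stimuli += [StimulusEvent(ect, t, c.stim_dur, c.stim_amp) for t in burst_times]
    t_final = burst_times[-1] + c.stim_dur
    t_end = t_final + c.track_ms
    res = solve_monodomain(
        substrate.geometry, substrate.params_by_region, electrolytes, stimuli,
        t_end, dt=c.dt, initial_states=Y0, record_window=(t_end, t_end),
        final_window_ms=c.quiescence_ms)
    res.meta["t_final_stimulus"] = t_final
    res.meta["site"] = site
    res.meta["protocol"] = f"burst_{site}"
    return res


def spiral_phase_map(geometry, pitch_cm: float = 2.0) -> np.ndarray:
    """Phase in [0, 2*pi) of a 2x2 arrangement of Archimedean spirals.

    Adjacent cores have opposite chirality (sign of the angular term); each
    node takes the phase of its nearest core.
    """
    ny, nx = geometry.shape
    dx_cm = geometry.dx_mm / 10.0
    xs = np.arange(nx) * dx_cm
    ys = np.arange(ny) * dx_cm
    X, Yc = np.meshgrid(xs, ys)
    lx, ly = xs[-1], ys[-1]
    centers = [(0.25 * lx, 0.25 * ly, +1), (0.75 * lx, 0.25 * ly, -1),
               (0.25 * lx, 0.75 * ly, -1), (0.75 * lx, 0.75 * ly, +1)]
    phase = np.zeros((ny, nx))
    best = np.full((ny, nx), np.inf)
    for cx, cy, chir in centers:
        r = np.hypot(X - cx, Yc - cy)
        th = np.arctan2(Yc - cy, X - cx)
        ph = np.mod(chir * th + 2.0 * np.pi * r / pitch_cm, 2.0 * np.pi)
        closer = r < best
        phase[closer] = ph[closer]
        best[closer] = r[closer]
    return phase.reshape(-1)


def spiral_initial_condition(substrate: Substrate,
                             electrolytes: ElectrolyteSet,
                             config: InductionConfig | None = None) -> np.ndarray:
    """(n, 21) initial state field realising four spiral voltage waves.

    Each node's state is sampled along its region's CL-300 limit-cycle
    trajectory at the time offset ``phase / (2*pi) * CL``. Deterministic for
    a given substrate and configuration.
    """
    c = config or InductionConfig()
    geom = substrate.geometry
    min_side_cm = (min(geom.nx, geom.ny) - 1) * geom.dx_mm / 10.0
    if min_side_cm < 4.0:
        raise DomainError(
            f"sheet {min_side_cm:.1f} cm across; need >= 4 cm for 4 spiral cores")

    phase = spiral_phase_map(geom, c.spiral_pitch_cm)
    cl = c.prepace_cl_spiral
    out_dt = 1.0
    # per-region one-beat trajectory at the CL-300 limit cycle
    traj: dict[int, np.ndarray] = {}
    for r in np.unique(substrate.region_id):
        p = substrate.params_by_region[int(r)]
        key = id(p)
        if key not in traj:
            pacing = PacingSpec(cl_ms=cl, n_beats=c.n_prepace)
            pre = prepace(p, electrolytes, pacing)
            tr = record_ap(pre.state, p, electrolytes, pacing, n_beats=1,
                           out_dt=out_dt, pre_ms=0.0)
            traj[key] = tr.states
        traj[int(r)] = traj[key]

    n = geom.n_nodes
    Y = np.empty((n, N_STATES))
    for r in np.unique(substrate.region_id):
        states = traj[int(r)]
        nt = states.shape[0]
        sel = substrate.region_id == r
        idx = np.minimum((phase[sel] / (2 * np.pi) * (cl / out_dt)).astype(int),
                         nt - 1)
        Y[sel] = states[idx]
    return Y


def run_protocol(substrate: Substrate, protocol: InductionProtocol,
                 electrolytes: ElectrolyteSet) -> TissueResult:
    """Run one induction protocol end to end."""
    c = protocol.config
    if protocol.kind in ("burst_LAA", "burst_roof"):
        site = "LAA" if protocol.kind == "burst_LAA" else "roof"
        return burst_induction(substrate, site, electrolytes, c)
    Y0 = spiral_initial_condition(substrate, electrolytes, c)
    res = solve_monodomain(
        substrate.geometry, substrate.params_by_region, electrolytes, [],
        c.track_ms, dt=c.dt, initial_states=Y0,
        record_window=(c.track_ms, c.track_ms),
        final_window_ms=c.quiescence_ms)
    res.meta["t_final_stimulus"] = 0.0
    res.meta["protocol"] = "four_spirals"
    return res


def classify_episode(result: TissueResult,
                     protocol: InductionProtocol | str = "four_spirals",
                     config: InductionConfig | None = None,
                     rmp_mv: float = -81.0) -> EndpointRecord:
    """Binary endpoints and dominant frequency from activation tracking.

    *Induced*: any node with >= ``min_activations`` activations after the
    final stimulus at mean cycle length < ``max_cl_ms``. *Terminated*:
    induced and quiescent over the final ``quiescence_ms`` (no activations,
    all V < RMP + margin). Dominant frequency: 1 / mean inter-activation
    interval over such "active" nodes.
    """
    if isinstance(protocol, InductionProtocol):
        kind = protocol.kind
        c = config or protocol.config
    else:
        kind = protocol
        c = config or InductionConfig()
    t_final = float(result.meta.get("t_final_stimulus", 0.0))
    t_end = float(result.meta.get("t_end", np.nan))
    if np.isfinite(t_end) and t_end - t_final < c.track_ms - 1e-6:
        raise DomainError("result does not cover the full tracking window")

    act_times = result.act_times
    counts = np.minimum(result.act_count, act_times.shape[1])

    induced = False
    intervals = []
    last_act_time = t_final
    for node in np.flatnonzero(counts > 0):
        times = act_times[node, :counts[node]]
        times = times[np.isfinite(times) & (times > t_final)]
        if times.size:
            last_act_time = max(last_act_time, float(times.max()))
        if times.size >= c.min_activations:
            gaps = np.diff(times)
            if gaps.size and np.mean(gaps) < c.max_cl_ms:
                induced = True
                intervals.append(np.mean(gaps))

    dom_f = 1000.0 / float(np.mean(intervals)) if intervals else np.nan
    duration = (last_act_time - t_final) / 1000.0 if induced else np.nan

    terminated = None
    if induced:
        q0 = t_final + c.track_ms - c.quiescence_ms
        recent = act_times[np.isfinite(act_times)]
        act_in_final = np.any(recent >= q0)
        quiescent_v = bool(np.all(result.final_max_v < rmp_mv + c.rmp_margin_mv))
        terminated = (not act_in_final) and quiescent_v

    rec = EndpointRecord(
        induced_LAA=induced and kind == "burst_LAA",
        induced_AR=induced and kind == "burst_roof",
        induced_any=induced,
        terminated=terminated,
        dominant_frequency_hz=dom_f,
        episode_duration_s=duration,
    )
    return rec


def screen_single_stimulus(substrate: Substrate, electrolytes: ElectrolyteSet,
                           config: InductionConfig | None = None,
                           cs_cl_ms: float = 1000.0,
                           expected_repol_ms: float = 500.0,
                           persist_ms: float = 1000.0) -> bool:
    """True when the two-stimulus mapping protocol self-sustains.

    Runs the coronary-sinus two-stimulus protocol used for the activation
    maps; returns True (run must be excluded from QoI tables) when activity
    persists more than ``persist_ms`` after the second beat's expected
    repolarisation.
    """
    c = config or InductionConfig()
    Y0 = _region_initial_states(substrate, electrolytes, cs_cl_ms, c.n_prepace)
    cs = substrate.stimulus_masks["CS"]
    stimuli = [StimulusEvent(cs, 0.0, c.stim_dur, c.stim_amp),
               StimulusEvent(cs, cs_cl_ms, c.stim_dur, c.stim_amp)]
    t_check = cs_cl_ms + expected_repol_ms + persist_ms
    t_end = t_check + 200.0
    res = solve_monodomain(substrate.geometry, substrate.params_by_region,
                           electrolytes, stimuli, t_end, dt=c.dt,
                           initial_states=Y0, record_window=(t_end, t_end))
    times = res.act_times[np.isfinite(res.act_times)]
    return bool(np.any(times > t_check))
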