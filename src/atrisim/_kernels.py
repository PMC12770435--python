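"""Fast fixed-step integrators for the CRN++ model (numba).

The voltage-dependent gate kinetics and current factors are tabulated on a
uniform membrane-potential grid and linearly interpolated; gates advance with
the Rush-Larsen exponential update (the table stores ``exp(-dt/tau)``
directly, so tables are built per time step). Concentrations advance with
forward Euler. This is the standard scheme for monodomain cardiac tissue
simulation and is also used for long 0-D pacing trains.

Everything here operates on the frozen state layout of :mod:`atrisim.ionic`
(index 0 = V, 1..15 gates, 16..20 concentrations) and on "prepared" inputs:

* ``gp``  -- effective conductance vector (12,) with the potassium scaling of
  GK1/GKr already folded in;
* ``aux`` -- per-cell electrolyte constants (logs of the extracellular
  concentrations each current sees, pump/exchanger factors), see
  :func:`prepare_cell`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .ionic import (
    CM_PF, FARADAY, R_GAS, V_I, V_REL, V_UP,
    CURRENT_NAMES, V_GATE_NAMES,
    CellParameters, gate_kinetics, potassium_scaling,
)

# table geometry
VMIN = -120.0
VMAX = 80.0
NV = 8001
DV_INV = (NV - 1) / (VMAX - VMIN)

# table rows: 2*g and 2*g+1 hold inf / exp(-dt/tau) for gate g in V_GATE_NAMES
_ROW_IK1DEN = 24
_ROW_GKUR = 25
_ROW_IKRDEN = 26
_ROW_NACA1 = 27
_ROW_NACA2 = 28
_ROW_NAK1 = 29
_ROW_NAK2 = 30
N_ROWS = 31

_RT_F = R_GAS * 310.0 / FARADAY  # tables assume the fixed 310 K of the model

# state indices of the 12 voltage gates, in V_GATE_NAMES order
_VGATE_IDX = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 15], dtype=np.int64)

_table_cache: dict[float, np.ndarray] = {}


def build_tables(dt: float) -> np.ndarray:
    """(N_ROWS, NV) lookup table for time step ``dt`` (ms). Cached."""
    key = round(float(dt), 9)
    if key in _table_cache:
        return _table_cache[key]
    v = np.linspace(VMIN, VMAX, NV)
    tabs = np.empty((N_ROWS, NV))
    kin = gate_kinetics(v)
    for g, name in enumerate(V_GATE_NAMES):
        inf, tau = kin[name]
        tabs[2 * g] = inf
        tabs[2 * g + 1] = np.exp(-dt / tau)
    tabs[_ROW_IK1DEN] = 1.0 / (1.0 + np.exp(0.07 * (v + 80.0)))
    tabs[_ROW_GKUR] = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    tabs[_ROW_IKRDEN] = 1.0 / (1.0 + np.exp((v + 15.0) / 22.4))
    vf_rt = v / _RT_F
    tabs[_ROW_NACA1] = np.exp(0.35 * vf_rt)
    tabs[_ROW_NACA2] = np.exp(-0.65 * vf_rt)
    tabs[_ROW_NAK1] = np.exp(-0.1 * vf_rt)
    tabs[_ROW_NAK2] = np.exp(-vf_rt)
    _table_cache[key] = tabs
    return tabs


# aux layout
_N_AUX = 14


def prepare_cell(params: CellParameters, elec_pc: np.ndarray):
    """Effective conductances and electrolyte constants for the kernels.

    ``elec_pc`` is the (12, 3) per-current (Ko, Nao, Cao) array. Returns
    ``(gp, aux, variable_eca)``.
    """
    idx = {n: i for i, n in enumerate(CURRENT_NAMES)}
    gp = params.as_vector()
    gp[1] *= potassium_scaling(elec_pc[idx["IK1"], 0], params.k_anchor, params.k_exponent)
    gp[4] *= potassium_scaling(elec_pc[idx["IKr"], 0], params.k_anchor, params.k_exponent)
    aux = np.empty(_N_AUX)
    aux[0] = np.log(elec_pc[idx["INa"], 1])
    aux[1] = np.log(elec_pc[idx["IK1"], 0])
    aux[2] = np.log(elec_pc[idx["Ito"], 0])
    aux[3] = np.log(elec_pc[idx["IKur"], 0])
    aux[4] = np.log(elec_pc[idx["IKr"], 0])
    aux[5] = np.log(elec_pc[idx["IKs"], 0])
    aux[6] = np.log(elec_pc[idx["ICaL"], 2])
    aux[7] = np.log(elec_pc[idx["IbCa"], 2])
    aux[8] = np.log(elec_pc[idx["IbNa"], 1])
    ko_nak = elec_pc[idx["INaK"], 0]
    aux[9] = ko_nak / (ko_nak + 1.5)
    aux[10] = (np.exp(elec_pc[idx["INaK"], 1] / 67.3) - 1.0) / 7.0
    nao_x = elec_pc[idx["INaCa"], 1]
    cao_x = elec_pc[idx["INaCa"], 2]
    aux[11] = cao_x
    aux[12] = nao_x ** 3
    aux[13] = (87.5 ** 3 + nao_x ** 3) * (1.38 + cao_x)
    return gp, aux, 1 if params.variable_eca else 0


@njit(cache=True, inline="always", fastmath=True)
def _lerp(tabs, row, k, f):
    return tabs[row, k] * (1.0 - f) + tabs[row, k + 1] * f


@njit(cache=True, inline="always", fastmath=True)
def _cell_step(y, dt, gp, aux, veca, tabs, rlc_fca, rlc_u):
    """Advance gates + concentrations of one cell; return dV/dt (reaction).

    ``y`` is the (21,) state view; V itself (y[0]) is NOT updated here so the
    caller can combine reaction, stimulus and diffusion.
    """
    V = y[0]
    u = (V - VMIN) * DV_INV
    if u < 0.0:
        u = 0.0
    elif u > NV - 1.000001:
        u = NV - 1.000001
    k = int(u)
    f = u - k

    m = y[1]; h = y[2]; j = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]; d = y[10]; fg = y[11]; fca = y[12]
    ug = y[13]; vg = y[14]; wg = y[15]
    Nai = y[16]; Ki = y[17]; Cai = y[18]; Caup = y[19]; Carel = y[20]

    log_nai = np.log(Nai)
    log_ki = np.log(Ki)
    log_cai = np.log(Cai)

    # currents (use state at time n)
    ina = gp[0] * m * m * m * h * j * (V - _RT_F * (aux[0] - log_nai))
    ik1 = gp[1] * (V - _RT_F * (aux[1] - log_ki)) * _lerp(tabs, _ROW_IK1DEN, k, f)
    ito = gp[2] * oa * oa * oa * oi * (V - _RT_F * (aux[2] - log_ki))
    ikur = (gp[3] * _lerp(tabs, _ROW_GKUR, k, f) * ua * ua * ua * ui
            * (V - _RT_F * (aux[3] - log_ki)))
    ikr = gp[4] * xr * (V - _RT_F * (aux[4] - log_ki)) * _lerp(tabs, _ROW_IKRDEN, k, f)
    iks = gp[5] * xs * xs * (V - _RT_F * (aux[5] - log_ki))
    if veca == 1:
        ical = gp[6] * d * fg * fca * (V - 0.5 * _RT_F * (aux[6] - log_cai))
    else:
        ical = gp[6] * d * fg * fca * (V - 65.0)
    ibca = gp[7] * (V - 0.5 * _RT_F * (aux[7] - log_cai))
    ibna = gp[8] * (V - _RT_F * (aux[8] - log_nai))
    fnak = 1.0 / (1.0 + 0.1245 * _lerp(tabs, _ROW_NAK1, k, f)
                  + 0.0365 * aux[10] * _lerp(tabs, _ROW_NAK2, k, f))
    inak = gp[9] * fnak * (1.0 / (1.0 + (10.0 / Nai) ** 1.5)) * aux[9]
    e1 = _lerp(tabs, _ROW_NACA1, k, f)
    e2 = _lerp(tabs, _ROW_NACA2, k, f)
    inaca = (gp[10] * (e1 * Nai * Nai * Nai * aux[11] - e2 * aux[12] * Cai)
             / (aux[13] * (1.0 + 0.1 * e2)))
    icap = gp[11] * Cai / (0.0005 + Cai)

    itot = (ina + ik1 + ito + ikur + ikr + iks + ical + ibca + ibna
            + inak + inaca + icap)

    # Rush-Larsen update of the 12 voltage gates
    for g in range(12):
        inf = _lerp(tabs, 2 * g, k, f)
        rlc = _lerp(tabs, 2 * g + 1, k, f)
        idx = _VGATE_IDX[g]
        y[idx] = inf + (y[idx] - inf) * rlc

    # calcium subsystem
    i_rel = 30.0 * ug * ug * vg * wg * (Carel - Cai)
    i_tr = (Caup - Carel) / 180.0
    i_up = 0.005 / (1.0 + 0.00092 / Cai)
    i_up_leak = 0.005 * Caup / 15.0

    fn = 1e-12 * V_REL * i_rel - 5e-13 / FARADAY * (0.5 * ical * CM_PF
                                                    - 0.2 * inaca * CM_PF)
    efn = np.exp(-(fn - 3.4175e-13) / 1.367e-15)
    u_inf = 1.0 / (1.0 + efn)
    y[13] = u_inf + (ug - u_inf) * rlc_u
    tau_v = 1.91 + 2.09 / (1.0 + efn)
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 1.367e-15))
    y[14] = v_inf + (vg - v_inf) * np.exp(-dt / tau_v)
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    y[12] = fca_inf + (fca - fca_inf) * rlc_fca

    c_f_vi = CM_PF / (FARADAY * V_I)
    y[16] = Nai + dt * (-3.0 * inak - 3.0 * inaca - ibna - ina) * c_f_vi
    y[17] = Ki + dt * (2.0 * inak - ik1 - ito - ikur - ikr - iks) * c_f_vi
    b1 = ((2.0 * inaca - icap - ical - ibca) * CM_PF / (2.0 * FARADAY * V_I)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + 0.07 * 0.0005 / ((Cai + 0.0005) * (Cai + 0.0005))
          + 0.05 * 0.00238 / ((Cai + 0.00238) * (Cai + 0.00238)))
    y[18] = Cai + dt * b1 / b2
    y[19] = Caup + dt * (i_up - i_up_leak - i_tr * V_REL / V_UP)
    y[20] = Carel + dt * (i_tr - i_rel) / (1.0 + 8.0 / ((Carel + 0.8) * (Carel + 0.8)))

    return -itot


@njit(cache=True, fastmath=True)
def pace_cell(y, n_beats, cl, dt, stim_dur, stim_amp, gp, aux, veca, tabs,
              beat_states):
    """Paced 0-D train; records the state at the start of every beat.

    ``beat_states`` must be (n_beats + 1, 21); row b holds the state at the
    start of beat b, the final row the end-of-train state. Returns the index
    of the first beat where a non-finite V appeared, or -1 on success.
    """
    rlc_fca = np.exp(-dt / 2.0)
    rlc_u = np.exp(-dt / 8.0)
    steps_per_beat = int(round(cl / dt))
    stim_steps = int(round(stim_dur / dt))
    for b in range(n_beats):
        beat_states[b] = y
        for s in range(steps_per_beat):
            stim = stim_amp if s < stim_steps else 0.0
            dv = _cell_step(y, dt, gp, aux, veca, tabs, rlc_fca, rlc_u)
            y[0] += dt * (dv + stim)
        if not np.isfinite(y[0]):
            return b
    beat_states[n_beats] = y
    return -1


@njit(cache=True, fastmath=True)
def record_cell(y, n_steps, dt, ev_start, ev_dur, ev_amp, gp, aux, veca, tabs,
                out_every, out_states):
    """Integrate with an explicit stimulus schedule, recording full states.

    ``out_states`` must be (n_steps // out_every + 1, 21); row r holds the
    state at t = r * out_every * dt. Returns -1 on success or the failing
    step index.
    """
    rlc_fca = np.exp(-dt / 2.0)
    rlc_u = np.exp(-dt / 8.0)
    out_states[0] = y
    r = 1
    for s in range(n_steps):
        t = s * dt
        stim = 0.0
        for e in range(ev_start.shape[0]):
            if ev_start[e] <= t < ev_start[e] + ev_dur[e]:
                stim += ev_amp[e]
        dv = _cell_step(y, dt, gp, aux, veca, tabs, rlc_fca, rlc_u)
        y[0] += dt * (dv + stim)
        if (s + 1) % out_every == 0:
            if not np.isfinite(y[0]):
                return s
            out_states[r] = y
            r += 1
    return -1


@njit(cache=True, fastmath=True)
def run_tissue(Y, nx, ny, dt, n_steps, t_offset,
               gp, aux, veca, tabs,
               dxe, dyn, inv_dx2, inv_dy2,
               ev_start, ev_dur, ev_amp, ev_mask,
               rec_i0, rec_i1, rec_every, rec_vm,
               act_thr, act_refr, act_count, act_times,
               fin_i0, fin_max_v):
    """Explicit monodomain step loop on a structured nx-by-ny grid.

    * ``Y``: (n, 21) states, node index c = iy*nx + ix.
    * ``gp``/``aux``: per-node prepared parameters, (n, 12) / (n, 14).
    * ``dxe``: (n,) diffusion coefficient on the east face of each node
      (mm^2/ms, arithmetic face mean); ``dyn`` the north face.
    * stimulus events: arrays over events; ``ev_mask`` is (n_ev, n) uint8.
    * recording: Vm stored in ``rec_vm`` (nt_rec, n) float32 every
      ``rec_every`` steps for step index in [rec_i0, rec_i1).
    * activation tracking: upward crossings of ``act_thr`` separated by at
      least ``act_refr`` ms appended to ``act_times`` (n, max_ev), counts in
      ``act_count``; times include ``t_offset``.
    * ``fin_max_v``: running max of V for steps >= fin_i0 (quiescence check).

    Returns -1 on success, else the step index where V went non-finite.
    """
    n = nx * ny
    rlc_fca = np.exp(-dt / 2.0)
    rlc_u = np.exp(-dt / 8.0)
    dv_r = np.empty(n)
    last_act = np.full(n, -1e30)
    max_ev = act_times.shape[1]
    rec_row = 0
    n_ev = ev_start.shape[0]

    for s in range(n_steps):
        t = t_offset + s * dt

        # record the pre-step state so sample r is the state after
        # rec_i0 + r*rec_every steps (matches the 0-D recording convention)
        if rec_i0 <= s < rec_i1 and (s - rec_i0) % rec_every == 0:
            if rec_row < rec_vm.shape[0]:
                for c in range(n):
                    rec_vm[rec_row, c] = Y[c, 0]
                rec_row += 1

        # reaction step (gates + concentrations updated in place)
        for c in range(n):
            dv_r[c] = _cell_step(Y[c], dt, gp[c], aux[c], veca, tabs,
                                 rlc_fca, rlc_u)

        # stimulus
        for e in range(n_ev):
            if ev_start[e] <= t < ev_start[e] + ev_dur[e]:
                amp = ev_amp[e]
                for c in range(n):
                    if ev_mask[e, c] == 1:
                        dv_r[c] += amp

        # diffusion (no-flux boundaries) + V update + event tracking
        for iy in range(ny):
            base = iy * nx
            for ix in range(nx):
                c = base + ix
                v = Y[c, 0]
                lap = 0.0
                if ix > 0:
                    lap += dxe[c - 1] * (Y[c - 1, 0] - v) * inv_dx2
                if ix < nx - 1:
                    lap += dxe[c] * (Y[c + 1, 0] - v) * inv_dx2
                if iy > 0:
                    lap += dyn[c - nx] * (Y[c - nx, 0] - v) * inv_dy2
                if iy < ny - 1:
                    lap += dyn[c] * (Y[c + nx, 0] - v) * inv_dy2
                dv_r[c] += lap

        for c in range(n):
            v_old = Y[c, 0]
            v_new = v_old + dt * dv_r[c]
            Y[c, 0] = v_new
            if v_old < act_thr <= v_new and (t - last_act[c]) > act_refr:
                last_act[c] = t
                if act_count[c] < max_ev:
                    act_times[c, act_count[c]] = t
                act_count[c] += 1
            if s >= fin_i0 and v_new > fin_max_v[c]:
                fin_max_v[c] = v_new

        if (s + 1) % 1000 == 0:
            ok = True
            for c in range(n):
                if not np.isfinite(Y[c, 0]):
                    ok = False
                    break
            if not ok:
                return s
    return -1
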