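"""Monodomain reaction-diffusion solver for 1-D strands and 2-D sheets.

The tissue equation is ``Cm dV/dt = -I_ion + div(D grad V)`` with
``D = sigma / (beta * Cm)`` (sigma: effective conductivity S/m, beta:
surface-to-volume ratio, Cm: specific membrane capacitance). Diffusion uses
second-order finite differences with no-flux boundaries and arithmetic face
averaging of heterogeneous D; the reaction step is the Rush-Larsen cell
update of :mod:`atrisim._kernels` (operator combined in a single explicit
step). Deterministic for fixed inputs.

The default scaling constants (beta 1400 /cm, Cm 1 uF/cm^2) and the six-row
region conductivity table are chosen so a healthy strand at reference
electrolytes conducts at 0.6-0.8 m/s; all values are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels as K
from .ionic import (
    DEFAULT_MASK, CellParameters, DomainError, ElectrolyteSet, NumericalError,
    N_STATES, rest_state,
)
from .protocols0d import DEFAULT_STIM_DUR

__all__ = [
    "BETA_PER_M", "CM_F_PER_M2", "DEFAULT_CONDUCTIVITIES",
    "sigma_to_diffusivity", "Geometry1D", "Geometry2D", "StimulusEvent",
    "TissueResult", "ConfigurationError", "solve_monodomain", "strand_cv",
    "strand_cv_protocol", "write_vtk_structured",
]

# monodomain scaling: D [mm^2/ms] = sigma [S/m] / (beta [1/m] * Cm [F/m^2]) * 1e-3
BETA_PER_M = 140_000.0   # 1400 /cm
CM_F_PER_M2 = 0.01       # 1 uF/cm^2

#: per-region (sigma_longitudinal, sigma_transverse) in S/m for the six
#: IIR-derived tissue classes (0 = lowest intensity / healthy ... 3 =
#: borderline, 4-5 = fibrotic with reduced coupling). Declared defaults.
DEFAULT_CONDUCTIVITIES = (
    (0.28, 0.070),
    (0.25, 0.063),
    (0.22, 0.055),
    (0.20, 0.050),
    (0.14, 0.028),
    (0.10, 0.017),
)


class ConfigurationError(ValueError):
    """Invalid solver/geometry configuration (detected before stepping)."""


def sigma_to_diffusivity(sigma_s_per_m: float) -> float:
    """Effective conductivity (S/m) -> diffusion coefficient (mm^2/ms).

    sigma/(beta*Cm) has units m^2/s; 1 m^2/s = 1e6 mm^2 / 1e3 ms.
    """
    return sigma_s_per_m / (BETA_PER_M * CM_F_PER_M2) * 1e3


_sigma_to_d = sigma_to_diffusivity


@dataclass(frozen=True)
class Geometry1D:
    """Homogeneous 1-D strand (single-cable equivalent of a thin slab)."""

    length_cm: float = 1.0
    dx_um: float = 100.0

    def __post_init__(self) -> None:
        n_int = self.length_cm * 1e4 / self.dx_um
        if abs(n_int - round(n_int)) > 1e-9 or round(n_int) + 1 < 3:
            raise ConfigurationError(
                "strand length must be an integer multiple of the node "
                f"spacing with >= 3 nodes (length {self.length_cm} cm, "
                f"dx {self.dx_um} um)")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length_cm * 1e4 / self.dx_um)) + 1

    @property
    def dx_mm(self) -> float:
        return self.dx_um * 1e-3

    @property
    def x_cm(self) -> np.ndarray:
        return np.arange(self.n_nodes) * self.dx_um * 1e-4

    @property
    def shape(self) -> tuple:
        return (1, self.n_nodes)  # (ny, nx)


@dataclass(frozen=True)
class Geometry2D:
    """Structured 2-D sheet with per-node region ids.

    ``region_id`` indexes ``conductivities`` (sigma_l, sigma_t in S/m).
    ``fibre_angle`` is a per-node fibre direction in radians; only
    axis-aligned fibres (angle 0) are currently supported by the solver,
    i.e. sigma_l acts along x and sigma_t along y.
    """

    nx: int
    ny: int
    spacing_um: float
    region_id: np.ndarray = None
    conductivities: tuple = DEFAULT_CONDUCTIVITIES
    fibre_angle: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ConfigurationError("need at least 3x3 nodes")
        rid = self.region_id
        if rid is None:
            rid = np.zeros(self.nx * self.ny, dtype=np.int64)
            object.__setattr__(self, "region_id", rid)
        rid = np.asarray(rid).reshape(-1)
        object.__setattr__(self, "region_id", rid.astype(np.int64))
        if rid.size != self.nx * self.ny:
            raise ConfigurationError("region_id must cover all nodes")
        if rid.min() < 0 or rid.max() >= len(self.conductivities):
            raise ConfigurationError("region id outside conductivity table")
        for sl, st in self.conductivities:
            if sl <= 0 or st <= 0:
                raise ConfigurationError("conductivities must be positive")
        if self.fibre_angle is not None and np.any(np.asarray(self.fibre_angle) != 0.0):
            raise ConfigurationError("only axis-aligned fibres (angle 0) supported")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def dx_mm(self) -> float:
        return self.spacing_um * 1e-3

    @property
    def shape(self) -> tuple:
        return (self.ny, self.nx)


@dataclass(frozen=True)
class StimulusEvent:
    """Rectangular current injection on a node mask."""

    mask: np.ndarray       # bool, (n_nodes,)
    onset_ms: float
    duration_ms: float
    amplitude: float       # pA/pF, positive depolarises

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool).reshape(-1)
        object.__setattr__(self, "mask", m)
        if self.onset_ms < 0:
            raise DomainError("stimulus onset must be >= 0")
        if not m.any():
            raise DomainError("stimulus mask is empty")


@dataclass
class TissueResult:
    """Output of a monodomain run.

    ``vm`` is the recorded membrane potential, (nt, n_nodes) float32 sampled
    at ``t`` (ms); it may be None when only activation tracking was
    requested. ``act_times``/``act_count`` hold per-node upward crossings of
    the activation threshold; ``final_max_v`` the per-node max V over the
    terminal quiescence window.
    """

    geometry: object
    t: np.ndarray
    vm: np.ndarray | None
    dt: float
    act_times: np.ndarray
    act_count: np.ndarray
    final_max_v: np.ndarray
    meta: dict = field(default_factory=dict)


def _per_node_prepared(geometry, params_field, electrolytes_field, mask=None,
                       reference=None):
    """Per-node (gp, aux) arrays from region-wise or uniform inputs."""
    n = geometry.n_nodes
    if isinstance(geometry, Geometry1D):
        region = np.zeros(n, dtype=int)
        params_by_region = {0: params_field} if isinstance(params_field, CellParameters) \
            else dict(enumerate(params_field))
    else:
        region = geometry.region_id
        if isinstance(params_field, CellParameters):
            params_by_region = {r: params_field for r in np.unique(region)}
        else:
            params_by_region = dict(enumerate(params_field))

    if isinstance(electrolytes_field, ElectrolyteSet):
        elec = electrolytes_field
    else:
        raise DomainError("per-node electrolyte fields not supported; pass one ElectrolyteSet")

    msk = mask or DEFAULT_MASK
    ref = reference or elec
    elec_pc = msk.resolve(elec, ref)

    gp = np.empty((n, 12))
    aux = np.empty((n, K._N_AUX))
    veca = None
    for r in np.unique(region):
        p = params_by_region[int(r)]
        g, a, ve = K.prepare_cell(p, elec_pc)
        sel = region == r
        gp[sel] = g
        aux[sel] = a
        if veca is None:
            veca = ve
        elif veca != ve:
            raise DomainError("variable_eca must agree across regions")
    return gp, aux, int(veca), region


def _face_diffusivities(geometry):
    """East/north face D arrays (mm^2/ms) by arithmetic mean."""
    if isinstance(geometry, Geometry1D):
        n = geometry.n_nodes
        d = np.full(n, _sigma_to_d(DEFAULT_CONDUCTIVITIES[0][0]))
        dxe = 0.5 * (d + np.roll(d, -1))
        dyn = np.zeros(n)
        return d, dxe, dyn
    sig = np.asarray(geometry.conductivities)
    dl = _sigma_to_d(1.0) * sig[geometry.region_id, 0]
    dt_ = _sigma_to_d(1.0) * sig[geometry.region_id, 1]
    ny, nx = geometry.shape
    DL = dl.reshape(ny, nx)
    DT = dt_.reshape(ny, nx)
    dxe = np.zeros((ny, nx))
    dxe[:, :-1] = 0.5 * (DL[:, :-1] + DL[:, 1:])
    dyn = np.zeros((ny, nx))
    dyn[:-1, :] = 0.5 * (DT[:-1, :] + DT[1:, :])
    return dl, dxe.reshape(-1), dyn.reshape(-1)


def solve_monodomain(geometry, params_field, electrolytes_field,
                     stimuli: Sequence[StimulusEvent], t_end: float,
                     dt: float = 0.02, initial_states: np.ndarray | None = None,
                     record_window: tuple | None = None, out_dt: float = 1.0,
                     act_threshold: float = -40.0, act_refractory: float = 50.0,
                     max_activations: int = 64,
                     final_window_ms: float = 200.0,
                     strand_conductivity: float | None = None,
                     t_offset: float = 0.0) -> TissueResult:
    """Run the explicit monodomain solver.

    ``params_field`` is a single :class:`CellParameters` (uniform tissue) or
    a sequence indexed by region id. ``initial_states`` may be a single (21,)
    state broadcast to all nodes, an (n, 21) field, or None (CRN rest).
    ``record_window=(t0, t1)`` stores Vm every ``out_dt`` ms inside the
    window; None records the whole run. ``strand_conductivity`` overrides the
    default healthy sigma_l for 1-D runs (S/m).
    """
    ny, nx = geometry.shape
    n = ny * nx
    dx = geometry.dx_mm

    dnode, dxe, dyn = _face_diffusivities(geometry)
    if isinstance(geometry, Geometry1D) and strand_conductivity is not None:
        dval = _sigma_to_d(strand_conductivity)
        dnode = np.full(n, dval)
        dxe = np.full(n, dval)
        dyn = np.zeros(n)

    # explicit-scheme stability bound
    dmax = float(np.max(dnode))
    ndims = 1 if ny == 1 else 2
    dt_max = dx * dx / (2.0 * ndims * dmax) if dmax > 0 else np.inf
    if dt > dt_max + 1e-12:
        raise ConfigurationError(
            f"dt={dt} ms violates the explicit stability bound {dt_max:.4f} ms "
            f"for dx={dx} mm, Dmax={dmax:.4f} mm^2/ms")

    gp, aux, veca, _region = _per_node_prepared(geometry, params_field,
                                                electrolytes_field)

    Y = np.empty((n, N_STATES))
    if initial_states is None:
        Y[:] = rest_state()
    else:
        ini = np.asarray(initial_states, dtype=float)
        Y[:] = ini if ini.ndim == 2 else ini[None, :]

    n_steps = int(round(t_end / dt))
    if record_window is None:
        record_window = (0.0, t_end)
    r0, r1 = record_window
    rec_i0 = max(0, int(round((r0 - t_offset) / dt)))
    rec_i1 = min(n_steps, int(round((r1 - t_offset) / dt)))
    rec_every = max(1, int(round(out_dt / dt)))
    nt_rec = max(0, (rec_i1 - rec_i0 + rec_every - 1) // rec_every)
    rec_vm = np.empty((nt_rec, n), dtype=np.float32)

    n_ev = len(stimuli)
    ev_start = np.array([s.onset_ms for s in stimuli], dtype=float)
    ev_dur = np.array([s.duration_ms for s in stimuli], dtype=float)
    ev_amp = np.array([s.amplitude for s in stimuli], dtype=float)
    ev_mask = np.zeros((max(n_ev, 1), n), dtype=np.uint8)
    for i, s in enumerate(stimuli):
        if s.mask.size != n:
            raise DomainError("stimulus mask size mismatch")
        ev_mask[i] = s.mask.astype(np.uint8)
    if n_ev == 0:
        ev_start = np.empty(0)
        ev_dur = np.empty(0)
        ev_amp = np.empty(0)
        ev_mask = np.zeros((0, n), dtype=np.uint8)

    act_count = np.zeros(n, dtype=np.int64)
    act_times = np.full((n, max_activations), np.nan, dtype=np.float64)
    fin_i0 = max(0, n_steps - int(round(final_window_ms / dt)))
    fin_max_v = np.full(n, -1e30)

    tabs = K.build_tables(dt)
    bad = K.run_tissue(Y, nx, ny, dt, n_steps, t_offset, gp, aux, veca, tabs,
                       dxe, dyn, 1.0 / dx ** 2, 1.0 / dx ** 2,
                       ev_start, ev_dur, ev_amp, ev_mask,
                       rec_i0, rec_i1, rec_every, rec_vm,
                       act_threshold, act_refractory, act_count, act_times,
                       fin_i0, fin_max_v)
    if bad >= 0:
        badnode = int(np.flatnonzero(~np.isfinite(Y[:, 0]))[0]) if not np.all(
            np.isfinite(Y[:, 0])) else -1
        raise NumericalError(
            f"non-finite Vm at t={t_offset + bad * dt:.2f} ms (node {badnode})")

    t_rec = t_offset + (rec_i0 + rec_every * np.arange(nt_rec)) * dt
    return TissueResult(
        geometry=geometry, t=t_rec, vm=rec_vm, dt=dt,
        act_times=act_times, act_count=act_count, final_max_v=fin_max_v,
        meta={"dt": dt, "dx_mm": dx, "scheme": "explicit-FD/Rush-Larsen",
              "t_end": t_end, "t_offset": t_offset, "final_states": Y},
    )


# ---------------------------------------------------------------------------
# Strand conduction velocity
# ---------------------------------------------------------------------------

def strand_cv(result: TissueResult, probes_cm: tuple = (0.25, 0.75),
              window: tuple | None = None):
    """Two-point conduction velocity on a 1-D strand.

    CV = (distance between probes) / (LAT difference), in m/s, with LAT the
    time of maximum dV/dt at each probe node. Returns ``(cv, blocked)``;
    ``cv`` is NaN and ``blocked`` True when either probe never activates.
    """
    geom = result.geometry
    if not isinstance(geom, Geometry1D):
        raise DomainError("strand_cv needs a Geometry1D result")
    from .biomarkers import lat_from_vm
    lat = lat_from_vm(result, window=window)
    idx = [int(round(p * 1e4 / geom.dx_um)) for p in probes_cm]
    l0, l1 = lat[idx[0]], lat[idx[1]]
    if not (np.isfinite(l0) and np.isfinite(l1)) or l1 == l0:
        return np.nan, True
    dist_mm = abs(probes_cm[1] - probes_cm[0]) * 10.0
    return float(dist_mm / (l1 - l0)), False


def strand_cv_protocol(params: CellParameters, electrolytes: ElectrolyteSet,
                       cl_ms: float, n_prepace: int = 100, n_beats: int = 2,
                       geometry: Geometry1D | None = None, dt: float = 0.02,
                       stim_amp: float = 60.0, stim_extent_cm: float = 0.05,
                       strand_conductivity: float | None = None,
                       prepaced_state: np.ndarray | None = None):
    """CV at one cycle length: 0-D pre-pacing at the target CL, strand
    initialised from that state, end-paced beats, CV on the last beat.

    Returns ``(cv_m_per_s, blocked, TissueResult)``.
    """
    from .protocols0d import PacingSpec, prepace

    geom = geometry or Geometry1D()
    if prepaced_state is None:
        pre = prepace(params, electrolytes, PacingSpec(cl_ms=cl_ms, n_beats=n_prepace))
        state0 = pre.state
    else:
        state0 = prepaced_state
    n = geom.n_nodes
    mask = geom.x_cm <= stim_extent_cm
    stimuli = [StimulusEvent(mask, onset_ms=k * cl_ms, duration_ms=DEFAULT_STIM_DUR,
                             amplitude=stim_amp) for k in range(n_beats)]
    t_end = n_beats * cl_ms
    last = ((n_beats - 1) * cl_ms, t_end)
    res = solve_monodomain(geom, params, electrolytes, stimuli, t_end, dt=dt,
                           initial_states=state0, record_window=last,
                           out_dt=0.1, strand_conductivity=strand_conductivity)
    cv, blocked = strand_cv(res, window=last)
    return cv, blocked, res


# ---------------------------------------------------------------------------
# Legacy-ASCII VTK export (text only)
# ---------------------------------------------------------------------------

def write_vtk_structured(path, nx: int, ny: int, spacing_mm: float,
                         point_data: dict) -> None:
    """Write per-node scalar fields as a legacy ASCII VTK structured grid."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\natrisim fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {spacing_mm} {spacing_mm} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float).reshape(-1)
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.6g")
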