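"""Electrolyte-parameterised human atrial myocyte model (CRN++).

The cell model is the Courtemanche–Ramirez–Nattel (CRN) human atrial action
potential model extended with extracellular-electrolyte sensitivity:

* reversal potentials ``ENa``, ``EK`` (and optionally ``ECa``) are recomputed
  from the extracellular concentrations each current sees;
* the inward-rectifier ``IK1`` and rapid delayed-rectifier ``IKr`` maximal
  conductances scale with ``sqrt([K+]o / anchor)`` (anchor 5.4 mM, the CRN
  default), reproducing the well-known cross-over sensitivity of these
  channels to extracellular potassium;
* the Na+/K+ pump, Na+/Ca2+ exchanger and background currents evaluate the
  extracellular concentrations directly.

A per-current override mask allows any single current to see a *perturbed*
electrolyte set while all other currents see the *reference* set; this is the
primitive behind per-current sensitivity attribution.

Fibrosis remodelling (GNa -40 %, GK1 -50 %, GCaL -50 %) is applied with
apply-once semantics via :func:`apply_fibrosis_remodelling`.

State layout (frozen; index -> name):

====  =======  =====================================
idx   name     meaning
====  =======  =====================================
0     V        membrane potential, mV
1-3   m h j    INa activation / fast / slow inact.
4-5   oa oi    Ito gates
6-7   ua ui    IKur gates
8     xr       IKr activation
9     xs       IKs activation
10-11 d f      ICaL gates
12    fca      ICaL Ca-dependent inactivation
13-15 u v w    SR release gates
16    Nai      intracellular Na+, mM
17    Ki       intracellular K+, mM
18    Cai      intracellular Ca2+, mM
19    Ca_up    SR uptake compartment Ca2+, mM
20    Ca_rel   SR release compartment Ca2+, mM
====  =======  =====================================
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np

__all__ = [
    "R_GAS",
    "FARADAY",
    "CM_PF",
    "CURRENT_NAMES",
    "STATE_NAMES",
    "N_STATES",
    "ElectrolyteSet",
    "REFERENCE_ELECTROLYTES",
    "CellParameters",
    "CurrentSet",
    "ElectrolyteOverrideMask",
    "DomainError",
    "NumericalError",
    "nernst_potential",
    "potassium_scaling",
    "rest_state",
    "gate_kinetics",
    "compute_currents",
    "derivatives",
    "apply_fibrosis_remodelling",
]

# ---------------------------------------------------------------------------
# Physical constants (CRN units)
# ---------------------------------------------------------------------------

R_GAS = 8.3143        # J / (mol K)
FARADAY = 96.4867     # C / mmol
CM_PF = 100.0         # membrane capacitance, pF

# cell compartment volumes (um^3)
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

KQ10 = 3.0  # temperature scaling of Ito / IKur gate kinetics

CURRENT_NAMES = (
    "INa", "IK1", "Ito", "IKur", "IKr", "IKs",
    "ICaL", "IbCa", "IbNa", "INaK", "INaCa", "ICap",
)

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Ca_up", "Ca_rel",
)
N_STATES = len(STATE_NAMES)

# published CRN resting initial conditions
_REST = np.array([
    -81.18, 2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1,
    4.966e-3, 9.986e-1, 3.296e-5, 1.869e-2, 1.367e-4, 9.996e-1,
    7.755e-1, 0.0, 1.0, 9.992e-1, 1.117e1, 1.39e2, 1.013e-4, 1.488, 1.488,
])


class DomainError(ValueError):
    """Input outside the physically meaningful domain."""


class NumericalError(RuntimeError):
    """Non-finite quantity produced during model evaluation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

# accepted simulation ranges (mM)
KO_RANGE = (2.0, 10.0)
NAO_RANGE = (80.0, 200.0)
CAO_RANGE = (0.5, 5.0)


@dataclass(frozen=True)
class ElectrolyteSet:
    """Extracellular electrolyte triple ([K+]o, [Na+]o, [Ca2+]o) in mM.

    Reference plasma values are 4.5 / 140 / 1.8 mM; the accepted simulation
    ranges are Ko in [2, 10], Nao in [80, 200], Cao in [0.5, 5].
    """

    Ko: float
    Nao: float
    Cao: float

    def __post_init__(self) -> None:
        for name, val, (lo, hi) in (
            ("Ko", self.Ko, KO_RANGE),
            ("Nao", self.Nao, NAO_RANGE),
            ("Cao", self.Cao, CAO_RANGE),
        ):
            if not np.isfinite(val) or val <= 0:
                raise DomainError(f"{name} must be a positive finite concentration, got {val!r}")
            if not lo <= val <= hi:
                raise DomainError(
                    f"{name}={val} mM outside accepted simulation range [{lo}, {hi}] mM"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.Ko, self.Nao, self.Cao], dtype=float)


REFERENCE_ELECTROLYTES = ElectrolyteSet(Ko=4.5, Nao=140.0, Cao=1.8)


@dataclass(frozen=True)
class CellParameters:
    """Maximal conductances / transport maxima of the CRN++ model.

    Conductances are in nS/pF (CRN convention); ``i_nak_max``, ``i_cap_max``
    in pA/pF and ``i_naca_max`` in pA/pF (scaling constant of the exchanger).
    ``g_kur`` is a dimensionless scale on the voltage-dependent IKur
    conductance. ``fibrotic`` is metadata recording whether fibrosis
    remodelling has been applied (apply-once semantics). ``variable_eca``
    switches the ICaL driving term from the fixed CRN constant (+65 mV) to the
    Nernst calcium reversal potential. ``k_anchor``/``k_exponent`` define the
    potassium sensitivity of IK1 and IKr conductances.
    """

    g_na: float = 7.8
    g_k1: float = 0.09
    g_to: float = 0.1652
    g_kur: float = 1.0
    g_kr: float = 0.029411765
    g_ks: float = 0.12941176
    g_cal: float = 0.12375
    g_bca: float = 0.001131
    g_bna: float = 0.0006744375
    i_nak_max: float = 0.59933874
    i_naca_max: float = 1600.0
    i_cap_max: float = 0.275
    fibrotic: bool = False
    variable_eca: bool = False
    k_anchor: float = 5.4
    k_exponent: float = 0.5
    temperature: float = 310.0

    _VECTOR_FIELDS = (
        "g_na", "g_k1", "g_to", "g_kur", "g_kr", "g_ks",
        "g_cal", "g_bca", "g_bna", "i_nak_max", "i_naca_max", "i_cap_max",
    )

    def __post_init__(self) -> None:
        for name in self._VECTOR_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"conductance {name} must be non-negative, got {v!r}")
        if self.k_anchor <= 0 or self.temperature <= 0:
            raise DomainError("k_anchor and temperature must be positive")

    def as_vector(self) -> np.ndarray:
        """Conductance vector in the order of ``CURRENT_NAMES`` plumbing."""
        return np.array([getattr(self, f) for f in self._VECTOR_FIELDS], dtype=float)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CellParameters":
        return cls(**json.loads(text))


#: units sidecar for serialised parameter sets
PARAMETER_UNITS = {
    "g_na": "nS/pF", "g_k1": "nS/pF", "g_to": "nS/pF",
    "g_kur": "dimensionless scale", "g_kr": "nS/pF", "g_ks": "nS/pF",
    "g_cal": "nS/pF", "g_bca": "nS/pF", "g_bna": "nS/pF",
    "i_nak_max": "pA/pF", "i_naca_max": "pA/pF", "i_cap_max": "pA/pF",
    "fibrotic": "flag", "variable_eca": "flag",
    "k_anchor": "mM", "k_exponent": "dimensionless", "temperature": "K",
}


class CurrentSet(NamedTuple):
    """Per-current transmembrane current values, pA/pF."""

    INa: float
    IK1: float
    Ito: float
    IKur: float
    IKr: float
    IKs: float
    ICaL: float
    IbCa: float
    IbNa: float
    INaK: float
    INaCa: float
    ICap: float

    @property
    def total(self) -> float:
        return float(sum(self))

    def as_dict(self) -> dict:
        return dict(zip(CURRENT_NAMES, self))


@dataclass(frozen=True)
class ElectrolyteOverrideMask:
    """Which electrolyte set each current sees: "perturbed" or "reference".

    The default sends the perturbed set to every current (mask neutrality:
    with perturbed == reference the masked model is identical to unmasked).
    """

    assignment: Mapping[str, str] = field(
        default_factory=lambda: {name: "perturbed" for name in CURRENT_NAMES}
    )

    def __post_init__(self) -> None:
        for name in CURRENT_NAMES:
            if name not in self.assignment:
                raise DomainError(f"mask missing entry for current {name}")
            if self.assignment[name] not in ("perturbed", "reference"):
                raise DomainError(
                    f"mask entry for {name} must be 'perturbed' or 'reference'"
                )

    @classmethod
    def only_perturbed(cls, *currents: str) -> "ElectrolyteOverrideMask":
        """Mask sending the perturbed set only into the named currents."""
        unknown = set(currents) - set(CURRENT_NAMES)
        if unknown:
            raise DomainError(f"unknown currents: {sorted(unknown)}")
        return cls({n: ("perturbed" if n in currents else "reference")
                    for n in CURRENT_NAMES})

    def resolve(self, perturbed: ElectrolyteSet,
                reference: ElectrolyteSet) -> np.ndarray:
        """(12, 3) array of (Ko, Nao, Cao) as seen by each current."""
        out = np.empty((len(CURRENT_NAMES), 3))
        pa, ra = perturbed.as_array(), reference.as_array()
        for i, name in enumerate(CURRENT_NAMES):
            out[i] = pa if self.assignment[name] == "perturbed" else ra
        return out


DEFAULT_MASK = ElectrolyteOverrideMask()


def rest_state() -> np.ndarray:
    """Published CRN resting state (fresh copy)."""
    return _REST.copy()


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def nernst_potential(valence: int, conc_out: float, conc_in: float,
                     temperature: float = 310.0) -> float:
    """Nernst equilibrium potential (R*T)/(z*F) * ln(out/in), in mV."""
    if valence == 0:
        raise DomainError("valence must be non-zero")
    conc_out = np.asarray(conc_out, dtype=float)
    conc_in = np.asarray(conc_in, dtype=float)
    if np.any(conc_out <= 0) or np.any(conc_in <= 0):
        raise DomainError("concentrations must be strictly positive")
    return (R_GAS * temperature) / (valence * FARADAY) * np.log(conc_out / conc_in)


def potassium_scaling(Ko: float, anchor: float = 5.4,
                      exponent: float = 0.5) -> float:
    """Multiplicative (Ko/anchor)**exponent scale on GK1 and GKr.

    The conductance of inward-rectifying potassium channels grows roughly
    with the square root of extracellular potassium; the anchor is the CRN
    default of 5.4 mM so the scale is 1 at the original model conditions.
    """
    if Ko <= 0 or anchor <= 0:
        raise DomainError("Ko and anchor must be positive")
    return float((Ko / anchor) ** exponent)


# ---------------------------------------------------------------------------
# Gate kinetics (vectorised over V; shared by the ODE right-hand side and the
# lookup-table builder used by the fast integrators)
# ---------------------------------------------------------------------------

V_GATE_NAMES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")


def _safe_ratio(num, den, limit):
    """num/den with a supplied limit where den vanishes (removable poles)."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-10
    out = np.where(small, limit, np.asarray(num, dtype=float) / np.where(small, 1.0, den))
    return out


def gate_kinetics(V):
    """Steady states and time constants of the 12 voltage-dependent gates.

    Returns ``{name: (inf, tau_ms)}`` with arrays broadcast over ``V``.
    """
    V = np.asarray(V, dtype=float)
    out = {}

    a = _safe_ratio(0.32 * (V + 47.13), 1.0 - np.exp(-0.1 * (V + 47.13)), 3.2)
    b = 0.08 * np.exp(-V / 11.0)
    out["m"] = (a / (a + b), 1.0 / (a + b))

    low = V < -40.0
    a = np.where(low, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b = np.where(
        low,
        3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * np.minimum(V, 0.0)),
        1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    out["h"] = (a / (a + b), 1.0 / (a + b))

    a = np.where(
        low,
        (-1.2714e5 * np.exp(0.2444 * np.minimum(V, 0.0)) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    b = np.where(
        low,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    out["j"] = (a / (a + b), 1.0 / (a + b))

    a = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    tau_shared = 1.0 / ((a + b) * KQ10)
    out["oa"] = (1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54)), tau_shared)
    out["ua"] = (1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6)), tau_shared)

    a = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    out["oi"] = (1.0 / (1.0 + np.exp((V + 43.1) / 5.3)), 1.0 / ((a + b) * KQ10))

    a = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b = np.exp((V - 158.0) / 16.0)
    out["ui"] = (1.0 / (1.0 + np.exp((V - 99.45) / 27.48)), 1.0 / ((a + b) * KQ10))

    a = _safe_ratio(0.0003 * (V + 14.1), 1.0 - np.exp(-(V + 14.1) / 5.0), 0.0015)
    b = _safe_ratio(
        7.3898e-5 * (V - 3.3328), np.exp((V - 3.3328) / 5.1237) - 1.0, 3.7836118e-4
    )
    out["xr"] = (1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5)), 1.0 / (a + b))

    a = _safe_ratio(4e-5 * (V - 19.9), 1.0 - np.exp(-(V - 19.9) / 17.0), 0.00068)
    b = _safe_ratio(3.5e-5 * (V - 19.9), np.exp((V - 19.9) / 9.0) - 1.0, 0.000315)
    out["xs"] = (1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7)), 0.5 / (a + b))

    e = np.exp(-(V + 10.0) / 6.24)
    tau_d = _safe_ratio(1.0 - e, 0.035 * (V + 10.0) * (1.0 + e), 4.579 / (1.0 + e))
    out["d"] = (1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0)), tau_d)

    out["f"] = (
        1.0 / (1.0 + np.exp((V + 28.0) / 6.9)),
        9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02),
    )

    e = np.exp(-(V - 7.9) / 5.0)
    tau_w = _safe_ratio(6.0 * (1.0 - e), (1.0 + 0.3 * e) * (V - 7.9), 6.0 * 0.2 / 1.3)
    out["w"] = (1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0)), tau_w)

    return out


# ---------------------------------------------------------------------------
# Currents and full right-hand side
# ---------------------------------------------------------------------------

def compute_currents(state: np.ndarray, params: CellParameters,
                     elec_pc: np.ndarray) -> CurrentSet:
    """Evaluate the 12 transmembrane currents (pA/pF).

    ``elec_pc`` is the (12, 3) per-current electrolyte array produced by
    :meth:`ElectrolyteOverrideMask.resolve`; row order follows
    ``CURRENT_NAMES``.
    """
    V = state[0]
    m, h, j = state[1], state[2], state[3]
    oa, oi, ua, ui = state[4], state[5], state[6], state[7]
    xr, xs, d, f, fca = state[8], state[9], state[10], state[11], state[12]
    Nai, Ki, Cai = state[16], state[17], state[18]

    T = params.temperature
    rt_f = R_GAS * T / FARADAY
    vf_rt = V / rt_f

    idx = {n: i for i, n in enumerate(CURRENT_NAMES)}

    def Ko_of(n):   # noqa: E731 - tiny local helpers
        return elec_pc[idx[n], 0]

    def Nao_of(n):
        return elec_pc[idx[n], 1]

    def Cao_of(n):
        return elec_pc[idx[n], 2]

    # INa
    ena = rt_f * np.log(Nao_of("INa") / Nai)
    i_na = params.g_na * m ** 3 * h * j * (V - ena)

    # IK1 with Ko-dependent conductance
    ek_k1 = rt_f * np.log(Ko_of("IK1") / Ki)
    gk1 = params.g_k1 * potassium_scaling(Ko_of("IK1"), params.k_anchor, params.k_exponent)
    i_k1 = gk1 * (V - ek_k1) / (1.0 + np.exp(0.07 * (V + 80.0)))

    # Ito
    ek = rt_f * np.log(Ko_of("Ito") / Ki)
    i_to = params.g_to * oa ** 3 * oi * (V - ek)

    # IKur (voltage-dependent maximal conductance)
    ek = rt_f * np.log(Ko_of("IKur") / Ki)
    g_kur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    i_kur = params.g_kur * g_kur * ua ** 3 * ui * (V - ek)

    # IKr with Ko-dependent conductance
    ek = rt_f * np.log(Ko_of("IKr") / Ki)
    gkr = params.g_kr * potassium_scaling(Ko_of("IKr"), params.k_anchor, params.k_exponent)
    i_kr = gkr * xr * (V - ek) / (1.0 + np.exp((V + 15.0) / 22.4))

    # IKs
    ek = rt_f * np.log(Ko_of("IKs") / Ki)
    i_ks = params.g_ks * xs ** 2 * (V - ek)

    # ICaL: fixed CRN driving term unless variable_eca
    if params.variable_eca:
        eca_l = rt_f / 2.0 * np.log(Cao_of("ICaL") / Cai)
        i_cal = params.g_cal * d * f * fca * (V - eca_l)
    else:
        i_cal = params.g_cal * d * f * fca * (V - 65.0)

    # background currents
    eca = rt_f / 2.0 * np.log(Cao_of("IbCa") / Cai)
    i_bca = params.g_bca * (V - eca)
    ena_b = rt_f * np.log(Nao_of("IbNa") / Nai)
    i_bna = params.g_bna * (V - ena_b)

    # Na/K pump
    ko_nak, nao_nak = Ko_of("INaK"), Nao_of("INaK")
    sigma = (np.exp(nao_nak / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vf_rt) + 0.0365 * sigma * np.exp(-vf_rt))
    i_nak = (params.i_nak_max * f_nak * (1.0 / (1.0 + (10.0 / Nai) ** 1.5))
             * ko_nak / (ko_nak + 1.5))

    # Na/Ca exchanger
    nao_x, cao_x = Nao_of("INaCa"), Cao_of("INaCa")
    e1 = np.exp(0.35 * vf_rt)
    e2 = np.exp(-0.65 * vf_rt)
    i_naca = (params.i_naca_max
              * (e1 * Nai ** 3 * cao_x - e2 * nao_x ** 3 * Cai)
              / ((87.5 ** 3 + nao_x ** 3) * (1.38 + cao_x) * (1.0 + 0.1 * e2)))

    # sarcolemmal Ca pump (no extracellular dependence)
    i_cap = params.i_cap_max * Cai / (0.0005 + Cai)

    return CurrentSet(i_na, i_k1, i_to, i_kur, i_kr, i_ks,
                      i_cal, i_bca, i_bna, i_nak, i_naca, i_cap)


def derivatives(state: np.ndarray, params: CellParameters,
                perturbed: ElectrolyteSet,
                reference: ElectrolyteSet | None = None,
                mask: ElectrolyteOverrideMask | None = None,
                stim: float = 0.0):
    """Full CRN++ right-hand side.

    Returns ``(dstate/dt, CurrentSet)``. ``stim`` is a depolarising stimulus
    current in pA/pF (positive depolarises). Raises :class:`NumericalError`
    naming the offending current if any rate is non-finite.
    """
    state = np.asarray(state, dtype=float)
    if reference is None:
        reference = perturbed
    if mask is None:
        mask = DEFAULT_MASK
    elec_pc = mask.resolve(perturbed, reference)

    cur = compute_currents(state, params, elec_pc)
    for name, val in zip(CURRENT_NAMES, cur):
        if not np.isfinite(val):
            raise NumericalError(f"non-finite current {name} at V={state[0]:.3f} mV")

    V, fca, u, v, w = state[0], state[12], state[13], state[14], state[15]
    Nai, Ki, Cai, Caup, Carel = state[16], state[17], state[18], state[19], state[20]

    dy = np.empty(N_STATES)

    dy[0] = -cur.total + stim

    kin = gate_kinetics(V)
    for i, name in enumerate(V_GATE_NAMES):
        inf, tau = kin[name]
        dy[1 + _VGATE_STATE_OFFSETS[i]] = (float(inf) - state[1 + _VGATE_STATE_OFFSETS[i]]) / float(tau)

    # Ca-dependent / flux-dependent gates
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    dy[12] = (fca_inf - fca) / 2.0

    i_rel = 30.0 * u ** 2 * v * w * (Carel - Cai)
    i_tr = (Caup - Carel) / 180.0
    i_up = 0.005 / (1.0 + 0.00092 / Cai)
    i_up_leak = 0.005 * Caup / 15.0

    fn = 1e-12 * V_REL * i_rel - 5e-13 / FARADAY * (0.5 * cur.ICaL * CM_PF
                                                    - 0.2 * cur.INaCa * CM_PF)
    u_inf = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 1.367e-15))
    dy[13] = (u_inf - u) / 8.0
    tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(fn - 3.4175e-13) / 1.367e-15))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 1.367e-15))
    dy[14] = (v_inf - v) / tau_v
    # w handled with the voltage gates above

    c_f_vi = CM_PF / (FARADAY * V_I)
    dy[16] = (-3.0 * cur.INaK - 3.0 * cur.INaCa - cur.IbNa - cur.INa) * c_f_vi
    dy[17] = (2.0 * cur.INaK - cur.IK1 - cur.Ito - cur.IKur - cur.IKr - cur.IKs) * c_f_vi

    b1 = ((2.0 * cur.INaCa - cur.ICap - cur.ICaL - cur.IbCa) * CM_PF
          / (2.0 * FARADAY * V_I)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + 0.07 * 0.0005 / (Cai + 0.0005) ** 2
          + 0.05 * 0.00238 / (Cai + 0.00238) ** 2)
    dy[18] = b1 / b2
    dy[19] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dy[20] = (i_tr - i_rel) / (1.0 + 10.0 * 0.8 / (Carel + 0.8) ** 2)

    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(dy))]
        raise NumericalError(f"non-finite rate(s) for state(s) {bad}")
    return dy, cur


# map V_GATE_NAMES order -> offset within state[1:]
_VGATE_STATE_OFFSETS = tuple(STATE_NAMES.index(n) - 1 for n in V_GATE_NAMES)


# ---------------------------------------------------------------------------
# Fibrosis remodelling
# ---------------------------------------------------------------------------

def apply_fibrosis_remodelling(params: CellParameters) -> CellParameters:
    """Fibrotic-tissue electrophysiology: GNa x0.60, GK1 x0.50, GCaL x0.50.

    Apply-once semantics: calling on already-remodelled parameters raises.
    """
    if params.fibrotic:
        raise DomainError("fibrosis remodelling already applied")
    return replace(params, g_na=params.g_na * 0.60, g_k1=params.g_k1 * 0.50,
                   g_cal=params.g_cal * 0.50, fibrotic=True)
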