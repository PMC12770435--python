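"""Latin-hypercube designs, Gaussian-process emulation and Sobol indices.

The electrolyte inputs are sampled uniformly over their clinical ranges
(reference +/- the stated fractions: [K+]o 4.5 +/- 1.5 mM, [Na+]o 140 +/-
35 mM, [Ca2+]o 1.8 +/- 0.45 mM). Variance-based first-, second- and
total-order Sobol indices are estimated with the Saltelli pick-freeze scheme
(Saltelli-2010 first-order estimator, Jansen total-order estimator) on
quasi-random A/B/AB_i/BA_i matrices. Because each tissue/cell simulation is
expensive, the default pipeline fits one Gaussian-process emulator per
quantity of interest on a small Latin-hypercube design and estimates the
indices on the emulator mean; direct simulation at reduced N is available
via the same ``sobol_indices`` entry point.

Per-current attribution uses the electrolyte override mask of the cell
model: the perturbed electrolyte enters only the mathematical expression of
one named current while every other current sees the reference value; the
output variance so produced, normalised across currents, gives the
per-current "doughnut" fractions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .ionic import (
    CURRENT_NAMES, CellParameters, DomainError, ElectrolyteOverrideMask,
    ElectrolyteSet, REFERENCE_ELECTROLYTES,
)

__all__ = [
    "ELECTROLYTE_NAMES", "DEFAULT_RANGES", "ElectrolyteDesign", "lhs_design",
    "GPEmulator", "fit_emulator", "SobolResult", "sobol_indices",
    "attribution_gsa", "per_current_attribution", "CURRENT_ELECTROLYTE_DEPS",
]

ELECTROLYTE_NAMES = ("Ko", "Nao", "Cao")

#: uniform GSA/LHS ranges: reference +/- 1.5 / 35 / 0.45 mM
DEFAULT_RANGES = {
    "Ko": (3.0, 6.0),
    "Nao": (105.0, 175.0),
    "Cao": (1.35, 2.25),
}

#: which extracellular species each current's equations contain
CURRENT_ELECTROLYTE_DEPS = {
    "INa": ("Nao",),
    "IK1": ("Ko",),
    "Ito": ("Ko",),
    "IKur": ("Ko",),
    "IKr": ("Ko",),
    "IKs": ("Ko",),
    "ICaL": ("Cao",),   # only with the variable-ECa formulation
    "IbCa": ("Cao",),
    "IbNa": ("Nao",),
    "INaK": ("Ko", "Nao"),
    "INaCa": ("Nao", "Cao"),
    "ICap": (),
}


def _ranges_array(ranges) -> np.ndarray:
    if isinstance(ranges, dict):
        return np.array([ranges[k] for k in ELECTROLYTE_NAMES], dtype=float)
    return np.asarray(ranges, dtype=float)


@dataclass
class ElectrolyteDesign:
    """n x 3 sampled electrolyte combinations (columns Ko, Nao, Cao)."""

    samples: np.ndarray
    ranges: np.ndarray
    seed: int
    includes_baseline: bool = False

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def with_baseline(self, reference: ElectrolyteSet = REFERENCE_ELECTROLYTES
                      ) -> "ElectrolyteDesign":
        """Append the reference combination as the final (baseline) row."""
        if self.includes_baseline:
            return self
        rows = np.vstack([self.samples, reference.as_array()])
        return ElectrolyteDesign(rows, self.ranges, self.seed, True)

    def electrolyte_sets(self) -> list:
        return [ElectrolyteSet(*row) for row in self.samples]

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.samples, columns=ELECTROLYTE_NAMES)
        if self.includes_baseline:
            df["is_baseline"] = [False] * (self.n - 1) + [True]
        return df


def lhs_design(ranges=None, n: int = 30, seed: int = 0) -> ElectrolyteDesign:
    """Plain (maximin-free) Latin hypercube over the electrolyte ranges.

    Each column has exactly one sample per equal-probability stratum. A
    degenerate range (lo == hi) yields a constant column with a warning.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rg = _ranges_array(DEFAULT_RANGES if ranges is None else ranges)
    sampler = qmc.LatinHypercube(d=rg.shape[0], seed=seed)
    u = sampler.random(n)
    lo, hi = rg[:, 0], rg[:, 1]
    if np.any(lo > hi):
        raise DomainError("range lower bound exceeds upper bound")
    degenerate = lo == hi
    if degenerate.any():
        import warnings
        names = [ELECTROLYTE_NAMES[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"degenerate range(s) for {names}; column(s) constant")
    return ElectrolyteDesign(lo + u * (hi - lo), rg, seed)


# ---------------------------------------------------------------------------
# Gaussian-process emulator
# ---------------------------------------------------------------------------

class GPEmulator:
    """Stationary-kernel GP mapping electrolyte triples to one QoI.

    Inputs are scaled to the unit cube internally; an anisotropic RBF kernel
    with a white-noise nugget is fitted by marginal-likelihood optimisation
    with a fixed number of seeded restarts.
    """

    def __init__(self, ranges, seed: int = 0, n_restarts: int = 3,
                 nugget: float = 1e-8):
        self.ranges = _ranges_array(ranges)
        self.seed = seed
        self.n_restarts = n_restarts
        self.nugget = nugget
        self._gp = None

    def _scale(self, X):
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        return (np.asarray(X, dtype=float) - lo) / span

    def fit(self, X, y) -> "GPEmulator":
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 10:
            raise DomainError("need >= 10 training rows for the emulator")
        bad = np.flatnonzero(~np.isfinite(y))
        if bad.size:
            raise DomainError(f"non-finite QoI at design rows {bad.tolist()}")
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(length_scale=np.ones(X.shape[1]),
                        length_scale_bounds=(1e-2, 1e2))
                  + WhiteKernel(self.nugget, (1e-12, 1e-2)))
        self._gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True,
            n_restarts_optimizer=self.n_restarts,
            random_state=self.seed)
        self._gp.fit(self._scale(X), y)
        return self

    def predict(self, X, return_std: bool = False):
        if self._gp is None:
            raise DomainError("emulator not fitted")
        return self._gp.predict(self._scale(np.atleast_2d(X)),
                                return_std=return_std)

    def __call__(self, X):
        return self.predict(X)


def fit_emulator(X, y, ranges=None, seed: int = 0) -> GPEmulator:
    """Fit a GP emulator of one QoI on an electrolyte design."""
    rg = DEFAULT_RANGES if ranges is None else ranges
    return GPEmulator(rg, seed=seed).fit(X, y)


# ---------------------------------------------------------------------------
# Sobol variance-based indices
# ---------------------------------------------------------------------------

@dataclass
class SobolResult:
    """First/second/total-order Sobol estimates and doughnut fractions."""

    names: tuple
    s1: np.ndarray              # (d,)
    s2: dict                    # {(i, j): estimate}
    st: np.ndarray              # (d,)
    variance: float
    n: int
    seed: int
    zero_variance: bool = False
    doughnut: dict = field(default_factory=dict)

    def higher_order(self) -> float:
        """Residual variance fraction beyond first+second order."""
        return 1.0 - float(np.sum(self.s1)) - float(sum(self.s2.values()))


def _doughnut(names, s1, s2) -> dict:
    """Clamp small negative estimates to 0 and normalise so parts sum to 1."""
    parts = {n: max(0.0, float(v)) for n, v in zip(names, s1)}
    for (i, j), v in s2.items():
        parts[f"{names[i]}*{names[j]}"] = max(0.0, float(v))
    rem = max(0.0, 1.0 - sum(parts.values()))
    parts["higher-order"] = rem
    total = sum(parts.values())
    if total <= 0:
        return {k: np.nan for k in parts}
    return {k: v / total for k, v in parts.items()}


def sobol_indices(f, ranges, N: int = 1024, seed: int = 0,
                  names=None, second_order: bool = True) -> SobolResult:
    """Saltelli pick-freeze estimation of S1, S2 and ST.

    ``f`` maps an (m, d) array to (m,) outputs (an emulator mean or a direct
    simulation wrapper). Inputs are uniform over ``ranges`` ((d, 2) array or
    electrolyte dict); ``N`` must be a power of two (quasi-random base
    sample). Raw (possibly slightly negative) estimates are reported;
    clamping happens only in the normalised doughnut fractions.
    """
    rg = _ranges_array(ranges)
    d = rg.shape[0]
    if names is None:
        names = ELECTROLYTE_NAMES if d == 3 else tuple(f"x{i}" for i in range(d))
    if N < 2 or (N & (N - 1)) != 0:
        raise DomainError("N must be a power of two")

    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    base = sampler.random(N)
    lo, hi = rg[:, 0], rg[:, 1]
    A = lo + base[:, :d] * (hi - lo)
    B = lo + base[:, d:] * (hi - lo)

    blocks = [A, B]
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks.append(ABi)
    if second_order:
        for i in range(d):
            BAi = B.copy()
            BAi[:, i] = A[:, i]
            blocks.append(BAi)

    Y = np.asarray(f(np.vstack(blocks)), dtype=float)
    if not np.all(np.isfinite(Y)):
        raise DomainError("non-finite model output in Sobol evaluation")
    fA = Y[:N]
    fB = Y[N:2 * N]
    fAB = [Y[(2 + i) * N:(3 + i) * N] for i in range(d)]
    fBA = [Y[(2 + d + i) * N:(3 + d + i) * N] for i in range(d)] if second_order else None

    var = float(np.var(np.concatenate([fA, fB]), ddof=0))
    if var < 1e-300:
        return SobolResult(tuple(names), np.full(d, np.nan), {},
                           np.full(d, np.nan), 0.0, N, seed,
                           zero_variance=True)

    s1 = np.array([np.mean(fB * (fAB[i] - fA)) / var for i in range(d)])
    st = np.array([0.5 * np.mean((fA - fAB[i]) ** 2) / var for i in range(d)])
    s2 = {}
    if second_order:
        for i, j in itertools.combinations(range(d), 2):
            vij = np.mean(fBA[i] * fAB[j] - fA * fB) / var
            s2[(i, j)] = float(vij - s1[i] - s1[j])

    res = SobolResult(tuple(names), s1, s2, st, var, N, seed)
    res.doughnut = _doughnut(res.names, s1, s2)
    return res


# ---------------------------------------------------------------------------
# Per-current attribution through the electrolyte override mask
# ---------------------------------------------------------------------------

def _masked_qoi_fn(current_name: str, electrolyte_name: str, qoi: str,
                   params: CellParameters, cl_ms: float, n_prepace: int):
    """0-D biomarker evaluated with the perturbed electrolyte fed only into
    ``current_name``; every other current sees the reference set."""
    from .protocols0d import limit_cycle_ap

    mask = ElectrolyteOverrideMask.only_perturbed(current_name)
    e_idx = ELECTROLYTE_NAMES.index(electrolyte_name)

    def f(X):
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0])
        ref = REFERENCE_ELECTROLYTES.as_array()
        for r, x in enumerate(X):
            vals = ref.copy()
            vals[e_idx] = x[0] if X.shape[1] == 1 else x[e_idx]
            pert = ElectrolyteSet(*vals)
            bm, _, _ = limit_cycle_ap(params, pert, cl_ms=cl_ms,
                                      n_prepace=n_prepace,
                                      reference=REFERENCE_ELECTROLYTES,
                                      mask=mask)
            out[r] = getattr(bm, qoi)
        return out

    return f


def attribution_gsa(current_name: str, electrolyte_name: str, qoi: str = "apd70",
                    ranges=None, n_points: int = 8,
                    params: CellParameters | None = None,
                    cl_ms: float = 1000.0, n_prepace: int = 60) -> SobolResult:
    """Output variance produced when one electrolyte varies only inside one
    current's equations (all other currents pinned to reference).

    The input is one-dimensional, so the useful quantity is the raw output
    variance (S1 = ST = 1 trivially when the variance is non-zero); variances
    across currents are normalised by :func:`per_current_attribution`. The
    QoI is evaluated by direct 0-D simulation on an ``n_points`` uniform grid
    over the electrolyte's range.
    """
    if current_name not in CURRENT_NAMES:
        raise DomainError(f"unknown current {current_name}")
    rg = _ranges_array(DEFAULT_RANGES if ranges is None else ranges)
    e_idx = ELECTROLYTE_NAMES.index(electrolyte_name)
    lo, hi = rg[e_idx]
    params = params or CellParameters()

    f = _masked_qoi_fn(current_name, electrolyte_name, qoi, params, cl_ms, n_prepace)
    xs = np.linspace(lo, hi, n_points)[:, None]
    y = f(xs)
    var = float(np.var(y, ddof=0))
    depends = electrolyte_name in CURRENT_ELECTROLYTE_DEPS[current_name]
    zero = (var < 1e-12) or not depends
    s1 = np.array([1.0 if not zero else np.nan])
    return SobolResult((electrolyte_name,), s1, {}, s1.copy(), var,
                       n_points, 0, zero_variance=zero)


def per_current_attribution(electrolyte_name: str, currents=None,
                            qoi: str = "apd70", ranges=None,
                            params: CellParameters | None = None,
                            n_points: int = 8, cl_ms: float = 1000.0,
                            n_prepace: int = 60) -> dict:
    """Per-current variance attribution for one electrolyte.

    Returns ``{current: {"variance": v, "fraction": v / sum}}`` over the
    currents whose equations contain the electrolyte (or an explicit list);
    fractions sum to 1 whenever any variance is non-zero.
    """
    if currents is None:
        currents = [c for c, deps in CURRENT_ELECTROLYTE_DEPS.items()
                    if electrolyte_name in deps]
    res = {c: attribution_gsa(c, electrolyte_name, qoi=qoi, ranges=ranges,
                              n_points=n_points, params=params, cl_ms=cl_ms,
                              n_prepace=n_prepace)
           for c in currents}
    total = sum(r.variance for r in res.values())
    return {c: {"variance": r.variance,
                "fraction": (r.variance / total if total > 0 else np.nan),
                "zero_variance": r.zero_variance}
            for c, r in res.items()}
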