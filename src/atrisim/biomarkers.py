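"""Activation/repolarisation maps and cohort-style QoI summaries.

From a recorded tissue simulation, per-node maps are built of

* LAT  -- local activation time, argmax dV/dt within the analysis window;
* LRT  -- local repolarisation time, first 90 % recovery of the local
  amplitude after activation;
* APD90 = LRT - LAT;
* CV   -- conduction-velocity magnitude, 1/|grad LAT| by central differences.

Summaries are the medians (mAPD, mCV) and 2.5-97.5 inter-percentile ranges
(DAPD, DCV) over valid nodes, plus their relative variations against a
baseline summary. Nodes with amplitude below 40 mV are masked invalid and
excluded from the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ionic import DomainError
from .monodomain import Geometry1D, Geometry2D, TissueResult

__all__ = [
    "ActivationMaps", "BiomarkerSummary", "lat_from_vm",
    "activation_repolarisation_maps", "cv_map_from_lat", "summarise_qoi",
]


@dataclass
class ActivationMaps:
    lat: np.ndarray     # ms
    lrt: np.ndarray     # ms
    apd90: np.ndarray   # ms
    cv: np.ndarray | None  # m/s (filled by cv_map_from_lat)
    valid: np.ndarray   # bool


@dataclass
class BiomarkerSummary:
    """Median / inter-percentile QoIs and relative variations vs baseline."""

    mAPD: float
    mCV: float
    DAPD: float
    DCV: float
    rel_mAPD: float = 0.0
    rel_mCV: float = 0.0
    rel_DAPD: float = 0.0
    rel_DCV: float = 0.0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mAPD", "mCV", "DAPD", "DCV",
                 "rel_mAPD", "rel_mCV", "rel_DAPD", "rel_DCV")}


def _window_slice(result: TissueResult, window):
    t = result.t
    if window is None:
        sel = np.ones(t.size, dtype=bool)
    else:
        sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise DomainError("empty analysis window")
    return t[sel], result.vm[sel]


def _refine_peak_time(t, dv, idx) -> np.ndarray:
    """Sub-sample peak time by 3-point parabolic interpolation of dV/dt."""
    lat = t[idx].astype(float)
    n = dv.shape[1]
    for c in range(n):
        i = idx[c]
        if 0 < i < dv.shape[0] - 1:
            y0, y1, y2 = dv[i - 1, c], dv[i, c], dv[i + 1, c]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:  # proper maximum
                delta = 0.5 * (y0 - y2) / denom
                lat[c] += np.clip(delta, -0.5, 0.5) * (t[i] - t[i - 1])
    return lat


def lat_from_vm(result: TissueResult, window=None) -> np.ndarray:
    """Per-node LAT (ms) = time of max dV/dt (sub-sample refined);
    NaN for non-activated nodes."""
    t, vm = _window_slice(result, window)
    vm = vm.astype(np.float64)
    dv = np.gradient(vm, t, axis=0)
    idx = np.argmax(dv, axis=0)
    lat = _refine_peak_time(t, dv, idx)
    amp = vm.max(axis=0) - vm.min(axis=0)
    lat[amp < 40.0] = np.nan
    return lat


def activation_repolarisation_maps(result: TissueResult,
                                   window=None,
                                   min_amplitude: float = 40.0) -> ActivationMaps:
    """LAT / LRT / APD90 maps for one beat inside ``window``."""
    t, vm = _window_slice(result, window)
    vm = vm.astype(np.float64)
    nt, n = vm.shape
    dv = np.gradient(vm, t, axis=0)
    iup = np.argmax(dv, axis=0)
    lat = _refine_peak_time(t, dv, iup)

    vmin = vm.min(axis=0)
    # per-node peak after activation
    lrt = np.full(n, np.nan)
    apd = np.full(n, np.nan)
    amp = vm.max(axis=0) - vmin
    valid = amp >= min_amplitude
    for c in np.flatnonzero(valid):
        seg = vm[iup[c]:, c]
        ipk = int(np.argmax(seg))
        peak = seg[ipk]
        level = peak - 0.90 * (peak - vmin[c])
        below = np.flatnonzero(seg[ipk:] <= level)
        if below.size == 0:
            continue  # activated but not yet repolarised: LRT/APD stay NaN
        i = ipk + below[0] + iup[c]
        tt = t
        if i > 0 and vm[i, c] != vm[i - 1, c]:
            tc = tt[i - 1] + (tt[i] - tt[i - 1]) * (vm[i - 1, c] - level) / (vm[i - 1, c] - vm[i, c])
        else:
            tc = tt[i]
        lrt[c] = tc
        apd[c] = tc - lat[c]
    lat = np.where(valid, lat, np.nan)
    return ActivationMaps(lat=lat, lrt=lrt, apd90=apd, cv=None, valid=valid)


def cv_map_from_lat(maps: ActivationMaps, geometry,
                    grad_floor: float = 1e-3) -> np.ndarray:
    """CV magnitude (m/s) = 1/|grad LAT| with central differences.

    Gradient magnitudes below ``grad_floor`` ms/mm (plateaus / blocks) and
    nodes with invalid neighbours are masked NaN. Sheet edges use one-sided
    differences (via numpy.gradient).
    """
    if not maps.valid.any():
        raise DomainError("all nodes invalid; no CV map")
    dx = geometry.dx_mm
    if isinstance(geometry, Geometry1D):
        lat = maps.lat
        g = np.gradient(lat, dx)
        mag = np.abs(g)
    else:
        ny, nx = geometry.shape
        lat = maps.lat.reshape(ny, nx)
        gy, gx = np.gradient(lat, dx, dx)
        mag = np.hypot(gx, gy).reshape(-1)
    cv = np.where(mag > grad_floor, 1.0 / np.where(mag > grad_floor, mag, 1.0), np.nan)
    cv[~maps.valid] = np.nan
    maps.cv = cv
    return cv


def _ipr(x: np.ndarray) -> float:
    lo, hi = np.percentile(x, [2.5, 97.5])  # linear interpolation of order stats
    return float(hi - lo)


def summarise_qoi(maps: ActivationMaps,
                  baseline: "BiomarkerSummary | None" = None,
                  min_valid: int = 10) -> BiomarkerSummary:
    """Median and 2.5-97.5 inter-percentile summaries over valid nodes."""
    ok_apd = maps.valid & np.isfinite(maps.apd90)
    cv = maps.cv if maps.cv is not None else np.full_like(maps.apd90, np.nan)
    ok_cv = maps.valid & np.isfinite(cv)
    if ok_apd.sum() < min_valid or ok_cv.sum() < min_valid:
        raise DomainError(
            f"need >= {min_valid} valid nodes (APD {int(ok_apd.sum())}, "
            f"CV {int(ok_cv.sum())})")
    s = BiomarkerSummary(
        mAPD=float(np.median(maps.apd90[ok_apd])),
        mCV=float(np.median(cv[ok_cv])),
        DAPD=_ipr(maps.apd90[ok_apd]),
        DCV=_ipr(cv[ok_cv]),
    )
    if baseline is not None:
        for name in ("mAPD", "mCV", "DAPD", "DCV"):
            ref = getattr(baseline, name)
            if ref == 0:
                raise DomainError(f"baseline {name} is zero; relative QoI undefined")
            setattr(s, "rel_" + name, (getattr(s, name) - ref) / ref)
    return s
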