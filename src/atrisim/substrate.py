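"""Synthetic atrial substrates emulating an LGE-intensity-ratio cohort.

Real atrial substrates are characterised by an image intensity ratio (IIR)
field from late-gadolinium-enhancement MRI, thresholded into six tissue
classes with IIR > 1.22 marking fibrosis; across patients the fibrotic
fraction is distributed with mean 21 %, sd 15 %, range 0-70 % of the tissue.
This module generates 2-D stand-ins with the same statistical structure:

* a spatially correlated log-normal IIR field (filtered Gaussian noise,
  correlation length ~5 mm -- a qualitative stand-in for patchy fibrosis);
* the field's median is shifted by quantile matching so the fraction of
  nodes above 1.22 equals a draw from the clipped normal target
  distribution;
* six regions by five increasing IIR cut-points (1.22 among them), each with
  its own cell parameters (fibrotic regions remodelled) and conductivities;
* three stimulus boxes in normalised sheet coordinates standing in for the
  universal-atrial-coordinate windows used on real anatomies: a
  coronary-sinus analogue (0.5-0.7 x 0.8-0.9), a left-atrial-appendage
  analogue (0.9-0.91 x 0.9-0.91) and a roof analogue (0.48-0.49 x
  0.48-0.49).

Normalised sheet coordinates are an analogy to universal atrial coordinates,
not an implementation of them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .ionic import CellParameters, DomainError, apply_fibrosis_remodelling
from .monodomain import DEFAULT_CONDUCTIVITIES, Geometry2D, write_vtk_structured

__all__ = [
    "FIBROTIC_IIR_THRESHOLD", "STIMULUS_BOXES", "SubstrateConfig", "Substrate",
    "generate_iir_field", "build_substrate", "generate_cohort",
]

FIBROTIC_IIR_THRESHOLD = 1.22

#: normalised-coordinate stimulus windows (x0, x1, y0, y1)
STIMULUS_BOXES = {
    "CS": (0.5, 0.7, 0.8, 0.9),
    "LAA": (0.9, 0.91, 0.9, 0.91),
    "roof": (0.48, 0.49, 0.48, 0.49),
}


@dataclass(frozen=True)
class SubstrateConfig:
    """Generator configuration (defaults are the study conditions)."""

    size_cm: float = 5.0
    spacing_um: float = 500.0
    correlation_mm: float = 5.0
    fibrosis_mean: float = 0.21
    fibrosis_sd: float = 0.15
    fibrosis_range: tuple = (0.0, 0.70)
    #: five increasing IIR cut-points defining six classes; 1.22 is the
    #: fibrotic boundary (classes 4 and 5 are fibrotic)
    iir_thresholds: tuple = (0.9, 1.0, 1.1, FIBROTIC_IIR_THRESHOLD, 1.4)
    iir_log_sd: float = 0.18
    conductivities: tuple = DEFAULT_CONDUCTIVITIES
    area_jitter_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        thr = self.iir_thresholds
        if any(b <= a for a, b in zip(thr, thr[1:])) or len(thr) != 5:
            raise DomainError("need five strictly increasing IIR cut-points")
        if FIBROTIC_IIR_THRESHOLD not in thr:
            raise DomainError(f"{FIBROTIC_IIR_THRESHOLD} must be a cut-point")
        lo, hi = self.fibrosis_range
        if not 0.0 <= lo < hi <= 1.0:
            raise DomainError("fibrosis_range must satisfy 0 <= lo < hi <= 1")

    @property
    def n_side(self) -> int:
        return int(round(self.size_cm * 1e4 / self.spacing_um)) + 1


@dataclass
class Substrate:
    """One synthetic 2-D atrial sheet."""

    iir: np.ndarray                 # per-node IIR
    region_id: np.ndarray           # per-node class 0..5
    geometry: Geometry2D
    params_by_region: tuple         # CellParameters per region
    stimulus_masks: dict            # name -> bool (n,)
    config: SubstrateConfig
    seed: int
    target_fraction: float

    @property
    def fibrosis_fraction(self) -> float:
        """Fraction of nodes with IIR above the fibrotic threshold."""
        return float(np.mean(self.iir > FIBROTIC_IIR_THRESHOLD))

    @property
    def surface_area_cm2(self) -> float:
        g = self.geometry
        return g.nx * g.ny * (g.spacing_um * 1e-4) ** 2

    def save(self, directory) -> None:
        """Serialise to a directory: VTK maps + JSON manifest."""
        import os
        os.makedirs(directory, exist_ok=True)
        g = self.geometry
        write_vtk_structured(
            os.path.join(directory, "substrate.vtk"), g.nx, g.ny, g.dx_mm,
            {"IIR": self.iir, "region_id": self.region_id.astype(float)})
        manifest = {
            "seed": self.seed,
            "target_fraction": self.target_fraction,
            "fibrosis_fraction": self.fibrosis_fraction,
            "nx": g.nx, "ny": g.ny, "spacing_um": g.spacing_um,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)


def _clipped_normal_fraction(rng: np.random.Generator,
                             cfg: SubstrateConfig) -> float:
    lo, hi = cfg.fibrosis_range
    return float(np.clip(rng.normal(cfg.fibrosis_mean, cfg.fibrosis_sd), lo, hi))


def generate_iir_field(config: SubstrateConfig, seed: int,
                       target_fraction: float | None = None):
    """Correlated log-normal IIR field with a prescribed fibrotic fraction.

    The target fraction is drawn from the clipped normal cohort distribution
    unless given explicitly. The smoothed standard-normal field ``z`` is
    mapped to ``IIR = exp(mu + s * z)`` with ``mu`` set by quantile matching
    so the empirical fraction of nodes above 1.22 equals the target (to
    within one node). Bitwise reproducible for a fixed seed.

    Returns ``(iir (n,), target_fraction)``.
    """
    rng = np.random.default_rng(seed)
    if target_fraction is None:
        target_fraction = _clipped_normal_fraction(rng, config)
    lo, hi = config.fibrosis_range
    if not lo <= target_fraction <= hi:
        raise DomainError(
            f"target fraction {target_fraction} outside [{lo}, {hi}]")

    n = config.n_side
    noise = rng.standard_normal((n, n))
    sigma_nodes = config.correlation_mm / (config.spacing_um * 1e-3)
    z = ndimage.gaussian_filter(noise, sigma=sigma_nodes, mode="reflect")
    z = (z - z.mean()) / z.std()
    z = z.reshape(-1)

    s = config.iir_log_sd
    if target_fraction <= 0.0:
        mu = np.log(FIBROTIC_IIR_THRESHOLD) - s * (z.max() + 0.5)
    elif target_fraction >= 1.0:
        mu = np.log(FIBROTIC_IIR_THRESHOLD) - s * (z.min() - 0.5)
    else:
        q = np.quantile(z, 1.0 - target_fraction)
        mu = np.log(FIBROTIC_IIR_THRESHOLD) - s * q
    iir = np.exp(mu + s * z)
    return iir, float(target_fraction)


def segment_regions(iir: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Region ids 0..len(thresholds) by increasing IIR cut-points."""
    return np.searchsorted(np.asarray(thresholds), iir, side="right").astype(np.int64)


def _box_mask(nx: int, ny: int, box: tuple) -> np.ndarray:
    x0, x1, y0, y1 = box
    xs = np.arange(nx) / (nx - 1)
    ys = np.arange(ny) / (ny - 1)
    mx = (xs >= x0) & (xs <= x1)
    my = (ys >= y0) & (ys <= y1)
    return (my[:, None] & mx[None, :]).reshape(-1)


def build_substrate(iir: np.ndarray, config: SubstrateConfig,
                    seed: int = 0, target_fraction: float = np.nan,
                    base_params: CellParameters | None = None) -> Substrate:
    """Segment an IIR field into a simulation-ready substrate.

    Regions above the fibrotic cut-point receive remodelled cell parameters
    and the reduced conductivities of the region table; the three stimulus
    boxes are placed at their normalised-coordinate windows (a box that
    discretises to no node is expanded to its nearest node with a warning).
    """
    iir = np.asarray(iir, dtype=float).reshape(-1)
    if not np.all(np.isfinite(iir)):
        raise DomainError("IIR field must be finite")
    n = config.n_side
    if iir.size != n * n:
        raise DomainError(f"field size {iir.size} != {n}x{n}")

    region = segment_regions(iir, config.iir_thresholds)
    geometry = Geometry2D(nx=n, ny=n, spacing_um=config.spacing_um,
                          region_id=region, conductivities=config.conductivities)

    healthy = base_params or CellParameters()
    fibrotic = apply_fibrosis_remodelling(healthy)
    fib_start = list(config.iir_thresholds).index(FIBROTIC_IIR_THRESHOLD) + 1
    params_by_region = tuple(
        fibrotic if r >= fib_start else healthy for r in range(6))

    masks = {}
    for name, box in STIMULUS_BOXES.items():
        m = _box_mask(n, n, box)
        if not m.any():
            x0, x1, y0, y1 = box
            cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
            ix = int(round(cx * (n - 1)))
            iy = int(round(cy * (n - 1)))
            m = np.zeros(n * n, dtype=bool)
            m[iy * n + ix] = True
            warnings.warn(f"stimulus box {name} empty after discretisation; "
                          "expanded to nearest node")
        masks[name] = m

    return Substrate(iir=iir, region_id=region, geometry=geometry,
                     params_by_region=params_by_region, stimulus_masks=masks,
                     config=config, seed=seed, target_fraction=target_fraction)


def generate_cohort(n: int, config: SubstrateConfig | None = None,
                    seed: int = 0) -> list:
    """Generate ``n`` independent substrates (seeds spawned from ``seed``).

    Per-substrate sheet size is jittered (lognormal, sd ``area_jitter_sd``)
    to provide the atrial-surface-area feature; the fibrotic fraction of each
    substrate is an independent draw from the clipped cohort distribution.
    """
    if n < 0:
        raise DomainError("n must be >= 0")
    config = config or SubstrateConfig()
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(sub_seed)
        jitter = float(np.exp(rng.normal(0.0, config.area_jitter_sd)))
        spacing = config.spacing_um
        side = max(3, int(round(config.size_cm * jitter * 1e4 / spacing)) + 1)
        cfg = replace(config, size_cm=(side - 1) * spacing * 1e-4, seed=sub_seed)
        iir, frac = generate_iir_field(cfg, sub_seed)
        out.append(build_substrate(iir, cfg, seed=sub_seed, target_fraction=frac))
    return out
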