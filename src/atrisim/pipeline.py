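"""Configuration, seeding, manifests and cohort-level pipeline runners.

Three runners tie the stages together:

* :func:`run_cell_gsa` — 0-D electrolyte GSA of action-potential biomarkers
  for healthy and fibrotic myocytes (LHS design -> limit-cycle biomarkers ->
  GP emulator per QoI -> Sobol indices);
* :func:`run_strand_cv` — strand conduction velocity across cycle lengths
  400/500/700/1000 ms for each electrolyte set, with conduction block
  reported as a flag rather than a number;
* :func:`run_cohort` — synthetic-substrate cohort: paced-activation QoI
  table (relative to the per-substrate baseline), arrhythmia-induction
  endpoint table and machine-learning attribution reports.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` spawns, recorded in a :class:`RunManifest`
that round-trips losslessly through JSON. Scale knobs (design size, pre-pace
beats, sheet size, tracking window) default to desk-scale values; the
"paper" profile raises them to the full protocol sizes (15-min pre-pacing,
30-sample designs, 100-substrate cohorts) for cluster use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biomarkers import activation_repolarisation_maps, cv_map_from_lat, summarise_qoi
from .gsa import (
    DEFAULT_RANGES, ELECTROLYTE_NAMES, fit_emulator, lhs_design, sobol_indices,
)
from .induction import InductionConfig, InductionProtocol, classify_episode, run_protocol, screen_single_stimulus
from .ionic import (
    CellParameters, DomainError, ElectrolyteSet, REFERENCE_ELECTROLYTES,
    apply_fibrosis_remodelling,
)
from .ml import ENDPOINT_NAMES, FeatureTable, GuardError, attribution_report
from .monodomain import StimulusEvent, solve_monodomain, strand_cv_protocol
from .protocols0d import limit_cycle_ap
from .substrate import SubstrateConfig, generate_cohort

__all__ = [
    "PipelineConfig", "RunManifest", "stage_seed",
    "run_cell_gsa", "run_strand_cv", "run_cohort",
]

QOI_0D = ("apd70", "apd90", "rmp", "plateau_peak")
STRAND_CLS = (400.0, 500.0, 700.0, 1000.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Scale and protocol knobs for the pipeline runners."""

    profile: str = "desk"
    seed: int = 0
    # designs
    n_lhs: int = 30                 # electrolyte combinations per design
    gsa_N: int = 1024               # Sobol base sample on the emulator
    # 0-D
    prepace_beats: int = 100        # desk-scale train (full protocol: 15 min)
    cl_0d_ms: float = 1000.0
    # strand
    strand_cls: tuple = STRAND_CLS
    strand_design_n: int = 5        # electrolyte sets per CL (desk scale)
    # cohort
    n_substrates: int = 2
    substrate: SubstrateConfig = field(default_factory=SubstrateConfig)
    induction: InductionConfig = field(default_factory=InductionConfig)
    protocols: tuple = ("burst_LAA", "burst_roof", "four_spirals")
    map_out_dt: float = 1.0
    ml_n_permutations: int = 100

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "PipelineConfig":
        """Full protocol sizes (cluster-scale; hours to days on one CPU)."""
        return cls(profile="paper", seed=seed, n_lhs=30, gsa_N=4096,
                   prepace_beats=900, strand_design_n=30, n_substrates=100,
                   induction=InductionConfig(n_prepace=900))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "substrate" in raw:
            raw["substrate"] = SubstrateConfig(**{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in raw["substrate"].items()})
        if "induction" in raw:
            raw["induction"] = InductionConfig(**raw["induction"])
        for key in ("strand_cls", "protocols"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


STAGE_NAMES = ("substrate", "design", "gsa", "ml")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    if stage not in STAGE_NAMES:
        raise DomainError(f"unknown stage {stage}")
    ss = np.random.SeedSequence(master, spawn_key=(STAGE_NAMES.index(stage),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    master_seed: int
    stage_seeds: dict
    version: str
    started: float
    finished: float | None = None
    outputs: dict = field(default_factory=dict)

    @classmethod
    def start(cls, config: PipelineConfig) -> "RunManifest":
        from . import __version__
        return cls(config_hash=config.config_hash(), master_seed=config.seed,
                   stage_seeds={s: stage_seed(config.seed, s) for s in STAGE_NAMES},
                   version=__version__, started=time.time())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _cell_qoi_table(params: CellParameters, design, config: PipelineConfig
                    ) -> pd.DataFrame:
    rows = []
    for es in design.electrolyte_sets():
        bm, _, _ = limit_cycle_ap(params, es, cl_ms=config.cl_0d_ms,
                                  n_prepace=config.prepace_beats)
        rows.append({**{k: getattr(es, k) for k in ELECTROLYTE_NAMES},
                     **{q: getattr(bm, q) for q in QOI_0D}})
    return pd.DataFrame(rows)


def run_cell_gsa(config: PipelineConfig | None = None) -> dict:
    """0-D biomarker GSA for the healthy and fibrotic myocyte.

    Returns ``{"manifest", "designs", "qoi", "sobol"}``; the Sobol table has
    one row per (variant, QoI) with first/second/total-order indices and
    normalised doughnut fractions.
    """
    config = config or PipelineConfig()
    manifest = RunManifest.start(config)
    dseed = manifest.stage_seeds["design"]
    gseed = manifest.stage_seeds["gsa"]

    healthy = CellParameters()
    variants = {"healthy": healthy,
                "fibrotic": apply_fibrosis_remodelling(healthy)}
    design = lhs_design(n=config.n_lhs, seed=dseed).with_baseline()
    if design.n == 1:
        raise DomainError("empty electrolyte design")

    qoi_frames, sobol_rows = [], []
    for vname, params in variants.items():
        tab = _cell_qoi_table(params, design, config)
        tab.insert(0, "variant", vname)
        qoi_frames.append(tab)
        X = tab[list(ELECTROLYTE_NAMES)].to_numpy()
        for q in QOI_0D:
            em = fit_emulator(X, tab[q].to_numpy(), seed=gseed)
            res = sobol_indices(lambda Z: em.predict(Z), DEFAULT_RANGES,
                                N=config.gsa_N, seed=gseed)
            row = {"variant": vname, "qoi": q, "N": res.n,
                   "zero_variance": res.zero_variance}
            for i, nm in enumerate(res.names):
                row[f"S1_{nm}"] = res.s1[i]
                row[f"ST_{nm}"] = res.st[i]
            for (i, j), v in res.s2.items():
                row[f"S2_{res.names[i]}_{res.names[j]}"] = v
            for k, v in res.doughnut.items():
                row[f"doughnut_{k}"] = v
            sobol_rows.append(row)
    manifest.finished = time.time()
    return {"manifest": manifest, "design": design,
            "qoi": pd.concat(qoi_frames, ignore_index=True),
            "sobol": pd.DataFrame(sobol_rows)}


def run_strand_cv(config: PipelineConfig | None = None) -> dict:
    """Strand CV per cycle length and electrolyte set (healthy + fibrotic).

    Conduction block is reported via the ``blocked`` flag, with CV NaN.
    """
    config = config or PipelineConfig()
    manifest = RunManifest.start(config)
    design = lhs_design(n=config.strand_design_n,
                        seed=manifest.stage_seeds["design"]).with_baseline()
    healthy = CellParameters()
    variants = {"healthy": (healthy, None),
                "fibrotic": (apply_fibrosis_remodelling(healthy), 0.14)}
    rows = []
    for vname, (params, sigma) in variants.items():
        for es in design.electrolyte_sets():
            for cl in config.strand_cls:
                cv, blocked, _ = strand_cv_protocol(
                    params, es, cl_ms=cl, n_prepace=config.prepace_beats,
                    strand_conductivity=sigma)
                rows.append({"variant": vname, "cl_ms": cl,
                             **{k: getattr(es, k) for k in ELECTROLYTE_NAMES},
                             "cv_m_s": cv, "blocked": blocked})
    manifest.finished = time.time()
    return {"manifest": manifest, "design": design, "cv": pd.DataFrame(rows)}


def _paced_map_summary(sub, es, config: PipelineConfig, baseline=None):
    """Two-stimulus CS-paced activation maps -> QoI summary (second beat)."""
    cs = sub.stimulus_masks["CS"]
    c = config.induction
    cl = 1000.0
    stimuli = [StimulusEvent(cs, 0.0, c.stim_dur, c.stim_amp),
               StimulusEvent(cs, cl, c.stim_dur, c.stim_amp)]
    from .induction import _region_initial_states
    Y0 = _region_initial_states(sub, es, cl, c.n_prepace)
    res = solve_monodomain(sub.geometry, sub.params_by_region, es, stimuli,
                           2.0 * cl, dt=c.dt, initial_states=Y0,
                           record_window=(cl, 2.0 * cl),
                           out_dt=config.map_out_dt)
    maps = activation_repolarisation_maps(res)
    cv_map_from_lat(maps, sub.geometry)
    return summarise_qoi(maps, baseline)


def run_cohort(config: PipelineConfig | None = None,
               run_ml: bool = True) -> dict:
    """Cohort pipeline: QoI table, endpoint table and attribution reports.

    Per substrate, the design is the LHS electrolyte combinations plus the
    baseline row; runs that self-sustain after a single paced stimulus are
    flagged and excluded from the QoI table (but still listed). Endpoint
    classifiers are trained when the guard (>= 2 samples per class) passes;
    skipped endpoints are recorded in ``ml_skipped``.
    """
    config = config or PipelineConfig()
    manifest = RunManifest.start(config)
    subs = generate_cohort(config.n_substrates, config.substrate,
                           seed=manifest.stage_seeds["substrate"])
    design = lhs_design(n=config.n_lhs,
                        seed=manifest.stage_seeds["design"]).with_baseline()

    qoi_rows, ep_rows = [], []
    for si, sub in enumerate(subs):
        elecs = design.electrolyte_sets()
        baseline = _paced_map_summary(sub, REFERENCE_ELECTROLYTES, config)
        for ei, es in enumerate(elecs):
            key = {"substrate": si, "elec_id": ei,
                   **{k: getattr(es, k) for k in ELECTROLYTE_NAMES}}
            excluded = screen_single_stimulus(sub, es, config.induction)
            row = dict(key)
            row["excluded_single_stimulus"] = excluded
            if not excluded:
                s = _paced_map_summary(sub, es, config, baseline)
                row.update(s.as_dict())
            qoi_rows.append(row)

            ep = {"substrate": si, "elec_id": ei, **{k: getattr(es, k) for k in ELECTROLYTE_NAMES},
                  "fibrosis_fraction": sub.fibrosis_fraction,
                  "surface_area": sub.surface_area_cm2,
                  "excluded_single_stimulus": excluded}
            records = {}
            for kind in config.protocols:
                proto = InductionProtocol(kind, config.induction)
                res = run_protocol(sub, proto, es)
                records[kind] = classify_episode(res, proto)
            ep["induced_LAA"] = bool(records.get("burst_LAA") and records["burst_LAA"].induced_any)
            ep["induced_AR"] = bool(records.get("burst_roof") and records["burst_roof"].induced_any)
            ep["induced_any"] = ep["induced_LAA"] or ep["induced_AR"]
            terms = [r.terminated for r in records.values() if r.terminated is not None]
            ep["terminated"] = bool(terms and all(terms))
            dfs = [r.dominant_frequency_hz for r in records.values()
                   if np.isfinite(r.dominant_frequency_hz)]
            ep["dominant_frequency_hz"] = float(np.mean(dfs)) if dfs else np.nan
            ep_rows.append(ep)

    qoi_table = pd.DataFrame(qoi_rows)
    ep_table = pd.DataFrame(ep_rows)

    reports, skipped = {}, {}
    if run_ml and len(ep_table):
        table = FeatureTable(ep_table, augmented=True)
        for endpoint in ENDPOINT_NAMES:
            try:
                reports[endpoint] = attribution_report(
                    table, endpoint, seed=manifest.stage_seeds["ml"],
                    n_permutations=config.ml_n_permutations)
            except GuardError as exc:
                skipped[endpoint] = str(exc)

    manifest.finished = time.time()
    return {"manifest": manifest, "design": design, "substrates": subs,
            "qoi": qoi_table, "endpoints": ep_table,
            "ml_reports": reports, "ml_skipped": skipped}
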