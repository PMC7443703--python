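"""End-to-end pipeline: simulate -> preprocess -> sweep -> source analysis.

A single YAML/dict configuration drives the whole run; every stage records
its parameters, inputs and output digests in a :class:`RunManifest` so that
a run is fully reproducible from its manifest.  A stage failure is recorded
and dependent stages are skipped rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .phantom import SimConfig, make_condition_set
from .spectral import welch_psd
from .evaluation import (BandSet, DEFAULT_SWEEPS, detect_dbs_peak, make_report,
                         plot_report, preprocess_conditions, sweep)
from .container import save_container
from .source import (build_grid, compute_leadfield, data_covariance,
                     lcmv_weights, regularize_cov, source_power_at,
                     bootstrap_threshold, active_map, overlap_D)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid pipeline configurations."""


@dataclass
class StageRecord:
    name: str
    status: str                     # "ok", "failed", "skipped"
    params: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # path -> sha256
    error: str | None = None
    started: float = 0.0
    finished: float = 0.0


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def record(self, stage: StageRecord):
        self.stages.append(stage)

    def to_dict(self) -> dict:
        return {"config": self.config, "seed": self.seed,
                "version": self.version,
                "stages": [asdict(s) for s in self.stages]}

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def stage(self, name: str) -> StageRecord | None:
        for s in self.stages:
            if s.name == name:
                return s
        return None


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


DEFAULT_CONFIG = {
    "sim": {},                      # SimConfig overrides
    "methods": ["hampel", "s3p", "icami", "tsss"],
    "sweeps": {},                   # method -> list of values
    "source_freqs": [12.0, 4.0, 5.0, 6.0],
    "grid_spacing": 5e-3,
    "plots": False,
}


def load_config(source) -> dict:
    """Merge a dict or YAML file with the defaults."""
    import yaml

    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        raw = dict(source)
    elif source is None:
        raw = {}
    else:
        raise ConfigError(f"unsupported config source {type(source).__name__}")
    cfg = {**DEFAULT_CONFIG, **raw}
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    bad = [m for m in cfg["methods"] if m not in DEFAULT_SWEEPS]
    if bad:
        raise ConfigError(f"unknown methods: {bad}")
    return cfg


def run_pipeline(config=None, out_dir="megdbs_run", seed: int = 0) -> RunManifest:
    """Run the full study pipeline and return its manifest."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)

    def run_stage(name, fn, params=None, skip=False, reason=""):
        rec = StageRecord(name=name, status="skipped", params=params or {},
                          started=time.time())
        if skip:
            rec.error = reason
            rec.finished = time.time()
            manifest.record(rec)
            logger.info("stage %s skipped: %s", name, reason)
            return None
        try:
            result, outputs = fn()
            rec.outputs = {str(p): _digest(p) for p in outputs}
            rec.status = "ok"
        except Exception as exc:
            rec.status = "failed"
            rec.error = repr(exc)
            result = None
            logger.exception("stage %s failed", name)
        rec.finished = time.time()
        manifest.record(rec)
        return result

    # --- simulate -----------------------------------------------------------
    def do_sim():
        sim_cfg = SimConfig(**{"seed": seed, **cfg["sim"]})
        cset = make_condition_set(sim_cfg)
        path = out / "set.h5"
        save_container(path, cset, provenance={"stage": "simulate",
                                               "seed": seed,
                                               "version": __version__})
        return cset, [path]

    cset = run_stage("simulate", do_sim, params=cfg["sim"])

    # --- preprocess ---------------------------------------------------------
    def do_pre():
        return preprocess_conditions(cset), []

    pre = run_stage("preprocess", do_pre, skip=cset is None,
                    reason="simulation failed")

    # --- sensor-level sweeps ------------------------------------------------
    sweeps = {}
    bands = None
    if pre is not None:
        dsmw_spec = welch_psd(pre.dsmw)
        try:
            f_peak = detect_dbs_peak(dsmw_spec)
        except ValueError:
            f_peak = pre.config.f_stim
        bands = BandSet(f_peak=f_peak)
    for method in cfg["methods"]:
        values = cfg["sweeps"].get(method, DEFAULT_SWEEPS[method])

        def do_sweep(method=method, values=values):
            sw = sweep(method, values, pre, bands, seed=seed)
            return sw, []

        sw = run_stage(f"sweep_{method}", do_sweep,
                       params={"values": list(values)},
                       skip=pre is None, reason="preprocessing unavailable")
        if sw is not None:
            sweeps[method] = sw

    # --- report -------------------------------------------------------------
    def do_report():
        spectra = {"reference": welch_psd(pre.reference),
                   "dsmw": welch_psd(pre.dsmw)}
        report = make_report(pre, sweeps, spectra=spectra)
        rep_dir = out / "report"
        report.save(rep_dir)
        if cfg["plots"]:
            plot_report(report, rep_dir)
        return report, sorted(rep_dir.glob("*.csv"))

    run_stage("report", do_report, skip=pre is None or not sweeps,
              reason="no sweeps available")

    # --- source maps --------------------------------------------------------
    def do_source():
        grid = build_grid(pre.sensors, spacing=cfg["grid_spacing"])
        lf = compute_leadfield(grid, pre.sensors)
        noise_cov = regularize_cov(data_covariance(pre.empty_room))
        maps = {}
        outputs = []
        ref_active = {}
        for freq in cfg["source_freqs"]:
            for cond in ("reference", "dsmw"):
                rec = getattr(pre, cond)
                w = lcmv_weights(regularize_cov(data_covariance(rec)),
                                 noise_cov, lf)
                smap = source_power_at(rec, w, freq)
                if cond == "reference":
                    thr = bootstrap_threshold(smap, seed=seed)
                    smap = active_map(smap, thr)
                    ref_active[freq] = smap.active
                else:
                    thr = bootstrap_threshold(smap, exclude=ref_active[freq],
                                              seed=seed)
                    smap = active_map(smap, thr)
                maps[(cond, freq)] = smap
                path = out / f"smap_{cond}_{freq:g}Hz.h5"
                save_container(path, smap,
                               provenance={"stage": "source", "seed": seed,
                                           "condition": cond,
                                           "frequency": freq})
                outputs.append(path)
        d = {f"{freq:g}Hz": overlap_D(maps[("reference", freq)],
                                      maps[("dsmw", freq)]).d
             for freq in cfg["source_freqs"]}
        (out / "overlap_d.json").write_text(json.dumps(d, indent=2))
        outputs.append(out / "overlap_d.json")
        return maps, outputs

    run_stage("source", do_source, skip=pre is None,
              reason="preprocessing unavailable")

    manifest.save(out / "manifest.json")
    return manifest
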